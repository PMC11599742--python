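"""Vocabulary of chemical-component codes used to model lipids in rhodopsin structures.

Deposited rhodopsin models represent lipids and amphiphiles as small HET
fragments under three-letter chemical-component codes (hydrocarbon chains,
glycoside rings, host-lipid pieces, carotenoids...). This module ships a
curated classification table for those codes and a geometric branched-chain
detector that distinguishes methyl-branched (phytanyl-like, archaeal) chains
from linear (acyl-like, bacterial/synthetic) ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .errors import ElementInferenceRequired, InvalidComponentCode

#: The closed set of lipid classes used throughout the package.
LIPID_CLASSES = frozenset(
    {
        "archaeal_diphytanyl",
        "linear_acyl",
        "carotenoid",
        "isoprenoid_squalene",
        "detergent",
        "sugar_headgroup_fragment",
        "small_amphiphile_or_cryo",
        "unknown",
    }
)

#: Classes whose members are counted as lipids (as opposed to cryo additives
#: or entirely unrecognized components) by the partition and census layers.
LIPID_LIKE_CLASSES = frozenset(LIPID_CLASSES - {"unknown", "small_amphiphile_or_cryo"})

#: Default carbon-carbon bond inference threshold (Å). Covers the 1.53 Å
#: covalent C-C distance with refinement noise while excluding 1-3 neighbours
#: (>= ~2.5 Å in sp3 chains).
CC_BOND_CUTOFF = 1.9

_CODE_RE = re.compile(r"^[A-Z0-9]{3}$")


@dataclass(frozen=True)
class LipidComponentEntry:
    """Classification record for one chemical-component code."""

    code: str
    lipid_class: str
    display_name: str
    source: str  # "paper_list" | "user_extension"

    def __post_init__(self):
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid_class {self.lipid_class!r}")


@dataclass(frozen=True)
class ChainGeometryReport:
    """Branching summary of one residue's carbon skeleton.

    ``n_branch_points`` counts carbons bonded to >= 3 other carbons.
    The verdict is *branched* iff at least one branch point exists and the
    skeleton has >= 4 carbons; skeletons below 4 carbons are *undetermined*.
    """

    n_carbons: int
    n_branch_points: int
    verdict: str  # branched | linear | undetermined


def _builtin_table_path() -> Path:
    return Path(str(resources.files("lipshell").joinpath("data/lipid_components.tsv")))


def load_dictionary(path: str | Path | None = None,
                    extensions: Iterable[str | Path] = ()) -> dict[str, LipidComponentEntry]:
    """Load the component dictionary from TSV.

    Parameters
    ----------
    path:
        Base table; defaults to the table shipped with the package.
    extensions:
        Additional TSV files whose rows override/extend the base table.
        Rows read from extension files get ``source="user_extension"`` unless
        the file states otherwise.
    """
    entries: dict[str, LipidComponentEntry] = {}
    paths = [Path(path) if path is not None else _builtin_table_path()]
    paths += [Path(p) for p in extensions]
    for i, p in enumerate(paths):
        default_source = "paper_list" if i == 0 and path is None else "user_extension"
        for entry in _read_tsv(p, default_source):
            entries[entry.code] = entry
    return entries


def _read_tsv(path: Path, default_source: str) -> list[LipidComponentEntry]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            rows.append(
                LipidComponentEntry(
                    code=fields[idx["code"]].strip().upper(),
                    lipid_class=fields[idx["lipid_class"]].strip(),
                    display_name=fields[idx["display_name"]].strip(),
                    source=fields[idx["source"]].strip() if "source" in idx else default_source,
                )
            )
    return rows


def write_dictionary(entries: Mapping[str, LipidComponentEntry], path: str | Path) -> None:
    """Serialize a dictionary back to TSV (round-trips with :func:`load_dictionary`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("code\tlipid_class\tdisplay_name\tsource\n")
        for code in sorted(entries):
            e = entries[code]
            fh.write(f"{e.code}\t{e.lipid_class}\t{e.display_name}\t{e.source}\n")


_DEFAULT_DICT: dict[str, LipidComponentEntry] | None = None


def default_dictionary() -> dict[str, LipidComponentEntry]:
    """The shipped table, loaded once per process."""
    global _DEFAULT_DICT
    if _DEFAULT_DICT is None:
        _DEFAULT_DICT = load_dictionary()
    return _DEFAULT_DICT


def classify_component(code: str,
                       dictionary: Mapping[str, LipidComponentEntry] | None = None
                       ) -> LipidComponentEntry:
    """Classify a chemical-component code.

    Unlisted (but well-formed) codes return an entry with
    ``lipid_class="unknown"`` rather than raising; malformed identifiers
    raise :class:`InvalidComponentCode`.
    """
    if not isinstance(code, str):
        raise InvalidComponentCode(f"component code must be a string, got {type(code).__name__}")
    normalized = code.strip().upper()
    if not _CODE_RE.match(normalized):
        raise InvalidComponentCode(
            f"component code must be 3 uppercase alphanumeric characters, got {code!r}"
        )
    table = dictionary if dictionary is not None else default_dictionary()
    entry = table.get(normalized)
    if entry is None:
        return LipidComponentEntry(normalized, "unknown", "unlisted component", "user_extension")
    return entry


# --- branched-chain geometry -------------------------------------------------

_NAME_ELEMENT_RE = re.compile(r"([A-Za-z])")


def infer_element_from_name(atom_name: str) -> str:
    """Infer the element symbol from a crystallographic atom name.

    Strips digits/primes and takes the leading letter; two-letter symbols in
    lipid fragments are rare enough that the single-letter reading (C, O, N,
    S, P, H) is the right default.
    """
    m = _NAME_ELEMENT_RE.search(atom_name or "")
    if not m:
        raise ElementInferenceRequired(f"cannot infer element from atom name {atom_name!r}")
    return m.group(1).upper()


def detect_branching(atoms, bond_cutoff: float = CC_BOND_CUTOFF) -> ChainGeometryReport:
    """Report branching of one residue's carbon skeleton.

    ``atoms`` is any iterable yielding objects with ``element``, ``position``
    and (optionally, as fallback) ``atom_name`` attributes — an
    :class:`~lipshell.model.AtomSet` works directly. Carbon-carbon bonds are
    inferred by an interatomic distance threshold (default 1.9 Å).
    """
    elements, coords = [], []
    for a in atoms:
        el = (getattr(a, "element", "") or "").strip()
        if not el:
            el = infer_element_from_name(getattr(a, "atom_name", ""))
        elements.append(el.upper())
        coords.append(np.asarray(a.position, dtype=float))
    if not elements:
        raise ElementInferenceRequired("residue has no atoms")
    return detect_branching_arrays(np.array(elements), np.array(coords), bond_cutoff)


def detect_branching_arrays(elements: np.ndarray, coords: np.ndarray,
                            bond_cutoff: float = CC_BOND_CUTOFF) -> ChainGeometryReport:
    """Array-level core of :func:`detect_branching`."""
    carbon = np.asarray(elements) == "C"
    ccoords = np.asarray(coords, dtype=float)[carbon]
    n_carbons = int(ccoords.shape[0])
    if n_carbons < 4:
        return ChainGeometryReport(n_carbons, 0, "undetermined")
    degree = np.zeros(n_carbons, dtype=int)
    for i, j in cKDTree(ccoords).query_pairs(bond_cutoff):
        degree[i] += 1
        degree[j] += 1
    n_branch = int(np.count_nonzero(degree >= 3))
    return ChainGeometryReport(n_carbons, n_branch, "branched" if n_branch >= 1 else "linear")
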