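"""Crystal-structure I/O, content partitioning, and an atom-selection mini-language.

Structures are read with gemmi (PDB and mmCIF) into a flat, analysis-friendly
record model. Contents are partitioned into protein / retinal / lipid /
solvent / other-HET using the component dictionary, and printed atom
selections such as ``"chain A and resname L2P and resnum 270 and name
O2+C2+C3+C12-C21"`` can be evaluated directly.

Conventions (documented, deliberate):

* alternate locations: the highest-occupancy conformer is kept, ties going
  to altloc "A";
* only the first model of a multi-model file is read (crystal structures);
* hydrogens are retained but flagged, and all downstream geometry uses heavy
  atoms only;
* residue numbering is author numbering, selections are 1-based, name ranges
  are inclusive.
"""

from __future__ import annotations

import re
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, NamedTuple

import gemmi
import numpy as np

from .components import LIPID_LIKE_CLASSES, LipidComponentEntry, classify_component, default_dictionary
from .errors import AssemblyUnavailable, FormatError, InvalidComponentCode, SelectionError
from .geometry import RigidTransform, rotation_about_z

RETINAL_RESNAME = "RET"
_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}


class ResidueKey(NamedTuple):
    chain_id: str
    residue_name: str
    residue_number: int
    insertion_code: str


@dataclass(frozen=True)
class AtomRecord:
    """One retained crystallographic atom site."""

    chain_id: str
    residue_name: str
    residue_number: int
    insertion_code: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False
    altloc: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position {self.position!r}")
        object.__setattr__(self, "position", pos)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.residue_name,
                          self.residue_number, self.insertion_code)


class AtomSet:
    """Ordered, immutable collection of :class:`AtomRecord` with array access."""

    def __init__(self, atoms: Iterable[AtomRecord] = ()):
        self._atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self._atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self._atoms)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return AtomSet(self._atoms[i])
        return self._atoms[i]

    def __add__(self, other: "AtomSet") -> "AtomSet":
        return AtomSet(self._atoms + tuple(other))

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Å."""
        if self._coords is None:
            self._coords = (np.array([a.position for a in self._atoms], dtype=float)
                            if self._atoms else np.empty((0, 3)))
        return self._coords

    def filter(self, predicate: Callable[[AtomRecord], bool]) -> "AtomSet":
        return AtomSet(a for a in self._atoms if predicate(a))

    def heavy(self) -> "AtomSet":
        return self.filter(lambda a: not a.is_hydrogen)

    def chains(self) -> list[str]:
        seen: "OrderedDict[str, None]" = OrderedDict()
        for a in self._atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def by_residue(self) -> "OrderedDict[ResidueKey, AtomSet]":
        groups: "OrderedDict[ResidueKey, list[AtomRecord]]" = OrderedDict()
        for a in self._atoms:
            groups.setdefault(a.residue_key, []).append(a)
        return OrderedDict((k, AtomSet(v)) for k, v in groups.items())

    def transformed(self, transform: RigidTransform) -> "AtomSet":
        return AtomSet(replace(a, position=transform.apply(a.position)) for a in self._atoms)


@dataclass
class Partition:
    """Disjoint cover of a structure's retained atoms by content class."""

    protein: AtomSet
    retinal: AtomSet
    lipid: AtomSet
    solvent: AtomSet
    other_het: AtomSet

    def sets(self) -> dict[str, AtomSet]:
        return {"protein": self.protein, "retinal": self.retinal, "lipid": self.lipid,
                "solvent": self.solvent, "other_het": self.other_het}

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets().items()}

    def residue_counts(self) -> dict[str, int]:
        return {k: len(v.by_residue()) for k, v in self.sets().items()}


@dataclass
class Structure:
    """A parsed (or generated) structure: flat atoms plus light metadata."""

    entry_id: str
    atoms: AtomSet
    space_group: str | None = None
    assembly_ops: list[RigidTransform] = field(default_factory=list)
    helices: list[tuple[str, int, int]] = field(default_factory=list)  # (chain, start, end)

    def __len__(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        return self.atoms.chains()

    def select(self, expression: str) -> AtomSet:
        return select(self, expression)

    def transformed(self, transform: RigidTransform) -> "Structure":
        return Structure(self.entry_id, self.atoms.transformed(transform),
                         self.space_group, list(self.assembly_ops), list(self.helices))


# --- reading ------------------------------------------------------------------

_FORMATS = {"PDB": gemmi.CoorFormat.Pdb, "MMCIF": gemmi.CoorFormat.Mmcif}


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``format`` may be "PDB" or "mmCIF"; by default it is detected from the
    file. Altlocs are resolved (highest occupancy, ties to "A"), only the
    first model is kept, and waters go to solvent at partition time.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if format is None:
            st = gemmi.read_structure(str(path))
        else:
            key = format.upper().replace("MMCIF", "MMCIF")
            if key not in _FORMATS:
                raise FormatError(f"unknown format {format!r}; use 'PDB' or 'mmCIF'")
            st = gemmi.read_structure(str(path), format=_FORMATS[key])
    except FormatError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with context
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise FormatError(f"{path}: no models found")
    if len(st) > 1:
        warnings.warn(f"{path.name}: {len(st)} models present; keeping the first only")

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for res in chain:
            icode = (res.seqid.icode or "").strip()
            het = res.het_flag != "A"
            for name, group in _group_by_name(res):
                best = min(group, key=lambda at: (-at.occ, at.altloc or "A"))
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    insertion_code=icode,
                    atom_name=name,
                    element=best.element.name.upper(),
                    position=np.array([best.pos.x, best.pos.y, best.pos.z]),
                    occupancy=min(max(best.occ, 0.0), 1.0),
                    b_factor=best.b_iso,
                    is_hetero=het,
                    altloc=best.altloc or "",
                ))
    ops = []
    for assembly in st.assemblies:
        for gen in assembly.generators:
            for op in gen.operators:
                tr = op.transform
                mat = np.array(tr.mat.tolist(), dtype=float)
                vec = np.array(tr.vec.tolist(), dtype=float)
                ops.append(RigidTransform(mat, vec))
        break  # first assembly only
    helices = []
    for h in st.helices:
        try:
            helices.append((h.start.chain_name, h.start.res_id.seqid.num,
                            h.end.res_id.seqid.num))
        except Exception:
            continue
    return Structure(entry_id=st.name or path.stem, atoms=AtomSet(atoms),
                     space_group=st.spacegroup_hm or None,
                     assembly_ops=ops, helices=helices)


def _group_by_name(res) -> Iterable[tuple[str, list]]:
    groups: "OrderedDict[str, list]" = OrderedDict()
    for at in res:
        groups.setdefault(at.name, []).append(at)
    return groups.items()


# --- writing ------------------------------------------------------------------

def to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.entry_id
    if structure.space_group:
        st.spacegroup_hm = structure.space_group
    model = gemmi.Model("1")
    chain_order: "OrderedDict[str, gemmi.Chain]" = OrderedDict()
    serial = 0
    for a in structure.atoms:
        if a.chain_id not in chain_order:
            chain_order[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = chain_order[a.chain_id]
        res = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if (last.seqid.num == a.residue_number and last.name == a.residue_name
                    and (last.seqid.icode or "").strip() == a.insertion_code):
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            chain.add_residue(res)
            res = chain[len(chain) - 1]
        at = gemmi.Atom()
        at.name = a.atom_name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        at.altloc = a.altloc or "\0"
        serial += 1
        at.serial = serial
        res.add_atom(at)
    for chain in chain_order.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str | Path) -> None:
    to_gemmi(structure).write_pdb(str(path))


def write_mmcif(structure: Structure, path: str | Path) -> None:
    to_gemmi(structure).make_mmcif_document().write_file(str(path))


def write_atom_table(structure: Structure, path: str | Path) -> None:
    """Flat TSV of all retained atoms (one row per atom)."""
    import pandas as pd

    rows = [{
        "chain": a.chain_id, "resname": a.residue_name, "resnum": a.residue_number,
        "icode": a.insertion_code, "name": a.atom_name, "element": a.element,
        "x": a.position[0], "y": a.position[1], "z": a.position[2],
        "occupancy": a.occupancy, "b_factor": a.b_factor, "hetero": a.is_hetero,
    } for a in structure.atoms]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")


# --- partitioning -------------------------------------------------------------

def partition(structure: Structure,
              dictionary: dict[str, LipidComponentEntry] | None = None) -> Partition:
    """Partition retained atoms into protein / retinal / lipid / solvent / other-HET.

    A residue counts as lipid when its component code classifies to any lipid
    class other than ``unknown`` or ``small_amphiphile_or_cryo``; cryo agents,
    ions and unlisted codes land in ``other_het``.
    """
    table = dictionary if dictionary is not None else default_dictionary()
    buckets: dict[str, list[AtomRecord]] = {k: [] for k in
                                            ("protein", "retinal", "lipid", "solvent", "other_het")}
    for key, atom_set in structure.atoms.by_residue().items():
        buckets[_residue_bucket(key.residue_name, table)].extend(atom_set)
    return Partition(**{k: AtomSet(v) for k, v in buckets.items()})


def _residue_bucket(resname: str, table) -> str:
    if resname == RETINAL_RESNAME:
        return "retinal"
    if resname in _WATER_NAMES:
        return "solvent"
    info = gemmi.find_tabulated_residue(resname)
    if info is not None:
        if info.is_water():
            return "solvent"
        if info.is_amino_acid():
            return "protein"
    try:
        entry = classify_component(resname, table)
    except InvalidComponentCode:
        return "other_het"
    return "lipid" if entry.lipid_class in LIPID_LIKE_CLASSES else "other_het"


# --- selection mini-language ----------------------------------------------------

_RANGE_RE = re.compile(r"^([A-Za-z']+)(\d+)-([A-Za-z']*)(\d+)$")


def expand_name_ranges(spec: str, position: int = 0) -> list[str]:
    """Expand a '+'-joined atom-name list; ranges like ``C12-C21`` expand numerically."""
    names: list[str] = []
    for token in spec.split("+"):
        token = token.strip()
        if not token:
            raise SelectionError("empty atom-name token", position)
        m = _RANGE_RE.match(token)
        if m:
            prefix, lo, prefix2, hi = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
            if prefix2 and prefix2 != prefix:
                raise SelectionError(f"mismatched prefixes in range {token!r}", position)
            if hi < lo:
                raise SelectionError(f"descending range {token!r}", position)
            names.extend(f"{prefix}{i}" for i in range(lo, hi + 1))
        else:
            names.append(token)
    return [n.upper() for n in names]


def parse_selection(expression: str) -> Callable[[AtomRecord], bool]:
    """Compile a conjunction of chain/resname/resnum/name clauses to a predicate."""
    tokens: list[tuple[str, int]] = []
    for m in re.finditer(r"\S+", expression):
        tokens.append((m.group(0), m.start()))
    if not tokens:
        raise SelectionError("empty selection", 0)
    clauses: list[Callable[[AtomRecord], bool]] = []
    i = 0
    while i < len(tokens):
        word, pos = tokens[i]
        keyword = word.lower()
        if keyword not in ("chain", "resname", "resnum", "name"):
            raise SelectionError(f"unknown clause {word!r}", pos)
        if i + 1 >= len(tokens):
            raise SelectionError(f"clause {word!r} missing its argument", pos)
        arg, argpos = tokens[i + 1]
        if keyword == "chain":
            value = arg
            clauses.append(lambda a, v=value: a.chain_id == v)
        elif keyword == "resname":
            value = arg.upper()
            clauses.append(lambda a, v=value: a.residue_name.upper() == v)
        elif keyword == "resnum":
            try:
                num = int(arg)
            except ValueError:
                raise SelectionError(f"resnum expects an integer, got {arg!r}", argpos)
            clauses.append(lambda a, v=num: a.residue_number == v)
        else:  # name
            allowed = set(expand_name_ranges(arg, argpos))
            clauses.append(lambda a, v=frozenset(allowed): a.atom_name.upper() in v)
        i += 2
        if i < len(tokens):
            word, pos = tokens[i]
            if word.lower() != "and":
                raise SelectionError(f"expected 'and', got {word!r}", pos)
            i += 1
            if i >= len(tokens):
                raise SelectionError("dangling 'and'", pos)
    return lambda a: all(c(a) for c in clauses)


def select(structure: Structure, expression: str) -> AtomSet:
    """Evaluate a selection expression; an empty result is legal but warned about."""
    predicate = parse_selection(expression)
    result = structure.atoms.filter(predicate)
    if len(result) == 0:
        warnings.warn(f"selection {expression!r} matched no atoms")
    return result


# --- assembly expansion ---------------------------------------------------------

_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def _fresh_chain_names(used: set[str], n: int) -> list[str]:
    out: list[str] = []
    for ch in _CHAIN_ALPHABET:
        if len(out) == n:
            break
        if ch not in used:
            out.append(ch)
            used.add(ch)
    while len(out) < n:  # two-letter fallback
        name = f"{_CHAIN_ALPHABET[len(out) % 52]}{len(out) // 52}"
        if name not in used:
            out.append(name)
            used.add(name)
    return out


def c3_operators(axis_origin: np.ndarray | None = None) -> list[RigidTransform]:
    """Identity + 120°/240° rotations about the global z axis (through the origin
    unless ``axis_origin`` is given)."""
    origin = np.zeros(3) if axis_origin is None else np.asarray(axis_origin, dtype=float)
    ops = []
    for k in range(3):
        rot = rotation_about_z(2.0 * np.pi * k / 3.0)
        ops.append(RigidTransform(rot, origin - rot @ origin))
    return ops


def expand_assembly(structure: Structure,
                    ops: list[RigidTransform] | None = None,
                    point_symmetry: str | None = None) -> Structure:
    """Apply assembly operators, giving generated copies fresh chain identifiers.

    ``ops`` is the full operator list (identity included); alternatively
    ``point_symmetry="C3"`` builds the three rotations about the global z
    axis. With neither argument, operators deposited with the entry are used;
    if none exist, :class:`AssemblyUnavailable` is raised.
    """
    if ops is None:
        if point_symmetry is not None:
            if point_symmetry.upper() != "C3":
                raise AssemblyUnavailable(f"unsupported point symmetry {point_symmetry!r}")
            ops = c3_operators()
        elif structure.assembly_ops:
            ops = structure.assembly_ops
        else:
            raise AssemblyUnavailable(
                f"{structure.entry_id}: no operators supplied or deposited")
    used = set(structure.chains())
    atoms: list[AtomRecord] = []
    for k, op in enumerate(ops):
        is_identity = (np.allclose(op.rotation, np.eye(3), atol=1e-12)
                       and np.allclose(op.translation, 0.0, atol=1e-12))
        if k == 0 and is_identity:
            atoms.extend(structure.atoms)
            continue
        src_chains = structure.chains()
        mapping = dict(zip(src_chains, _fresh_chain_names(used, len(src_chains))))
        for a in structure.atoms:
            atoms.append(replace(a, chain_id=mapping[a.chain_id],
                                 position=op.apply(a.position)))
    return Structure(structure.entry_id, AtomSet(atoms), structure.space_group,
                     [], list(structure.helices))
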