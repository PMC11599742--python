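"""Per-protomer lipid censuses and trimer lipid budgets.

A "fragment" is one HET residue whose component code classifies to a lipid
class; multi-residue lipids are not merged (that is the granularity at which
deposited models — and published per-protomer counts — enumerate lipids).
Per-protomer values are kept as exact rationals so that, e.g., two glycolipids
in a trimer render as "2/3" rather than 0.67.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from .components import LIPID_LIKE_CLASSES, LipidComponentEntry, classify_component
from .errors import InvalidComponentCode, InvalidProtomerCount
from .model import Structure, partition


def format_fraction(value: Fraction) -> str:
    """Render a rational count the way published tables do ("2", "2/3", "10/3")."""
    if value.denominator == 1:
        return str(value.numerator)
    return f"{value.numerator}/{value.denominator}"


@dataclass(frozen=True)
class CensusRow:
    """Lipid census of one entry, total and recalculated per protomer."""

    entry_id: str
    n_protomers: int
    per_class_total: dict[str, int]
    per_class_per_protomer: dict[str, Fraction]
    lipid_total: int
    lipid_per_protomer: Fraction
    other_het_residues: int  # non-lipid HET residues (cryo agents, unknown codes, ions)

    def to_dict(self) -> dict:
        return {
            "entry_id": self.entry_id,
            "n_protomers": self.n_protomers,
            "per_class_total": dict(self.per_class_total),
            "per_class_per_protomer": {k: format_fraction(v)
                                       for k, v in self.per_class_per_protomer.items()},
            "lipid_total": self.lipid_total,
            "lipid_per_protomer": format_fraction(self.lipid_per_protomer),
            "other_het_residues": self.other_het_residues,
        }


def lipid_census(structure: Structure,
                 dictionary: dict[str, LipidComponentEntry] | None = None,
                 n_protomers: int = 1,
                 entry_id: str | None = None) -> CensusRow:
    """Count lipid fragments per class and recalculate per protomer (exact rationals)."""
    if not isinstance(n_protomers, int) or n_protomers < 1:
        raise InvalidProtomerCount(f"n_protomers must be a positive integer, got {n_protomers!r}")
    part = partition(structure, dictionary)
    totals: dict[str, int] = {}
    for key in part.lipid.by_residue():
        entry = classify_component(key.residue_name, dictionary)
        totals[entry.lipid_class] = totals.get(entry.lipid_class, 0) + 1
    for cls in totals:
        assert cls in LIPID_LIKE_CLASSES
    per_protomer = {cls: Fraction(n, n_protomers) for cls, n in totals.items()}
    lipid_total = sum(totals.values())
    other = len(part.other_het.by_residue())
    return CensusRow(
        entry_id=entry_id or structure.entry_id,
        n_protomers=n_protomers,
        per_class_total=dict(sorted(totals.items())),
        per_class_per_protomer=dict(sorted(per_protomer.items())),
        lipid_total=lipid_total,
        lipid_per_protomer=Fraction(lipid_total, n_protomers),
        other_het_residues=other,
    )


def trimer_lipid_budget(per_protomer: int, extra_per_protomer: int = 1,
                        n_protomers: int = 3) -> int:
    """Total lipid placement budget for an oligomer prediction.

    ``per_protomer`` annular fragments plus ``extra_per_protomer`` molecules
    per protomer (by default one, for the consistently occupied retinal
    binding site), times the number of protomers.
    """
    if per_protomer < 0 or extra_per_protomer < 0:
        raise ValueError("counts must be non-negative")
    if n_protomers < 1:
        raise InvalidProtomerCount(f"n_protomers must be >= 1, got {n_protomers}")
    return n_protomers * (per_protomer + extra_per_protomer)


def census_table(rows: list[CensusRow]):
    """Census rows as a pandas DataFrame (one row per entry) for TSV export."""
    import pandas as pd

    records = []
    for r in rows:
        rec = {"entry": r.entry_id, "n_protomers": r.n_protomers,
               "lipid_total": r.lipid_total,
               "lipid_per_protomer": format_fraction(r.lipid_per_protomer),
               "other_het_residues": r.other_het_residues}
        for cls, n in r.per_class_total.items():
            rec[f"total:{cls}"] = n
            rec[f"per_protomer:{cls}"] = format_fraction(r.per_class_per_protomer[cls])
        records.append(rec)
    return pd.DataFrame(records)


def write_census_json(rows: list[CensusRow], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in rows], indent=1))
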