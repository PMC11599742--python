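"""Membrane coordinate frames and structure superposition.

A :class:`MembraneFrame` carries the membrane normal, the z-origin placed at
the bilayer median, and the hydrophobic-hydrophilic boundary depths. Frames
are assigned from externally computed boundaries when available; a
transparent slab estimator is provided as a fallback for synthetic scenes
(it slides a hydrophobic-belt window along the bundle axis; it is *not* a
reimplementation of boundary-energy methods such as PPM).

Superposition follows the common practice for rhodopsin comparisons: align
on backbone (N, CA, C, O) plus retinal atoms, or on helical Cα atoms when a
helix-restricted RMSD is wanted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import geometry
from .errors import EmptyCorrespondence, InsufficientData
from .geometry import RigidTransform
from .model import AtomSet, Structure

BACKBONE_NAMES = ("N", "CA", "C", "O")

#: Kyte-Doolittle hydropathy, used only by the fallback slab estimator.
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9, "TYR": -1.3,
    "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5, "ASP": -3.5, "ASN": -3.5,
    "LYS": -3.9, "ARG": -4.5,
}


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane normal + bilayer-median origin + boundary depths (Å)."""

    normal: np.ndarray  # unit 3-vector
    z_origin: float  # Å along the normal; bilayer median
    z_lower: float  # Å relative to origin, < 0
    z_upper: float  # Å relative to origin, > 0

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("membrane normal must be a unit vector")
        if not (self.z_lower < 0.0 < self.z_upper):
            raise ValueError("boundaries must straddle the origin: z_lower < 0 < z_upper")
        object.__setattr__(self, "normal", n)

    @property
    def thickness(self) -> float:
        return self.z_upper - self.z_lower

    def depth(self, coords: np.ndarray) -> np.ndarray:
        """Signed depth of positions relative to the bilayer median."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.normal - self.z_origin

    def contains(self, depths: np.ndarray) -> np.ndarray:
        depths = np.asarray(depths, dtype=float)
        return (depths >= self.z_lower) & (depths <= self.z_upper)

    def transformed(self, transform: RigidTransform) -> "MembraneFrame":
        """Co-transform the frame so depths of co-transformed atoms are preserved."""
        new_normal = transform.rotation @ self.normal
        new_origin = self.z_origin + float(new_normal @ transform.translation)
        return MembraneFrame(new_normal, new_origin, self.z_lower, self.z_upper)

    def to_dict(self) -> dict:
        return {"normal": self.normal.tolist(), "z_origin": self.z_origin,
                "z_lower": self.z_lower, "z_upper": self.z_upper}

    @classmethod
    def from_dict(cls, d: dict) -> "MembraneFrame":
        return cls(np.array(d["normal"], dtype=float), float(d["z_origin"]),
                   float(d["z_lower"]), float(d["z_upper"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MembraneFrame":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --- superposition ---------------------------------------------------------------

def kabsch_superpose(reference: AtomSet | np.ndarray,
                     mobile: AtomSet | np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal superposition of ``mobile`` onto ``reference``.

    Inputs are equal-length, correspondence-ordered atom sets (or coordinate
    arrays). Returns the rigid transform and the RMSD over the correspondence.
    """
    ref = reference.coords if isinstance(reference, AtomSet) else np.asarray(reference, float)
    mob = mobile.coords if isinstance(mobile, AtomSet) else np.asarray(mobile, float)
    return geometry.kabsch(ref, mob)


def pair_backbone_retinal(a: Structure, b: Structure) -> tuple[AtomSet, AtomSet]:
    """Backbone + retinal correspondence between two structures.

    Protein N/CA/C/O atoms are paired on shared (chain, residue-number) keys;
    retinal atoms on shared atom names of the first retinal residue of each
    structure. When the two structures share no chain identifiers, backbone
    pairing falls back to residue numbers within the first protein chain of
    each.
    """
    from .model import RETINAL_RESNAME, partition

    part_a, part_b = partition(a), partition(b)

    def backbone_index(part, restrict_chain: str | None):
        index = {}
        for atom in part.protein.heavy():
            if atom.atom_name.upper() not in BACKBONE_NAMES:
                continue
            if restrict_chain is not None and atom.chain_id != restrict_chain:
                continue
            chain = atom.chain_id if restrict_chain is None else "*"
            index[(chain, atom.residue_number, atom.insertion_code,
                   atom.atom_name.upper())] = atom
        return index

    idx_a = backbone_index(part_a, None)
    idx_b = backbone_index(part_b, None)
    shared = sorted(set(idx_a) & set(idx_b))
    if not shared:
        chain_a = part_a.protein.chains()[0] if len(part_a.protein) else None
        chain_b = part_b.protein.chains()[0] if len(part_b.protein) else None
        if chain_a is not None and chain_b is not None:
            idx_a = backbone_index(part_a, chain_a)
            idx_b = backbone_index(part_b, chain_b)
            shared = sorted(set(idx_a) & set(idx_b))
    atoms_a = [idx_a[k] for k in shared]
    atoms_b = [idx_b[k] for k in shared]

    def first_retinal(part) -> dict[str, object]:
        residues = part.retinal.by_residue()
        if not residues:
            return {}
        first = next(iter(residues.values()))
        return {atom.atom_name.upper(): atom for atom in first.heavy()}

    ret_a, ret_b = first_retinal(part_a), first_retinal(part_b)
    for name in sorted(set(ret_a) & set(ret_b)):
        atoms_a.append(ret_a[name])
        atoms_b.append(ret_b[name])

    if not atoms_a:
        raise EmptyCorrespondence(
            f"{a.entry_id} and {b.entry_id} share no backbone/{RETINAL_RESNAME} atoms")
    return AtomSet(atoms_a), AtomSet(atoms_b)


def align_backbone_retinal(reference: Structure, mobile: Structure
                           ) -> tuple[RigidTransform, float]:
    """Superpose ``mobile`` onto ``reference`` on backbone + retinal atoms."""
    ref_set, mob_set = pair_backbone_retinal(reference, mobile)
    return kabsch_superpose(ref_set, mob_set)


def helical_rmsd(a: Structure, b: Structure,
                 helix_ranges: list[tuple[str | None, int, int]] | None = None,
                 superpose: bool = True) -> float:
    """RMSD over helical Cα atoms, after superposing on those same atoms.

    ``helix_ranges`` is a list of (chain or None, first residue, last residue),
    inclusive; by default the deposited helix annotations of ``a`` are used.
    ``superpose=False`` evaluates the RMSD in the current coordinates (useful
    for closed-form checks).
    """
    ranges = helix_ranges if helix_ranges is not None else a.helices
    if not ranges:
        raise EmptyCorrespondence("no helix ranges provided or deposited")

    def in_ranges(atom) -> bool:
        for chain, lo, hi in ranges:
            if (chain is None or atom.chain_id == chain) and lo <= atom.residue_number <= hi:
                return True
        return False

    def ca_index(st: Structure):
        return {(atom.chain_id, atom.residue_number, atom.insertion_code): atom
                for atom in st.atoms.heavy()
                if atom.atom_name.upper() == "CA" and not atom.is_hetero and in_ranges(atom)}

    idx_a, idx_b = ca_index(a), ca_index(b)
    shared = sorted(set(idx_a) & set(idx_b))
    if not shared:
        # fall back to residue-number-only pairing across differing chain ids
        idx_a = {(num, ic): atom for (ch, num, ic), atom in idx_a.items()}
        idx_b = {(num, ic): atom for (ch, num, ic), atom in idx_b.items()}
        shared = sorted(set(idx_a) & set(idx_b))
    if not shared:
        raise EmptyCorrespondence("no shared helical Cα atoms")
    ref = np.array([idx_a[k].position for k in shared])
    mob = np.array([idx_b[k].position for k in shared])
    if not superpose:
        return geometry.rmsd(ref, mob)
    _, value = geometry.kabsch(ref, mob)
    return value


# --- frame assignment --------------------------------------------------------------

def bundle_normal(ca_atoms: AtomSet) -> np.ndarray:
    """Membrane-normal estimate from the helix rise directions of a Cα trace.

    Uses i -> i+4 Cα displacement vectors (the local α-helix axis direction)
    within each chain and takes the dominant eigenvector of their
    orientation tensor; unlike a plain principal axis of the coordinates this
    stays normal-aligned for wide oligomeric assemblies. Sign-fixed so the
    largest-magnitude component is positive.
    """
    by_chain: dict[str, list] = {}
    for a in ca_atoms:
        by_chain.setdefault(a.chain_id, []).append(a)
    segments = []
    for atoms in by_chain.values():
        atoms.sort(key=lambda a: (a.residue_number, a.insertion_code))
        index = {a.residue_number: a for a in atoms}
        for num, a in index.items():
            partner = index.get(num + 4)
            if partner is None:
                continue
            v = partner.position - a.position
            norm = np.linalg.norm(v)
            if 3.0 <= norm <= 9.0:  # plausible helical rise over 4 residues
                segments.append(v / norm)
    if len(segments) < 3:
        raise InsufficientData("too few Cα i->i+4 segments to orient the membrane normal")
    seg = np.array(segments)
    tensor = seg.T @ seg
    w, v = np.linalg.eigh(tensor)
    axis = v[:, np.argmax(w)]
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """Largest-variance principal direction (the bundle long axis for 7-TM folds),
    sign-fixed so the largest-magnitude component is positive."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def assign_frame(structure: Structure,
                 boundaries: tuple[float, float] | None = None,
                 estimate: bool = False,
                 normal: np.ndarray | None = None,
                 slab_widths: tuple[float, ...] = (24.0, 26.0, 28.0, 30.0, 32.0, 34.0, 36.0),
                 ) -> MembraneFrame:
    """Assign a membrane frame to a structure.

    ``boundaries`` are the two hydrophobic-hydrophilic boundary positions as
    projections onto the membrane normal (externally computed boundaries are
    the expected input); the z-origin is placed at their midpoint — the
    bilayer median. With ``estimate=True`` the boundaries are estimated by a
    hydrophobic-belt slab search over the protein Cα trace.
    """
    from .model import partition

    part = partition(structure)
    ca = part.protein.filter(lambda at: at.atom_name.upper() == "CA").heavy()
    if normal is not None:
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
    else:
        source = _helical_ca(structure, ca)
        if len(source) < 3:
            raise InsufficientData("too few Cα atoms to orient the membrane normal")
        n = bundle_normal(source)

    if boundaries is not None:
        lo, hi = float(boundaries[0]), float(boundaries[1])
        if not lo < hi:
            raise ValueError("boundaries must satisfy z_lower < z_upper")
    elif estimate:
        if len(ca.by_residue()) < 50:
            raise InsufficientData("boundary estimation needs >= 50 protein residues")
        lo, hi = _estimate_boundaries(ca, n, slab_widths)
    else:
        raise ValueError("either supply boundaries or request estimate=True")
    origin = 0.5 * (lo + hi)
    return MembraneFrame(n, origin, lo - origin, hi - origin)


def _helical_ca(structure: Structure, ca: AtomSet) -> AtomSet:
    if not structure.helices:
        return ca
    ranges = structure.helices

    def in_ranges(atom) -> bool:
        return any((ch is None or atom.chain_id == ch) and lo <= atom.residue_number <= hi
                   for ch, lo, hi in ranges)

    helical = ca.filter(in_ranges)
    return helical if len(helical) >= 3 else ca


def _estimate_boundaries(ca: AtomSet, normal: np.ndarray,
                         widths: tuple[float, ...]) -> tuple[float, float]:
    """Slide a slab along the normal maximizing (hydrophobic − polar) Cα count."""
    proj = ca.coords @ normal
    hydro = np.array([KYTE_DOOLITTLE.get(a.residue_name.upper(), 0.0) > 0.0 for a in ca])
    lo_all, hi_all = proj.min(), proj.max()
    best = None
    centers = np.arange(lo_all, hi_all + 0.25, 0.5)
    for width in widths:
        half = width / 2.0
        for c in centers:
            inside = (proj >= c - half) & (proj <= c + half)
            score = int(np.count_nonzero(inside & hydro)) - int(np.count_nonzero(inside & ~hydro))
            key = (score, -width)  # prefer the tighter slab on ties
            if best is None or key > best[0]:
                best = (key, c - half, c + half)
    assert best is not None
    return best[1], best[2]
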