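"""Synthetic membrane-protein scenes with known ground truth.

Scenes emulate the geometry the analysis pipeline is aimed at: a C3-symmetric
seven-helix bundle (idealized α-helical Cα/backbone spirals, Cβ pseudo-atoms,
a retinal-like polyene chain in the core) embedded in a membrane slab, with
annular lipid chains planted at controlled nearest-surface distances in
inner-compartment, inter-protomer and peripheral locations, and noble-gas
atoms whose depths are drawn from a stated Gaussian mixture (bilayer core
plus flanking layers).

Placement is solved, not sampled: the requested nearest-approach distance d0
is achieved exactly (to root-finder tolerance) by sliding the chain along a
placement ray until its minimum distance to the protein heavy atoms equals
d0. Two placement modes exist:

* ``rigid`` — the ideal chain is translated as a whole; its bond geometry is
  preserved (use for branching tests and location labels), and the *minimum*
  lipid-protein distance equals d0.
* ``surface_tracking`` — each chain atom is slid independently along the ray,
  so *every* atom sits exactly d0 from its nearest protein atom (the
  idealization of an annular chain hugging the surface); bond geometry is
  mildly distorted. Default for linear peripheral chains.

Everything is deterministic for a given spec (seed included): fixture files
regenerate byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import PlacementFailure
from .geometry import rotation_about_z
from .model import AtomRecord, AtomSet, Structure, c3_operators, expand_assembly, write_pdb

# ideal α-helix Cα spiral
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = np.deg2rad(100.0)  # per residue
CA_RADIUS = 2.3  # Å from helix axis
BUNDLE_RADIUS = 10.0  # Å, helix axes from the protomer centre
CC_BOND = 1.53  # Å
CONTACT_RADIUS = 2.8  # Å, lower bound for any planted d0

_DEFAULT_RESNAME = {"archaeal_diphytanyl": "L2P", "linear_acyl": "OLC"}


@dataclass(frozen=True)
class LipidSpec:
    """One planted lipid chain."""

    lipid_class: str = "linear_acyl"
    location: str = "peripheral"  # inner_compartment | inter_protomer | peripheral
    d0: float = 4.0  # target nearest-surface distance, Å
    jitter: float = 0.0  # per-atom Gaussian σ, Å
    branched: bool = False
    n_carbons: int = 16
    resname: str | None = None
    surface_tracking: bool | None = None  # None = auto

    def __post_init__(self):
        if self.d0 <= CONTACT_RADIUS:
            raise ValueError(f"d0 must exceed the contact radius {CONTACT_RADIUS} Å")
        if self.location not in ("inner_compartment", "inter_protomer", "peripheral"):
            raise ValueError(f"unknown location {self.location!r}")

    @property
    def effective_resname(self) -> str:
        return self.resname or _DEFAULT_RESNAME.get(self.lipid_class, "OLC")

    @property
    def tracking(self) -> bool:
        if self.surface_tracking is not None:
            return self.surface_tracking and not self.branched
        return self.location == "peripheral" and not self.branched


@dataclass(frozen=True)
class GasMixtureSpec:
    """Noble-gas depth mixture: weights must sum to 1."""

    weights: tuple[float, ...] = (0.3, 0.4, 0.3)
    means: tuple[float, ...] = (-10.0, 0.0, 10.0)  # Å
    sds: tuple[float, ...] = (3.0, 3.0, 3.0)  # Å
    n_atoms: int = 300
    element: str = "KR"

    def __post_init__(self):
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("weights, means and sds must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene; identical specs give identical scenes."""

    seed: int = 0
    n_helices: int = 7
    helix_length: int = 22
    trimer: bool = True
    boundaries: tuple[float, float] = (-16.0, 16.0)
    lipids: tuple[LipidSpec, ...] = ()
    gas: GasMixtureSpec | None = None
    protomer_radius: float | None = None  # solved from the inner lipid when present

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        lipids = tuple(LipidSpec(**ls) for ls in d.get("lipids", ()))
        gas = d.get("gas")
        return cls(
            seed=int(d.get("seed", 0)),
            n_helices=int(d.get("n_helices", 7)),
            helix_length=int(d.get("helix_length", 22)),
            trimer=bool(d.get("trimer", True)),
            boundaries=tuple(d.get("boundaries", (-16.0, 16.0))),
            lipids=lipids,
            gas=GasMixtureSpec(**{**gas, "weights": tuple(gas["weights"]),
                                  "means": tuple(gas["means"]),
                                  "sds": tuple(gas["sds"])}) if gas else None,
            protomer_radius=d.get("protomer_radius"),
        )


# --- protomer construction ------------------------------------------------------


def _base_protomer(spec: SceneSpec) -> tuple[list[AtomRecord], list[tuple[str, int, int]]]:
    """Idealized 7-helix bundle + retinal-like chain, centred at the origin, chain A."""
    atoms: list[AtomRecord] = []
    ranges = []
    length = spec.helix_length
    z0 = -HELIX_RISE * (length - 1) / 2.0
    z_lo, z_hi = spec.boundaries
    for h in range(spec.n_helices):
        alpha = 2.0 * np.pi * h / spec.n_helices
        axis = BUNDLE_RADIUS * np.array([np.cos(alpha), np.sin(alpha), 0.0])
        first = h * 100 + 1
        ranges.append(("A", first, first + length - 1))
        for i in range(length):
            z = z0 + HELIX_RISE * i
            theta = HELIX_TWIST * i + alpha  # stagger phases between helices
            resname = "LEU" if z_lo <= z <= z_hi else "SER"
            resnum = first + i
            radial = np.array([np.cos(theta), np.sin(theta), 0.0])

            def ring(radius, dtheta, dz):
                ang = theta + dtheta
                return axis + radius * np.array([np.cos(ang), np.sin(ang), 0.0]) \
                    + np.array([0.0, 0.0, z + dz])

            for name, element, pos in (
                ("N", "N", ring(CA_RADIUS, -0.6, -0.9)),
                ("CA", "C", ring(CA_RADIUS, 0.0, 0.0)),
                ("C", "C", ring(CA_RADIUS, 0.6, 0.9)),
                ("O", "O", ring(3.0, 0.6, 1.2)),
                ("CB", "C", axis + (CA_RADIUS + 1.5) * radial + np.array([0.0, 0.0, z])),
            ):
                atoms.append(AtomRecord("A", resname, resnum, "", name, element, pos))
    # retinal-like polyene in the bundle core
    n_ret = 15
    for k in range(n_ret):
        pos = np.array([1.4 * (k - (n_ret - 1) / 2.0), 0.5 * (-1) ** k, 0.0])
        atoms.append(AtomRecord("A", "RET", 999, "", f"C{k + 1}", "C", pos,
                                is_hetero=True))
    return atoms, ranges


def _translate(atoms: list[AtomRecord], shift: np.ndarray) -> list[AtomRecord]:
    from dataclasses import replace
    return [replace(a, position=a.position + shift) for a in atoms]


# --- lipid chain templates ------------------------------------------------------


def _chain_template(n_carbons: int, branched: bool, straight: bool = False
                    ) -> tuple[list[str], np.ndarray]:
    """Local chain coordinates in the (u, v, z) placement basis.

    Linear chains zig-zag in the v-z plane with ideal 1.53 Å C-C bonds;
    branched chains add a methyl carbon along +u at every 4th backbone carbon
    (phytanyl-like pattern). ``straight`` collapses the zig-zag onto the z
    axis (used for on-axis inner-compartment chains, which must be exactly
    C3-symmetric).
    """
    names: list[str] = []
    coords: list[np.ndarray] = []
    if straight:
        dz, off = CC_BOND, 0.0
    else:
        off = 0.45
        dz = float(np.sqrt(CC_BOND**2 - (2 * off) ** 2))
    z0 = -dz * (n_carbons - 1) / 2.0
    for k in range(n_carbons):
        names.append(f"C{k + 1}")
        coords.append(np.array([0.0, off * (-1) ** k, z0 + dz * k]))
    if branched:
        n_branch = 0
        for k in range(3, n_carbons - 1, 4):  # internal carbons 4, 8, 12, ...
            n_branch += 1
            names.append(f"CM{n_branch}")
            coords.append(coords[k] + np.array([CC_BOND, 0.0, 0.0]))
    return names, np.array(coords)


# --- placement solvers ----------------------------------------------------------


def _min_dist(coords: np.ndarray, protein: "np.ndarray | cKDTree") -> float:
    if isinstance(protein, cKDTree):
        d, _ = protein.query(coords, k=1)
        return float(np.min(d))
    diff = coords[:, None, :] - protein[None, :, :]
    return float(np.sqrt(np.min(np.sum(diff * diff, axis=2))))


def _outermost_crossing(f, d0: float, s_hi: float, s_lo: float = 0.0,
                        step: float = 1.0) -> float:
    """Largest s in [s_lo, s_hi] with f(s) = d0, assuming f(s_hi) > d0."""
    if f(s_hi) <= d0:
        raise PlacementFailure("placement ray never clears the target distance")
    s = s_hi - step
    while s >= s_lo:
        if f(s) < d0:
            return float(brentq(lambda x: f(x) - d0, s, s + step, xtol=1e-12))
        s -= step
    raise PlacementFailure("no crossing of the target distance along the placement ray")


def _place_chain(template: np.ndarray, u: np.ndarray, protein: "np.ndarray | cKDTree",
                 d0: float, tracking: bool, s_hi: float) -> np.ndarray:
    """Place a chain along ray direction u so its nearest approach to the
    protein equals d0 (every atom at d0 when tracking)."""
    v = np.cross(np.array([0.0, 0.0, 1.0]), u)
    v /= np.linalg.norm(v)

    def world(s: float, rows: np.ndarray) -> np.ndarray:
        return (s + rows[:, 0:1]) * u + rows[:, 1:2] * v \
            + rows[:, 2:3] * np.array([0.0, 0.0, 1.0])

    if tracking:
        out = np.empty((len(template), 3))
        for k, row in enumerate(template):
            s_k = _outermost_crossing(
                lambda s, r=row: _min_dist(world(s, r[None, :]), protein), d0, s_hi)
            out[k] = world(s_k, row[None, :])[0]
        return out
    s_star = _outermost_crossing(lambda s: _min_dist(world(s, template), protein), d0, s_hi)
    return world(s_star, template)


def _place_inter(template: np.ndarray, protein_by_chain: dict[str, np.ndarray],
                 chain_pair: tuple[str, str], d0: float, s_hi: float) -> np.ndarray:
    """Place a chain in the groove between two protomers, equidistant (= d0) from both."""
    all_protein = cKDTree(np.vstack(list(protein_by_chain.values())))
    pa, pb = (cKDTree(protein_by_chain[c]) for c in chain_pair)

    def solved(phi: float) -> np.ndarray:
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        return _place_chain(template, u, all_protein, d0, tracking=False, s_hi=s_hi)

    def gap(phi: float) -> float:
        coords = solved(phi)
        return _min_dist(coords, pa) - _min_dist(coords, pb)

    lo, hi = np.deg2rad(60.0 - 30.0), np.deg2rad(60.0 + 30.0)
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise PlacementFailure("cannot bracket an equidistant inter-protomer placement")
    phi_star = brentq(gap, lo, hi, xtol=1e-10)
    return solved(phi_star)


# --- scene assembly --------------------------------------------------------------


def build_scene(spec: SceneSpec) -> tuple[Structure, dict]:
    """Build a scene and its ground-truth record.

    Returns the structure (protein chains A[, B, C], lipids on chain L, gas
    on chain G) and a JSON-serializable truth dict: the membrane frame, the
    solved trimer radius, per-lipid placement records and the gas mixture.
    """
    rng = np.random.default_rng(spec.seed)
    base_atoms, helix_ranges = _base_protomer(spec)
    base_protein = np.array([a.position for a in base_atoms
                             if not a.is_hetero and not a.is_hydrogen])

    inner = [ls for ls in spec.lipids if ls.location == "inner_compartment"]
    if inner and not spec.trimer:
        raise PlacementFailure("inner-compartment lipids require a trimer scene")
    if any(ls.location == "inter_protomer" for ls in spec.lipids) and not spec.trimer:
        raise PlacementFailure("inter-protomer lipids require a trimer scene")

    if spec.trimer:
        radius = spec.protomer_radius
        if radius is None:
            radius = _solve_trimer_radius(base_protein, inner[0] if inner else None)
        protomer = Structure("protomer", AtomSet(
            _translate(base_atoms, np.array([radius, 0.0, 0.0]))), helices=helix_ranges)
        assembly = expand_assembly(protomer, ops=c3_operators())
    else:
        radius = None
        assembly = Structure("protomer", AtomSet(base_atoms), helices=helix_ranges)

    protein_atoms = [a for a in assembly.atoms if not a.is_hetero and not a.is_hydrogen]
    protein = np.array([a.position for a in protein_atoms])
    protein_by_chain: dict[str, np.ndarray] = {}
    for a in protein_atoms:
        protein_by_chain.setdefault(a.chain_id, []).append(a.position)
    protein_by_chain = {c: np.array(v) for c, v in protein_by_chain.items()}
    protein_tree = cKDTree(protein)
    lateral_max = float(np.max(np.linalg.norm(protein[:, :2], axis=1)))
    s_hi = lateral_max + 30.0

    atoms = list(assembly.atoms)
    truth_lipids = []
    inner_seen = 0
    peripheral_seen = 0
    protomer_angles = (0.0, 120.0, 240.0) if spec.trimer else tuple(range(0, 360, 45))
    for idx, ls in enumerate(spec.lipids):
        # inner-compartment chains sit on the three-fold axis and must stay
        # exactly C3-symmetric: straight, unbranched skeleton regardless of spec
        inner_loc = ls.location == "inner_compartment"
        branched = ls.branched and not inner_loc
        names, template = _chain_template(ls.n_carbons, branched, straight=inner_loc)
        if inner_loc:
            # the solved trimer radius realizes d0 for the first inner chain
            coords = template.copy()
            coords[:, 2] += 3.0 * inner_seen  # stack extra inner chains along z
            inner_seen += 1
        elif ls.location == "inter_protomer":
            coords = _place_inter(template, protein_by_chain, ("A", "B"), ls.d0, s_hi)
        else:
            # aim successive peripheral rays at protomer centres (with a small
            # stagger once each centre is used) so they stay single-protomer
            base_angle = protomer_angles[peripheral_seen % len(protomer_angles)]
            stagger = 14.0 * (peripheral_seen // len(protomer_angles))
            peripheral_seen += 1
            phi = np.deg2rad(base_angle + stagger)
            u = np.array([np.cos(phi), np.sin(phi), 0.0])
            coords = _place_chain(template, u, protein_tree, ls.d0, ls.tracking, s_hi)
        if ls.jitter > 0:
            coords = coords + rng.normal(0.0, ls.jitter, size=coords.shape)
        resnum = 201 + idx
        for name, pos in zip(names, coords):
            atoms.append(AtomRecord("L", ls.effective_resname, resnum, "", name, "C",
                                    pos, is_hetero=True))
        truth_lipids.append({
            "chain": "L", "resnum": resnum, "resname": ls.effective_resname,
            "label": ls.location, "d0": ls.d0, "jitter": ls.jitter,
            "branched": branched, "surface_tracking": ls.tracking,
        })

    if spec.gas is not None:
        g = spec.gas
        comp = rng.choice(len(g.weights), size=g.n_atoms, p=np.array(g.weights))
        z = rng.normal(np.array(g.means)[comp], np.array(g.sds)[comp])
        phi = rng.uniform(0.0, 2.0 * np.pi, size=g.n_atoms)
        r_out = lateral_max + 1.5
        for k in range(g.n_atoms):
            pos = np.array([r_out * np.cos(phi[k]), r_out * np.sin(phi[k]), z[k]])
            atoms.append(AtomRecord("G", g.element.upper(), k + 1, "",
                                    g.element.upper(), g.element.upper(), pos,
                                    is_hetero=True))

    z_lo, z_hi = spec.boundaries
    truth = {
        "seed": spec.seed,
        "trimer": spec.trimer,
        "protomer_radius": radius,
        "frame": {"normal": [0.0, 0.0, 1.0], "z_origin": 0.0,
                  "z_lower": float(z_lo), "z_upper": float(z_hi)},
        "helix_ranges": [list(r) for r in assembly.helices],
        "lipids": truth_lipids,
        "gas": asdict(spec.gas) if spec.gas is not None else None,
    }
    structure = Structure(f"SYN{spec.seed}", AtomSet(atoms), helices=assembly.helices)
    return structure, truth


def _solve_trimer_radius(base_protein: np.ndarray, inner: LipidSpec | None) -> float:
    """Choose the protomer ring radius; with an inner lipid, solve it so the
    on-axis chain's nearest approach to each protomer equals that lipid's d0."""
    if inner is None:
        return 17.0
    _, template = _chain_template(inner.n_carbons, branched=False, straight=True)

    tree = cKDTree(base_protein)

    def f(radius: float) -> float:
        return _min_dist(template - np.array([radius, 0.0, 0.0]), tree)

    return _outermost_crossing(f, inner.d0, s_hi=45.0, s_lo=5.0)


def write_fixture(structure: Structure, path: str | Path, truth: dict | None = None) -> Path:
    """Write a scene as PDB (+ sidecar ``<stem>.truth.json`` when truth given)."""
    path = Path(path)
    write_pdb(structure, path)
    if truth is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return path
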