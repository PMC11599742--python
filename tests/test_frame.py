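"""Superposition, membrane-frame assignment, helical RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipshell import MembraneFrame, assign_frame, helical_rmsd, pair_backbone_retinal
from lipshell.errors import EmptyCorrespondence, InsufficientData, UnderdeterminedSuperposition
from lipshell.frame import principal_axis
from lipshell.geometry import RigidTransform, kabsch, quaternion_superpose, random_rotation
from lipshell.synth import LipidSpec, SceneSpec, build_scene


def random_cloud(rng, n=20):
    return rng.normal(scale=5.0, size=(n, 3))


def test_self_superposition_is_identity():
    rng = np.random.default_rng(0)
    pts = random_cloud(rng)
    transform, value = kabsch(pts, pts)
    assert value == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(transform.translation, 0.0, atol=1e-12)


def test_known_transform_is_recovered():
    rng = np.random.default_rng(1)
    pts = random_cloud(rng)
    rot = random_rotation(rng)
    trans = np.array([4.0, -2.0, 9.0])
    moved = pts @ rot.T + trans
    transform, value = kabsch(moved, pts)
    assert value < 1e-9
    np.testing.assert_allclose(transform.rotation, rot, atol=1e-9)
    np.testing.assert_allclose(transform.translation, trans, atol=1e-9)
    assert transform.is_proper()


def test_underdetermined_inputs_raise():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(UnderdeterminedSuperposition):
        kabsch(line, line)
    two = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    with pytest.raises(UnderdeterminedSuperposition):
        kabsch(two, two)


@settings(max_examples=30, derandomize=True)
@given(seed=st.integers(0, 100_000))
def test_rmsd_symmetric_and_rigid_invariant(seed):
    """RMSD after optimal superposition is symmetric in its arguments and
    unchanged by any rigid pre-transform of either cloud."""
    rng = np.random.default_rng(seed)
    a, b = random_cloud(rng), random_cloud(rng)
    _, forward = kabsch(a, b)
    _, backward = kabsch(b, a)
    assert forward == pytest.approx(backward, abs=1e-9)
    pre = RigidTransform(random_rotation(rng), rng.normal(size=3) * 20.0)
    _, moved = kabsch(a, pre.apply(b))
    assert moved == pytest.approx(forward, abs=1e-9)


def test_transform_inverse_round_trip():
    rng = np.random.default_rng(3)
    tr = RigidTransform(random_rotation(rng), rng.normal(size=3))
    pts = random_cloud(rng)
    np.testing.assert_allclose(tr.inverse().apply(tr.apply(pts)), pts, atol=1e-9)


# --- correspondence ------------------------------------------------------------


def test_pairing_structure_with_itself_is_complete(trimer_structure):
    ref, mob = pair_backbone_retinal(trimer_structure, trimer_structure)
    assert len(ref) == len(mob) > 0
    np.testing.assert_array_equal(ref.coords, mob.coords)
    # backbone N/CA/C/O of every protein residue plus retinal carbons
    names = {a.atom_name for a in ref}
    assert {"N", "CA", "C", "O"} <= names


def test_unshared_residues_are_excluded(monomer_scene, trimer_structure):
    _, mono, _ = monomer_scene
    ref, mob = pair_backbone_retinal(trimer_structure, mono)
    shared_nums = {a.residue_number for a in ref if not a.is_hetero}
    mono_nums = {a.residue_number for a in mono.atoms if not a.is_hetero}
    assert shared_nums <= mono_nums


def test_disjoint_numbering_raises_empty_correspondence(monomer_scene):
    from dataclasses import replace

    from lipshell.model import AtomSet, Structure
    _, mono, _ = monomer_scene
    shifted = Structure("shifted", AtomSet(
        replace(a, residue_number=a.residue_number + 5000)
        for a in mono.atoms if not a.is_hetero))
    with pytest.raises(EmptyCorrespondence):
        pair_backbone_retinal(mono, shifted)


# --- helical RMSD ---------------------------------------------------------------


def test_helical_rmsd_of_structure_with_itself_is_zero(trimer_structure):
    assert helical_rmsd(trimer_structure, trimer_structure) == pytest.approx(0.0, abs=1e-12)


def test_displaced_helix_closed_form():
    """One of 7 equal helices displaced by exactly 2 Å, frame frozen to identity:
    RMSD = 2/sqrt(7)."""
    from dataclasses import replace

    from lipshell.model import AtomSet, Structure
    spec = SceneSpec(seed=2, trimer=False)
    st, _ = build_scene(spec)
    shift = np.array([2.0, 0.0, 0.0])
    moved = Structure("moved", AtomSet(
        replace(a, position=a.position + shift) if 1 <= a.residue_number <= 99 else a
        for a in st.atoms), helices=st.helices)
    value = helical_rmsd(st, moved, superpose=False)
    assert value == pytest.approx(2.0 / np.sqrt(7.0), abs=1e-9)


def test_helical_rmsd_requires_shared_helices(trimer_structure):
    with pytest.raises(EmptyCorrespondence):
        helical_rmsd(trimer_structure, trimer_structure, helix_ranges=[("Z", 1, 10)])


# --- membrane frame --------------------------------------------------------------


def test_supplied_boundaries_fix_origin_at_midpoint(trimer_structure):
    frame = assign_frame(trimer_structure, boundaries=(-15.0, 15.0))
    assert frame.thickness == pytest.approx(30.0)
    assert frame.z_lower == pytest.approx(-15.0)
    assert frame.z_upper == pytest.approx(15.0)
    # bundle axis is z by construction
    assert abs(frame.normal @ np.array([0.0, 0.0, 1.0])) == pytest.approx(1.0, abs=1e-6)


def test_asymmetric_boundaries_are_recentred(trimer_structure):
    frame = assign_frame(trimer_structure, boundaries=(-10.0, 20.0))
    assert frame.z_origin == pytest.approx(5.0)
    assert frame.z_lower == pytest.approx(-15.0)
    assert frame.z_upper == pytest.approx(15.0)


def test_estimated_boundaries_match_planted_belt(trimer_structure, trimer_truth):
    """The slab estimator recovers the generator's hydrophobic belt within 2 Å."""
    frame = assign_frame(trimer_structure, estimate=True)
    lo = frame.z_origin + frame.z_lower
    hi = frame.z_origin + frame.z_upper
    assert lo == pytest.approx(trimer_truth["frame"]["z_lower"], abs=2.0)
    assert hi == pytest.approx(trimer_truth["frame"]["z_upper"], abs=2.0)


def test_estimation_needs_enough_residues():
    spec = SceneSpec(seed=9, trimer=False, n_helices=2, helix_length=10)
    st, _ = build_scene(spec)
    with pytest.raises(InsufficientData):
        assign_frame(st, estimate=True)


def test_frame_transfer_preserves_depths(trimer_structure, flat_frame):
    """Depths are invariant when structure and frame are co-transformed."""
    rng = np.random.default_rng(4)
    tr = RigidTransform(random_rotation(rng), rng.normal(size=3) * 30.0)
    moved = trimer_structure.transformed(tr)
    moved_frame = flat_frame.transformed(tr)
    d0 = flat_frame.depth(trimer_structure.atoms.coords)
    d1 = moved_frame.depth(moved.atoms.coords)
    np.testing.assert_allclose(d0, d1, atol=1e-6)


def test_principal_axis_of_z_rod():
    rng = np.random.default_rng(8)
    rod = np.column_stack([rng.normal(scale=0.5, size=400),
                           rng.normal(scale=0.5, size=400),
                           rng.uniform(-20, 20, size=400)])
    axis = principal_axis(rod)
    assert abs(axis[2]) > 0.999


def test_frame_invariants_enforced():
    with pytest.raises(ValueError):
        MembraneFrame(np.array([0.0, 0.0, 2.0]), 0.0, -15.0, 15.0)
    with pytest.raises(ValueError):
        MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0, 5.0, 15.0)
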