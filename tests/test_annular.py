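"""Annular shell extraction, surface distances, location labels."""

import numpy as np
import pytest

from lipshell import classify_location, extract_shell, nearest_surface_distances, partition
from lipshell.annular import DistanceSummary, _pair_distance
from lipshell.errors import EmptyInput, UnknownChain
from lipshell.geometry import RigidTransform, random_rotation
from lipshell.model import AtomRecord, AtomSet
from lipshell.synth import LipidSpec, SceneSpec, build_scene


def atom(name, element, pos, resname="OLA", resnum=1, chain="L", het=True):
    return AtomRecord(chain, resname, resnum, "", name, element, np.asarray(pos, float),
                      is_hetero=het)


def test_single_pair_distance():
    lipid = AtomSet([atom("C1", "C", [0, 0, 4.0])])
    protein = AtomSet([atom("CA", "C", [0, 0, 0], resname="LEU", chain="A", het=False)])
    s = nearest_surface_distances(lipid, protein)
    assert s.n_atoms == 1
    np.testing.assert_allclose(s.per_atom, [4.0])
    assert s.mean == pytest.approx(4.0) and s.sd == 0.0


def test_hydrogens_are_excluded():
    lipid = AtomSet([atom("C1", "C", [0, 0, 4.0]), atom("H1", "H", [0, 0, 1.0])])
    protein = AtomSet([atom("CA", "C", [0, 0, 0], chain="A", het=False)])
    s = nearest_surface_distances(lipid, protein)
    assert s.n_atoms == 1


def test_apolar_variant_shrinks_target_set():
    lipid = AtomSet([atom("C1", "C", [0, 0, 4.0])])
    protein = AtomSet([atom("N", "N", [0, 0, 1.0], chain="A", het=False),
                       atom("CA", "C", [0, 0, 0], chain="A", het=False)])
    all_atoms = nearest_surface_distances(lipid, protein)
    apolar = nearest_surface_distances(lipid, protein, apolar_only=True)
    assert all_atoms.mean == pytest.approx(3.0)
    assert apolar.mean == pytest.approx(4.0)


def test_empty_sets_raise():
    protein = AtomSet([atom("CA", "C", [0, 0, 0], chain="A", het=False)])
    with pytest.raises(EmptyInput):
        nearest_surface_distances(AtomSet(), protein)


def test_summary_statistics_recompute(trimer_structure, trimer_partition):
    s = nearest_surface_distances(trimer_partition.lipid, trimer_partition.protein)
    assert s.n_atoms == len(s.per_atom)
    assert s.mean == pytest.approx(float(np.mean(s.per_atom)), abs=1e-12)
    assert s.sd == pytest.approx(float(np.std(s.per_atom, ddof=1)), abs=1e-12)
    assert np.all(s.per_atom > 0)
    pop = nearest_surface_distances(trimer_partition.lipid, trimer_partition.protein,
                                    population_sd=True)
    assert pop.sd == pytest.approx(float(np.std(s.per_atom, ddof=0)), abs=1e-12)


def test_tree_path_bit_equal_to_brute_force(trimer_partition):
    """The k-d-tree nearest-distance path reproduces the exhaustive O(N*M)
    pairwise minimum bit-for-bit."""
    lipid = trimer_partition.lipid.heavy().coords
    protein = trimer_partition.protein.heavy().coords
    fast = _pair_distance(lipid, protein)
    diff = lipid[:, None, :] - protein[None, :, :]
    brute = np.sqrt(np.sum(diff * diff, axis=2)).min(axis=1)
    assert np.array_equal(fast, brute)


# --- shell ------------------------------------------------------------------------


def planted_scene(d0):
    spec = SceneSpec(seed=21, trimer=False, lipids=(LipidSpec(location="peripheral", d0=d0),))
    return build_scene(spec)[0]


def test_lipid_planted_inside_cutoff_is_member():
    st = planted_scene(4.0)
    shell = extract_shell(st, ["A"], cutoff=5.0)
    assert len(shell.members) == 1
    assert shell.members[0].min_distance == pytest.approx(4.0, abs=1e-9)


def test_lipid_planted_outside_cutoff_is_excluded():
    st = planted_scene(6.0)
    shell = extract_shell(st, ["A"], cutoff=5.0)
    assert len(shell.members) == 0


def test_boundary_distance_is_inclusive():
    st = planted_scene(5.0)
    shell = extract_shell(st, ["A"], cutoff=5.0)
    assert len(shell.members) == 1


def test_shell_monotone_in_cutoff(trimer_structure):
    inner = extract_shell(trimer_structure, ["A", "B", "C"], cutoff=5.0)
    outer = extract_shell(trimer_structure, ["A", "B", "C"], cutoff=7.0)
    assert set(inner.residue_keys()) <= set(outer.residue_keys())
    assert all(m.min_distance <= 5.0 for m in inner.members)
    mins = [m.min_distance for m in inner.members]
    assert mins == sorted(mins)


def test_shell_invariant_under_rigid_motion(trimer_structure):
    rng = np.random.default_rng(17)
    tr = RigidTransform(random_rotation(rng), rng.normal(size=3) * 25.0)
    moved = trimer_structure.transformed(tr)
    a = extract_shell(trimer_structure, ["A"], cutoff=5.0)
    b = extract_shell(moved, ["A"], cutoff=5.0)
    assert a.residue_keys() == b.residue_keys()
    np.testing.assert_allclose([m.min_distance for m in a.members],
                               [m.min_distance for m in b.members], atol=1e-9)


def test_unknown_chain_raises(trimer_structure):
    with pytest.raises(UnknownChain):
        extract_shell(trimer_structure, ["Q"])


# --- location labels ---------------------------------------------------------------


def test_planted_labels_are_recovered(trimer_structure, trimer_truth, flat_frame,
                                      trimer_partition):
    residues = trimer_partition.lipid.by_residue()
    for record in trimer_truth["lipids"]:
        key = next(k for k in residues if k.residue_number == record["resnum"])
        loc = classify_location(residues[key], trimer_structure, flat_frame,
                                part=trimer_partition)
        assert loc.label == record["label"], record


def test_inner_compartment_touches_all_protomers(trimer_structure, trimer_truth,
                                                 flat_frame, trimer_partition):
    residues = trimer_partition.lipid.by_residue()
    inner = next(r for r in trimer_truth["lipids"] if r["label"] == "inner_compartment")
    key = next(k for k in residues if k.residue_number == inner["resnum"])
    loc = classify_location(residues[key], trimer_structure, flat_frame,
                            part=trimer_partition)
    assert loc.contacting_protomers == frozenset({"A", "B", "C"})
    assert loc.axis_distance < 1.0  # centroid essentially on the three-fold axis


def test_monomer_defaults_to_peripheral_with_warning(monomer_scene, flat_frame):
    _, st, _ = monomer_scene
    part = partition(st)
    residue = next(iter(part.lipid.by_residue().values()))
    with pytest.warns(UserWarning):
        loc = classify_location(residue, st, flat_frame, part=part)
    assert loc.label == "peripheral"


def test_distance_summary_from_distances_roundtrip():
    d = np.array([1.0, 2.0, 3.0, 4.0])
    s = DistanceSummary.from_distances(d)
    assert s.mean == pytest.approx(2.5)
    assert s.sd == pytest.approx(float(np.std(d, ddof=1)))
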