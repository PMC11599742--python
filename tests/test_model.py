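"""Structure I/O, partitioning, selection grammar, assembly expansion."""

import numpy as np
import pytest

from lipshell import (
    expand_assembly,
    kabsch_superpose,
    partition,
    read_structure,
    select,
)
from lipshell.errors import AssemblyUnavailable, FormatError, SelectionError, UnknownChain
from lipshell.model import (
    AtomRecord,
    AtomSet,
    Structure,
    c3_operators,
    expand_name_ranges,
    parse_selection,
    write_mmcif,
    write_pdb,
)

MINIMAL_PDB = (
    "ATOM      1  CA  LEU A   1      11.000  10.000  10.000  1.00 10.00           C\n"
    "END\n"
)


def test_minimal_single_atom_pdb(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(MINIMAL_PDB)
    st = read_structure(p)
    assert len(st) == 1
    atom = st.atoms[0]
    assert (atom.chain_id, atom.residue_name, atom.atom_name) == ("A", "LEU", "CA")
    np.testing.assert_allclose(atom.position, [11.0, 10.0, 10.0])


def test_unparsable_file_raises_format_error(tmp_path):
    p = tmp_path / "junk.cif"
    p.write_text("this is not a structure\n")
    with pytest.raises(FormatError):
        read_structure(p, format="mmCIF")


def test_missing_file_raises(tmp_path):
    with pytest.raises(FormatError):
        read_structure(tmp_path / "absent.pdb")


def test_altloc_keeps_highest_occupancy(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(
        "ATOM      1  CA ALEU A   1      11.000  10.000  10.000  0.40 10.00           C\n"
        "ATOM      2  CA BLEU A   1      12.000  10.000  10.000  0.60 10.00           C\n"
        "END\n")
    st = read_structure(p)
    assert len(st) == 1
    assert st.atoms[0].altloc == "B"
    assert st.atoms[0].position[0] == pytest.approx(12.0)


def test_altloc_tie_prefers_a(tmp_path):
    p = tmp_path / "tie.pdb"
    p.write_text(
        "ATOM      1  CA BLEU A   1      12.000  10.000  10.000  0.50 10.00           C\n"
        "ATOM      2  CA ALEU A   1      11.000  10.000  10.000  0.50 10.00           C\n"
        "END\n")
    st = read_structure(p)
    assert st.atoms[0].altloc == "A"


def test_format_parity_pdb_vs_mmcif(tmp_path, trimer_structure):
    """The same content written as PDB and as mmCIF parses to the same partition."""
    pdb = tmp_path / "scene.pdb"
    cif = tmp_path / "scene.cif"
    write_pdb(trimer_structure, pdb)
    write_mmcif(trimer_structure, cif)
    st_pdb = read_structure(pdb)
    st_cif = read_structure(cif)
    assert len(st_pdb) == len(st_cif) == len(trimer_structure)
    assert partition(st_pdb).residue_counts() == partition(st_cif).residue_counts()
    np.testing.assert_allclose(st_pdb.atoms.coords, st_cif.atoms.coords, atol=1.1e-3)


def test_round_trip_preserves_names_and_coordinates(tmp_path, trimer_structure):
    p = tmp_path / "rt.pdb"
    write_pdb(trimer_structure, p)
    st = read_structure(p)
    assert len(st) == len(trimer_structure)
    assert [a.atom_name for a in st.atoms] == [a.atom_name for a in trimer_structure.atoms]
    np.testing.assert_allclose(st.atoms.coords, trimer_structure.atoms.coords, atol=5.1e-4)


def test_partition_is_disjoint_cover(trimer_structure, trimer_partition):
    sets = trimer_partition.sets()
    total = sum(len(s) for s in sets.values())
    assert total == len(trimer_structure)
    keys = [frozenset(id(a) for a in s) for s in sets.values()]
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            assert not keys[i] & keys[j]


def test_partition_buckets(trimer_partition, trimer_truth):
    assert len(trimer_partition.retinal.by_residue()) == 3  # one per protomer
    assert len(trimer_partition.lipid.by_residue()) == len(trimer_truth["lipids"])
    assert len(trimer_partition.protein) > 0
    # noble-gas atoms are not lipids
    assert all(k.residue_name != "KR" for k in trimer_partition.lipid.by_residue())


def test_glycerol_is_not_a_lipid():
    atoms = AtomSet([AtomRecord("A", "GOL", 1, "", "C1", "C", np.zeros(3), is_hetero=True)])
    part = partition(Structure("gol", atoms))
    assert len(part.lipid) == 0 and len(part.other_het) == 1


# --- selection grammar -------------------------------------------------------


def test_printed_selection_expands_to_32_names():
    names = expand_name_ranges("O2+C2+C3+C12-C21+C41-C45+C47-C60")
    assert len(names) == 32
    assert names[0] == "O2" and "C21" in names and "C60" in names


def test_simple_range_arithmetic():
    assert expand_name_ranges("C12-C21") == [f"C{i}" for i in range(12, 22)]


@pytest.mark.parametrize("bad", ["chain", "resnum twelve", "name ", "chain A and",
                                 "bogus A", "chain A or chain B"])
def test_grammar_violations_raise_parse_error(bad):
    with pytest.raises(SelectionError):
        parse_selection(bad)


def test_selection_on_scene(trimer_structure, trimer_truth):
    lip = trimer_truth["lipids"][0]
    expr = f"chain {lip['chain']} and resname {lip['resname']} and resnum {lip['resnum']}"
    atoms = select(trimer_structure, expr)
    assert len(atoms) > 0
    assert {a.residue_number for a in atoms} == {lip["resnum"]}


def test_empty_selection_is_legal_but_flagged(trimer_structure):
    with pytest.warns(UserWarning):
        result = select(trimer_structure, "resname XXX")
    assert len(result) == 0


def test_selection_is_monotone_under_conjunction(trimer_structure):
    base = select(trimer_structure, "chain A")
    narrowed = select(trimer_structure, "chain A and name CA")
    assert len(narrowed) <= len(base)
    base_ids = {id(a) for a in base}
    assert all(id(a) in base_ids for a in narrowed)


# --- assembly expansion ------------------------------------------------------


def _monomer_protein(monomer_scene):
    _, structure, _ = monomer_scene
    return structure


def test_c3_expansion_triples_atoms(monomer_scene):
    st = _monomer_protein(monomer_scene)
    expanded = expand_assembly(st, ops=c3_operators())
    assert len(expanded) == 3 * len(st)
    assert len(expanded.chains()) == 3 * len(st.chains())


def test_identity_op_only_leaves_structure_unchanged(monomer_scene):
    st = _monomer_protein(monomer_scene)
    from lipshell.geometry import RigidTransform
    expanded = expand_assembly(st, ops=[RigidTransform.identity()])
    assert len(expanded) == len(st)
    np.testing.assert_array_equal(expanded.atoms.coords, st.atoms.coords)


def test_no_operators_raises(monomer_scene):
    st = _monomer_protein(monomer_scene)
    with pytest.raises(AssemblyUnavailable):
        expand_assembly(st)


def test_symmetry_mates_superpose_exactly(trimer_structure):
    """Protomer-vs-protomer Cα RMSD after superposition vanishes for a C3 trimer."""
    part = partition(trimer_structure)
    ca = part.protein.filter(lambda a: a.atom_name == "CA")
    chain_a = ca.filter(lambda a: a.chain_id == "A")
    chain_b = ca.filter(lambda a: a.chain_id == "B")
    assert len(chain_a) == len(chain_b) > 0
    _, value = kabsch_superpose(chain_a, chain_b)
    assert value < 1e-6
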