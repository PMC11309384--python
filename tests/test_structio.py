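"""Structure I/O: mmCIF parsing, assemblies, polymer split, PDB writing."""

import numpy as np
import pytest

from ribannot import fixtures, structio
from ribannot.model import AssemblyDef, Atom, Chain, Residue, ResidueKind, Structure


def test_fixture_duplex_mmcif_roundtrip(duplex8, tmp_path):
    st, _ = duplex8
    path = tmp_path / "dup.cif"
    fixtures.write_mmcif(st, path)
    rd = structio.read_mmcif(path)
    assert len(rd.chains) == 2
    assert sum(len(c.polymer_residues()) for c in rd.chains) == 16
    for orig, back in zip(st.chains, rd.chains):
        assert [r.comp_id for r in orig.residues] == \
            [r.comp_id for r in back.residues]
        assert [r.label_seq for r in orig.residues] == \
            [r.label_seq for r in back.residues]


def test_empty_file_is_a_parse_error(tmp_path):
    path = tmp_path / "empty.cif"
    path.write_text("")
    with pytest.raises(structio.ParseError):
        structio.read_mmcif(path)


def test_missing_atom_site_is_a_parse_error(tmp_path):
    path = tmp_path / "noatoms.cif"
    path.write_text("data_x\n_entry.id X\n")
    with pytest.raises(structio.ParseError, match="atom_site"):
        structio.read_mmcif(path)


def test_u2_like_census_and_assemblies(u2_cif):
    st = structio.read_mmcif(u2_cif)
    assert len(st.chains) == 6
    assert [a.assembly_id for a in st.assemblies] == ["1", "2"]
    assert sorted(st.assembly("2").referenced_chains()) == ["C", "D", "R"]
    asm2 = structio.build_assembly(st, "2")
    assert sorted(c.chain_id for c in asm2.chains) == ["C", "D", "R"]


def test_unknown_assembly_id_lists_available(u2_cif):
    st = structio.read_mmcif(u2_cif)
    with pytest.raises(KeyError, match="available.*1.*2"):
        st.assembly("9")


def test_identity_assembly_is_bit_identical(duplex8):
    st, _ = duplex8
    asm = structio.build_assembly(st, "1")
    for orig, new in zip(st.chains, asm.chains):
        for ro, rn in zip(orig.residues, new.residues):
            for ao, an in zip(ro.atoms, rn.atoms):
                assert np.array_equal(ao.coords, an.coords)


def test_rotation_assembly_applies_transform(hairpin):
    st, _ = hairpin
    theta = 0.7
    op = np.eye(4)
    op[:3, :3] = [[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    op[:3, 3] = [1.0, -2.0, 3.0]
    st2 = Structure(st.entry_id, st.chains,
                    [AssemblyDef("rot", [(("A",), op)])])
    asm = structio.build_assembly(st2, "rot")
    for ro, rn in zip(st.chains[0].residues, asm.chains[0].residues):
        for ao, an in zip(ro.atoms, rn.atoms):
            expected = op[:3, :3] @ ao.coords + op[:3, 3]
            np.testing.assert_allclose(an.coords, expected, atol=1e-9)


def test_rigid_transform_preserves_distances(hairpin):
    st, _ = hairpin
    theta = 1.1
    op = np.eye(4)
    op[:3, :3] = [[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                  [-np.sin(theta), 0, np.cos(theta)]]
    op[:3, 3] = [10.0, 5.0, -3.0]
    st2 = Structure(st.entry_id, st.chains,
                    [AssemblyDef("rot", [(("A",), op)])])
    asm = structio.build_assembly(st2, "rot")
    before = np.array([a.coords for r in st.chains[0].residues
                       for a in r.atoms])
    after = np.array([a.coords for r in asm.chains[0].residues
                      for a in r.atoms])
    idx = np.arange(0, len(before) - 5, 7)
    d0 = np.linalg.norm(before[idx] - before[idx + 5], axis=1)
    d1 = np.linalg.norm(after[idx] - after[idx + 5], axis=1)
    np.testing.assert_allclose(d0, d1, atol=1e-6)


def test_improper_transform_rejected():
    op = np.eye(4)
    op[0, 0] = -1.0  # reflection
    asm = AssemblyDef("1", [(("A",), op)])
    with pytest.raises(ValueError, match="proper rotation"):
        asm.validate()


def test_split_polymer_nonpolymer(hairpin_mg):
    st, _ = hairpin_mg
    polymer, nonpoly = structio.split_polymer_nonpolymer(st.chains[0])
    assert len(polymer.residues) == 16
    assert all(r.is_polymer for r in polymer.residues)
    assert [r.comp_id for r in nonpoly] == ["MG"]


def test_all_water_chain_splits_to_empty_polymer():
    waters = [Residue("HOH", i, ResidueKind.WATER,
                      [Atom("O", "O", np.array([float(i), 0.0, 0.0]))])
              for i in range(1, 4)]
    polymer, nonpoly = structio.split_polymer_nonpolymer(Chain("W", waters))
    assert polymer.residues == []
    assert all(r.kind is ResidueKind.WATER for r in nonpoly)


def test_pdb_roundtrip_preserves_inventory_and_coords(hairpin_mg, tmp_path):
    st, _ = hairpin_mg
    path = tmp_path / "out.pdb"
    structio.write_pdb(st, path)
    rd = structio.read_pdb(path)
    inv0 = [(r.comp_id, r.is_polymer, a.name)
            for c in st.chains for r in c.residues for a in r.atoms]
    inv1 = [(r.comp_id, r.is_polymer, a.name)
            for c in rd.chains for r in c.residues for a in r.atoms]
    assert inv0 == inv1
    c0 = np.array([a.coords for c in st.chains for r in c.residues
                   for a in r.atoms])
    c1 = np.array([a.coords for c in rd.chains for r in c.residues
                   for a in r.atoms])
    assert np.abs(c0 - c1).max() < 1e-3


def test_pdb_refuses_too_many_atoms():
    big = Chain("A", [Residue(
        "G", 1, ResidueKind.RIBONUCLEOTIDE,
        [Atom(f"C{i}", "C", np.zeros(3)) for i in range(100_000)],
        label_seq=1)])
    st = Structure("big", [big])
    with pytest.raises(structio.StructureTooLargeError):
        structio.write_pdb(st, "/dev/null")


def test_pdb_refuses_too_many_chains():
    chains = [Chain(f"c{i}", [Residue(
        "G", 1, ResidueKind.RIBONUCLEOTIDE,
        [Atom("P", "P", np.zeros(3))], label_seq=1)]) for i in range(63)]
    st = Structure("wide", chains)
    with pytest.raises(structio.StructureTooLargeError):
        structio.write_pdb(st, "/dev/null")


def test_pdb_chain_renaming_reported(tmp_path):
    res = Residue("G", 1, ResidueKind.RIBONUCLEOTIDE,
                  [Atom("P", "P", np.zeros(3))], label_seq=1)
    st = Structure("ren", [Chain("AB", [res]), Chain("A", [res])])
    mapping = structio.write_pdb(st, tmp_path / "ren.pdb")
    assert mapping["A"] == "A"
    assert len(mapping["AB"]) == 1
    assert mapping["AB"] != "A"


def test_species_taxids_parsed(u2_cif):
    st = structio.read_mmcif(u2_cif)
    assert st.species_taxids.get("Q") == "9606"
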