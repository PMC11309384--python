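"""Contact detection, binding residues and interaction extraction."""

import numpy as np
import pytest

from ribannot import fixtures
from ribannot.chaintypes import ComponentInfo, LigandClass
from ribannot.config import PipelineConfig
from ribannot.interactions import (
    AtomRef,
    binding_residues,
    extract_interactions,
    find_contacts,
    vdw_radius,
)
from ribannot.model import Atom, Chain, Residue, ResidueKind
from ribannot.refdata import vdw_radius as table_radius


def brute_force_contacts(rna, ligand_atoms, margin=0.5):
    """O(N^2) oracle for the vdW + margin contact rule."""
    out = set()
    for ridx, res in enumerate(rna.residues):
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            for ref, b in ligand_atoms:
                if b.is_hydrogen:
                    continue
                d = float(np.linalg.norm(a.coords - b.coords))
                if d <= table_radius(a.element) + table_radius(b.element) \
                        + margin:
                    out.add((ridx, a.name, ref.atom_name))
    return out


def test_vdw_radius_values():
    assert vdw_radius("C") == 1.70
    assert vdw_radius("N") == 1.55
    assert vdw_radius("XX") == 1.80  # unknown element default


def _two_atom_setup(distance):
    rna = Chain("A", [Residue("G", 1, ResidueKind.RIBONUCLEOTIDE,
                              [Atom("C8", "C", np.zeros(3))], label_seq=1)])
    lig = [(AtomRef("L", 0, "LIG", 1, "", "C1", "C"),
            Atom("C1", "C", np.array([distance, 0.0, 0.0])))]
    return rna, lig


@pytest.mark.parametrize("distance,expected", [
    (3.80, 1),   # threshold is 1.70 + 1.70 + 0.5 = 3.90
    (3.90, 1),
    (3.95, 0),
])
def test_carbon_carbon_threshold(distance, expected):
    rna, lig = _two_atom_setup(distance)
    assert len(find_contacts(rna, lig)) == expected


def test_hydrogens_never_contact():
    rna = Chain("A", [Residue("G", 1, ResidueKind.RIBONUCLEOTIDE,
                              [Atom("H1", "H", np.zeros(3),
                                    is_hydrogen=True)], label_seq=1)])
    lig = [(AtomRef("L", 0, "LIG", 1, "", "C1", "C"),
            Atom("C1", "C", np.array([1.0, 0.0, 0.0])))]
    assert find_contacts(rna, lig) == []


@pytest.mark.parametrize("seed", range(20))
def test_grid_equals_brute_force(seed):
    chain, ligand = fixtures.make_random_cloud(seed, n_rna_atoms=150,
                                               n_ligand_atoms=50)
    got = {(c.rna_atom.residue_index, c.rna_atom.atom_name,
            c.ligand_atom.atom_name)
           for c in find_contacts(chain, ligand)}
    assert got == brute_force_contacts(chain, ligand)


def test_contact_symmetry(hairpin_mg):
    st, _ = hairpin_mg
    from ribannot.structio import split_polymer_nonpolymer
    polymer, nonpoly = split_polymer_nonpolymer(st.chains[0])
    mg = nonpoly[0]
    lig = [(AtomRef("A", 0, "MG", mg.auth_seq, "", a.name, a.element), a)
           for a in mg.atoms]
    forward = find_contacts(polymer, lig)
    # swap roles: put the RNA atoms on the ligand side
    rev_chain = Chain("L", [Residue("MG", mg.auth_seq, ResidueKind.OTHER,
                                    mg.atoms, label_seq=1)])
    rev_lig = [(AtomRef("A", i, r.comp_id, r.auth_seq, "", a.name, a.element),
                a)
               for i, r in enumerate(polymer.residues) for a in r.atoms]
    backward = find_contacts(rev_chain, rev_lig)
    fwd = {(c.rna_atom.atom_name, c.ligand_atom.atom_name,
            round(c.distance, 6)) for c in forward}
    bwd = {(c.ligand_atom.atom_name, c.rna_atom.atom_name,
            round(c.distance, 6)) for c in backward}
    assert fwd == bwd


@pytest.mark.parametrize("seed", range(5))
def test_margin_monotonicity(seed):
    chain, ligand = fixtures.make_random_cloud(seed, 100, 40)
    small = {(c.rna_atom.atom_name, c.ligand_atom.atom_name)
             for c in find_contacts(chain, ligand, margin=0.5)}
    large = {(c.rna_atom.atom_name, c.ligand_atom.atom_name)
             for c in find_contacts(chain, ligand, margin=0.6)}
    assert small <= large


def _contact(ridx, n):
    """n synthetic contacts on residue ridx."""
    return [type("C", (), {"rna_atom": AtomRef("A", ridx, "G", ridx + 1, "",
                                               f"X{k}", "C"),
                           "ligand_atom": None, "distance": 3.0})()
            for k in range(n)]


def test_binding_residue_needs_two_contacts():
    assert binding_residues(_contact(0, 1)) == []
    res = binding_residues(_contact(0, 2))
    assert [r.residue_index for r in res] == [0]


def test_monoatomic_ligand_two_atom_pairs_count(hairpin):
    # one Mg close to O2' and O3' of a single residue: two atom pairs
    st, _ = hairpin
    mg_st = fixtures.place_ligand(
        st, [("A", 3, "O2'"), ("A", 3, "O3'")], 2.1,
        ComponentInfo("MG", {"Mg": 1}))
    from ribannot.structio import split_polymer_nonpolymer
    polymer, nonpoly = split_polymer_nonpolymer(mg_st.chains[0])
    mg = nonpoly[0]
    lig = [(AtomRef("A", 0, "MG", mg.auth_seq, "", a.name, a.element), a)
           for a in mg.atoms]
    res = binding_residues(find_contacts(polymer, lig))
    assert 2 in {r.residue_index for r in res}  # residue 3 (0-based index 2)


def test_extraction_site_and_exclusions(hairpin_mg):
    st, _ = hairpin_mg
    records = extract_interactions(st, "A", assembly_id="1")
    assert len(records) == 1
    rec = records[0]
    assert rec.ligand.klass is LigandClass.METAL_ION
    assert [r.auth_seq for r in rec.site.residues] == [4, 5]
    assert rec.site.residue_tokens() == ["C4", "G5"]


def test_far_ligand_gives_no_record(hairpin):
    st, _ = hairpin
    far = fixtures.place_ligand(st, [("A", 4, "O2")], 15.0,
                                ComponentInfo("MG", {"Mg": 1}))
    assert extract_interactions(far, "A", assembly_id="1") == []


def test_water_never_a_ligand(hairpin):
    st, _ = hairpin
    watered = fixtures.place_ligand(st, [("A", 4, "O2")], 2.5,
                                    ComponentInfo("HOH", {"O": 1, "H": 2}))
    records = extract_interactions(watered, "A", assembly_id="1")
    assert all(r.ligand.ligand_id != "HOH" for r in records)


def test_duplex_partner_is_rna_ligand():
    st, truth = fixtures.make_duplex(fixtures.HelixSpec("GGGGGCCCCC"))
    records = extract_interactions(st, "A", assembly_id="1")
    assert len(records) == 1
    rec = records[0]
    assert rec.ligand.klass is LigandClass.RNA_LIGAND
    assert rec.ligand.ligand_id == "B"
    # the designed paired residues are all in the binding site
    assert {r.auth_seq for r in rec.site.residues} == set(range(1, 11))


def test_no_record_references_query_chain(hairpin_mg):
    st, _ = hairpin_mg
    for rec in extract_interactions(st, "A", assembly_id="1"):
        assert not (rec.ligand.auth_seq is None
                    and rec.ligand.chain_id == "A")


def test_query_must_be_eligible(duplex8):
    st, _ = duplex8  # 8 nt chains: not entries
    with pytest.raises(ValueError, match="eligible"):
        extract_interactions(st, "A", assembly_id="1")


def test_site_min_residues_configurable(hairpin):
    st, _ = hairpin
    single = fixtures.place_ligand(st, [("A", 4, "O2")], 2.1,
                                   ComponentInfo("MG", {"Mg": 1}))
    strict = extract_interactions(single, "A", assembly_id="1")
    cfg = PipelineConfig(site_min_residues=1)
    relaxed = extract_interactions(single, "A", cfg, assembly_id="1")
    assert len(relaxed) >= len(strict)
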