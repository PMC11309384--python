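"""Mapping-table dialects, GO/EC joins, F1 similarity, dedup, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from ribannot import annotate
from ribannot.annotate import (
    GOTermSet,
    RfamHit,
    assign_rfam,
    dedupe_sequences,
    ec_from_go,
    go_f1,
    load_mapping,
    parse_cmscan_tblout,
    summarize,
    transfer_go,
)


@pytest.fixture(scope="module")
def maps(bundle):
    t = bundle["tables"]
    return {
        "rfam_pdb": load_mapping("rfam_pdb", t["rfam_pdb"]),
        "rfam2go": load_mapping("rfam2go", t["rfam2go"]),
        "rnacentral_pdb": load_mapping("rnacentral_pdb", t["rnacentral_pdb"]),
        "goa_gaf": load_mapping("goa_gaf", t["goa_gaf"]),
        "ec2go": load_mapping("ec2go", t["ec2go"]),
        "ontology": load_mapping("go_obo_edges", t["go_obo"]),
    }


def test_rfam2go_rows(tmp_path):
    f = tmp_path / "r2g.txt"
    f.write_text(
        "Rfam:RF00001 5S rRNA > GO:x ; GO:0003735\n"
        "Rfam:RF00002 x > GO:y ; GO:0005840\n"
        "Rfam:RF00003 x > GO:z ; GO:0004526\n")
    df = load_mapping("rfam2go", f)
    assert len(df) == 3
    assert set(df["rfam_acc"]) == {"RF00001", "RF00002", "RF00003"}


def test_gaf_not_qualifier_skipped(maps):
    assert "GO:0099999" not in set(maps["goa_gaf"]["go_id"])
    assert "GO:0005840" in set(maps["goa_gaf"]["go_id"])


def test_duplicate_rows_deduplicated(tmp_path):
    f = tmp_path / "dup.tsv"
    f.write_text("MG\tCHEMBL1\nMG\tCHEMBL1\n")
    assert len(load_mapping("crossref_2col", f)) == 1


def test_all_malformed_raises(tmp_path):
    f = tmp_path / "bad.txt"
    f.write_text("garbage line\nanother one\n")
    with pytest.raises(ValueError, match="malformed"):
        load_mapping("rfam2go", f)


def test_unknown_kind_rejected(tmp_path):
    with pytest.raises(ValueError, match="unknown mapping kind"):
        load_mapping("nope", tmp_path)


def test_assign_rfam_from_mapping(maps):
    hits = assign_rfam(("ft01", "A"), maps["rfam_pdb"])
    assert [h.rfam_acc for h in hits] == ["RF90001"]
    assert hits[0].source == "mapping_file"


def test_assign_rfam_evalue_ordering(tmp_path, maps):
    tbl = tmp_path / "hits.tbl"
    tbl.write_text(
        "#target accession query qacc mdl mfrom mto sfrom sto strand "
        "trunc pass gc bias score evalue inc desc\n"
        "fam2 RF00002 q - cm 1 50 1 50 + no 1 0.5 0.0 20.1 1.2 ! x\n"
        "fam1 RF00001 q - cm 1 50 1 50 + no 1 0.5 0.0 40.3 0.003 ! x\n")
    hits = assign_rfam(("none", "Z"), maps["rfam_pdb"], cmscan_tblout=tbl)
    assert [(h.rfam_acc, h.e_value) for h in hits] == \
        [("RF00001", 0.003), ("RF00002", 1.2)]
    assert all(h.source == "cm_search" for h in hits)


def test_assign_rfam_no_sources_empty(maps):
    # a chain in neither source stays unannotated (remote-homolog miss)
    assert assign_rfam(("1vc6", "B"), maps["rfam_pdb"]) == []


def test_malformed_tblout_names_line(tmp_path):
    tbl = tmp_path / "bad.tbl"
    tbl.write_text("only three fields here\n")
    with pytest.raises(ValueError, match="bad.tbl:1"):
        parse_cmscan_tblout(tbl)


def test_transfer_go_union_and_aspects(maps):
    hits = assign_rfam(("ft01", "A"), maps["rfam_pdb"])
    go = transfer_go(("ft01", "A"), hits, maps["rfam2go"],
                     maps["rnacentral_pdb"], maps["goa_gaf"],
                     maps["ontology"])
    assert go["MF"].terms == {"GO:0003735"}   # via rfam2go
    assert go["CC"].terms == {"GO:0005840"}   # via RNAcentral + GOA
    assert go["BP"].terms == set()


def test_transfer_go_no_sources_empty(maps):
    go = transfer_go(("none", "Z"), [], maps["rfam2go"],
                     maps["rnacentral_pdb"], maps["goa_gaf"])
    assert all(len(v) == 0 for v in go.values())


def test_transfer_go_same_term_once(tmp_path, maps):
    # both routes supplying the same term leaves a single copy (set)
    import pandas as pd
    r2g = pd.DataFrame([{"rfam_acc": "RF90001", "go_id": "GO:0005840"}])
    hits = [RfamHit("RF90001", 0.001, "mapping_file")]
    go = transfer_go(("ft01", "A"), hits, r2g, maps["rnacentral_pdb"],
                     maps["goa_gaf"], maps["ontology"])
    assert go["CC"].terms == {"GO:0005840"}


def test_ancestor_closure(maps):
    ts = GOTermSet({"GO:0003735"})
    closed = ts.closure(maps["ontology"])
    assert closed.terms == {"GO:0003735", "GO:0005198"}
    assert closed.closed
    # part_of edges followed too
    cc = GOTermSet({"GO:0005840"}).closure(maps["ontology"])
    assert "GO:0005737" in cc.terms


def test_ec_from_go(maps):
    assert ec_from_go({"GO:0004526"}, maps["ec2go"]) == {"3.1.26.5"}
    assert ec_from_go(set(), maps["ec2go"]) == set()
    assert ec_from_go({"GO:0003735"}, maps["ec2go"]) == set()


@pytest.mark.parametrize("a,b,expected", [
    ({"x", "y"}, {"x", "y"}, 1.0),
    ({"x"}, {"y"}, 0.0),
    ({"a", "b"}, {"b", "c"}, 0.5),
    (set(), set(), 0.0),
])
def test_go_f1_cases(a, b, expected):
    assert go_f1(a, b) == expected


@settings(deadline=None, max_examples=50)
@given(st_.sets(st_.integers(0, 20)), st_.sets(st_.integers(0, 20)))
def test_go_f1_bounds_and_symmetry(a, b):
    f = go_f1(a, b)
    assert 0.0 <= f <= 1.0
    assert f == go_f1(b, a)
    if a:
        assert go_f1(a, a) == 1.0


def test_dedupe_sequences():
    groups = dedupe_sequences({
        ("1abc", "A"): "GGGCCC",
        ("1abc", "B"): "gggccc",      # case-normalised duplicate
        ("2xyz", "A"): "GGGCCT",      # T normalised to U
        ("2xyz", "B"): "GGGCCU",
        ("3foo", "A"): "AAAA",
    })
    reps = {rep: members for rep, members in groups}
    assert reps[("1abc", "A")] == [("1abc", "A"), ("1abc", "B")]
    assert reps[("2xyz", "A")] == [("2xyz", "A"), ("2xyz", "B")]
    assert reps[("3foo", "A")] == [("3foo", "A")]


def test_summarize_is_a_partition(hairpin_mg):
    from ribannot.interactions import extract_interactions
    st, _ = hairpin_mg
    records = extract_interactions(st, "A", assembly_id="1")
    counts = summarize(records)
    assert sum(counts.values()) == len(records)
    assert counts["METAL_ION"] == 1


def test_summarize_empty():
    counts = summarize([])
    assert sum(counts.values()) == 0


def test_written_tables_roundtrip(tmp_path, hairpin_mg):
    from ribannot.interactions import extract_interactions
    st, _ = hairpin_mg
    records = extract_interactions(st, "A", assembly_id="1")
    rec = annotate.AnnotationRecord(entry_id="fmg", chain_id="A",
                                    sequence="GCGCGCUUCGGCGCGC")
    paths = annotate.write_annotation_tables(
        records, {("fmg", "A"): rec}, tmp_path)
    df = annotate.read_interactions_table(paths["interactions"])
    assert len(df) == len(records)
    assert list(df["ligand_id"]) == ["MG"]
    assert list(df["binding_residues"]) == ["C4 G5"]


def test_empty_tables_header_only(tmp_path):
    paths = annotate.write_annotation_tables([], {}, tmp_path)
    lines = open(paths["interactions"]).read().splitlines()
    assert len(lines) == 1
    assert lines[0].split("\t") == annotate.INTERACTION_COLUMNS
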