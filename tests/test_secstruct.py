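"""Base-pair detection, dot-bracket and pseudoknot removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from ribannot import fixtures, secstruct
from ribannot.secstruct import (
    BasePair,
    detect_base_pairs,
    paired_regions,
    parse_dotbracket,
    remove_pseudoknots,
    to_dotbracket,
    write_stockholm,
)


def _pairs(bp_list):
    return [(p.i, p.j, p.pair_type) for p in bp_list]


def test_duplex_detection_exact(duplex8):
    st, truth = duplex8
    assert _pairs(detect_base_pairs(st.chains)) == truth.pairs


def test_hairpin_detection_exact(hairpin):
    st, truth = hairpin
    assert _pairs(detect_base_pairs(st.chains[0])) == truth.pairs


@pytest.mark.parametrize("jitter", [0.0, 0.3])
@pytest.mark.parametrize("seed", range(5))
def test_detection_stable_under_jitter(jitter, seed):
    spec = fixtures.HelixSpec("GAGUGCAC", jitter_sd=jitter, seed=seed,
                              gu_positions=frozenset([3]))
    st, truth = fixtures.make_duplex(spec)
    assert _pairs(detect_base_pairs(st.chains)) == truth.pairs


def test_wobble_pair_detected_as_gu():
    spec = fixtures.HelixSpec("GGGGCCCC", gu_positions=frozenset([2]))
    st, truth = fixtures.make_duplex(spec)
    detected = _pairs(detect_base_pairs(st.chains))
    assert detected == truth.pairs
    assert detected[1][2] == "GU"


def test_noncanonical_apposition_unpaired(duplex8):
    st, truth = duplex8
    # swap the base identity at position 3 of chain A to A: A.G apposition
    import copy
    st2 = copy.deepcopy(st)
    st2.chains[0].residues[2].comp_id = "A"
    detected = _pairs(detect_base_pairs(st2.chains))
    assert (3, 14, "GC") not in detected
    assert all(p[0] != 3 for p in detected)


def test_single_nucleotide_chain_has_no_pairs():
    st, _ = fixtures.make_hairpin(2, 3)
    chain = st.chains[0]
    from ribannot.model import Chain
    single = Chain("S", chain.residues[:1])
    assert detect_base_pairs(single) == []


def test_dotbracket_simple_hairpin():
    ss = to_dotbracket([(1, 8), (2, 7), (3, 6)], 8)
    assert ss.dotbracket == "(((..)))"


def test_dotbracket_empty():
    assert to_dotbracket([], 5).dotbracket == "....."


def test_dotbracket_pseudoknot_layers_roundtrip():
    pairs = [(1, 10), (2, 9), (5, 14), (6, 13)]
    ss = to_dotbracket(pairs, 14)
    assert set(ss.dotbracket) <= set("()[].")
    assert "[" in ss.dotbracket
    assert parse_dotbracket(ss.dotbracket) == sorted(pairs)


def test_dotbracket_conflicting_pairs_rejected():
    with pytest.raises(ValueError, match="more than one pair"):
        to_dotbracket([(1, 5), (1, 7)], 8)


@settings(deadline=None, max_examples=50)
@given(st_.integers(0, 10_000))
def test_dotbracket_roundtrip_random(seed):
    rng = np.random.default_rng(seed)
    length = int(rng.integers(4, 40))
    positions = list(rng.permutation(np.arange(1, length + 1)))
    pairs = []
    while len(positions) >= 2:
        i, j = positions.pop(), positions.pop()
        if rng.random() < 0.6:
            pairs.append((min(i, j), max(i, j)))
    try:
        ss = to_dotbracket(pairs, length)
    except ValueError:
        return  # >4 mutually crossing layers: legitimately refused
    assert parse_dotbracket(ss.dotbracket) == sorted(pairs)


def test_paired_regions_grouping():
    regions = paired_regions([(1, 10), (2, 9), (5, 15)])
    assert {(r.start_i, r.start_j, r.length) for r in regions} == \
        {(1, 10, 2), (5, 15, 1)}


def test_pseudoknot_longest_region_wins():
    # R1 (len 2) crosses R2 (len 1): keep R1
    pairs = [(1, 10), (2, 9), (5, 15)]
    kept = remove_pseudoknots(pairs)
    assert sorted(kept) == [(1, 10), (2, 9)]


def test_pseudoknot_identity_on_nested():
    pairs = [(1, 12), (2, 11), (4, 8)]
    assert sorted(remove_pseudoknots(pairs)) == sorted(pairs)


def test_pseudoknot_equal_length_tiebreak_five_prime():
    # two crossing regions, both length 2: keep the 5'-most start
    pairs = [(3, 12), (4, 11), (8, 20), (9, 19)]
    kept = remove_pseudoknots(pairs)
    assert sorted(kept) == [(3, 12), (4, 11)]


def _crossings(pairs):
    n = 0
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            (i, j), (k, l) = pairs[a], pairs[b]
            if i < k < j < l or k < i < l < j:
                n += 1
    return n


@settings(deadline=None, max_examples=50)
@given(st_.integers(0, 10_000))
def test_pseudoknot_removal_crossing_free_and_subset(seed):
    rng = np.random.default_rng(seed)
    length = int(rng.integers(6, 60))
    positions = list(rng.permutation(np.arange(1, length + 1)))
    pairs = []
    while len(positions) >= 2:
        i, j = positions.pop(), positions.pop()
        pairs.append((min(i, j), max(i, j)))
    kept = remove_pseudoknots(pairs)
    assert set(kept) <= set(pairs)
    assert _crossings(kept) == 0


def test_layer_one_of_crossing_free_set_is_input():
    pairs = [(1, 20), (2, 19), (5, 10), (12, 17)]
    ss = to_dotbracket(pairs, 20)
    assert set(ss.dotbracket) <= set("().")
    assert parse_dotbracket(ss.dotbracket) == sorted(pairs)


def test_stockholm_writer(tmp_path, hairpin):
    st, truth = hairpin
    pairs = detect_base_pairs(st.chains[0])
    seq = truth.sequences["A"]
    ss = to_dotbracket(remove_pseudoknots(pairs), len(seq))
    path = tmp_path / "hp.sto"
    write_stockholm("fhp_A", seq, ss, path)
    text = path.read_text()
    assert text.startswith("# STOCKHOLM 1.0")
    assert "#=GC SS_cons" in text
    assert text.rstrip().endswith("//")


def test_stockholm_rejects_pseudoknots(tmp_path):
    ss = to_dotbracket([(1, 10), (5, 14)], 14)
    with pytest.raises(ValueError, match="pseudoknot-free"):
        write_stockholm("x", "G" * 14, ss, tmp_path / "x.sto")
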