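"""Kabsch superposition, TM-score, alignment, clustering, site transfer."""

import numpy as np
import pytest

from ribannot import fixtures
from ribannot.structalign import (
    C3Trace,
    align_structures,
    cluster_representatives,
    kabsch_superpose,
    search_structure,
    tm_d0,
    tm_score,
    tm_score_sum,
    trace_from_chain,
    transfer_active_sites,
)


@pytest.fixture(scope="module")
def trace26():
    st, _ = fixtures.make_hairpin(10, 6)
    return trace_from_chain(st.chains[0])


@pytest.fixture(scope="module")
def trace100():
    st, _ = fixtures.make_hairpin(47, 6)
    return trace_from_chain(st.chains[0])


def _rigid(theta=0.6, axis="z", t=(4.0, -2.0, 7.0)):
    c, s = np.cos(theta), np.sin(theta)
    R = {"z": np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]),
         "x": np.array([[1, 0, 0], [0, c, -s], [0, s, c]])}[axis]
    return R, np.array(t)


def test_kabsch_identity(trace26):
    X = trace26.positions
    R, t, rmsd = kabsch_superpose(X, X)
    assert rmsd < 1e-9
    np.testing.assert_allclose(R, np.eye(3), atol=1e-9)


def test_kabsch_recovers_known_transform(trace26):
    X = trace26.positions
    R0, t0 = _rigid()
    Y = X @ R0.T + t0
    R, t, rmsd = kabsch_superpose(X, Y)
    assert rmsd < 1e-6
    np.testing.assert_allclose(R, R0, atol=1e-8)
    np.testing.assert_allclose(t, t0, atol=1e-7)


def test_kabsch_excludes_reflection(trace26):
    X = trace26.positions
    Y = X * np.array([-1.0, 1.0, 1.0])  # mirror image
    R, t, rmsd = kabsch_superpose(X, Y)
    assert np.linalg.det(R) > 0.99
    assert rmsd > 0.5


def test_kabsch_needs_three_points():
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((2, 3)), np.ones((2, 3)))


def test_d0_formula_and_floor():
    assert tm_d0(100) == pytest.approx(0.6 * np.sqrt(99.5) - 2.5)
    assert tm_d0(10) == 1.0  # floor
    with pytest.raises(ValueError):
        tm_d0(0)


def test_tm_score_sum_single_pair_at_d0():
    d0 = tm_d0(30)
    assert tm_score_sum(np.array([d0]), 30) == pytest.approx(0.5 / 30)


def test_self_alignment_is_exactly_one(trace26):
    res = align_structures(trace26, trace26)
    assert res.tm_query == 1.0
    assert res.tm_target == 1.0
    assert res.mapping == [(i, i) for i in range(len(trace26))]


def test_alignment_is_chain_id_independent(trace26):
    relabeled = C3Trace("zz", trace26.positions.copy(), trace26.sequence)
    a = align_structures(trace26, trace26)
    b = align_structures(trace26, relabeled)
    assert a.mapping == b.mapping
    assert a.tm_query == b.tm_query


def test_alignment_deterministic(trace100):
    rng = np.random.default_rng(0)
    other = C3Trace("o", trace100.positions + rng.normal(0, 1.0,
                    trace100.positions.shape), trace100.sequence)
    r1 = align_structures(trace100, other)
    r2 = align_structures(trace100, other)
    assert r1.mapping == r2.mapping
    assert r1.tm_query == r2.tm_query


def test_jittered_copy_high_tm(trace100):
    rng = np.random.default_rng(11)
    R0, t0 = _rigid(0.9, "x")
    jit = C3Trace("j", trace100.positions @ R0.T + t0
                  + rng.normal(0, 0.5, trace100.positions.shape),
                  trace100.sequence)
    res = align_structures(trace100, jit)
    assert res.tm_query >= 0.9


def test_insertion_alignment_maps_stem():
    a, _ = fixtures.make_hairpin(17, 6)    # 40 nt
    b, _ = fixtures.make_hairpin(17, 11)   # 45 nt: 5-nt longer loop
    ta = trace_from_chain(a.chains[0])
    tb = trace_from_chain(b.chains[0])
    res = align_structures(ta, tb)
    assert res.tm_query >= 0.45
    stem_mapped = {(q, t) for q, t in res.mapping if q < 17}
    assert stem_mapped == {(i, i) for i in range(17)}


def test_tm_score_matches_independent_reevaluation(trace100):
    rng = np.random.default_rng(4)
    other = C3Trace("o", trace100.positions
                    + rng.normal(0, 0.7, trace100.positions.shape),
                    trace100.sequence)
    res = align_structures(trace100, other)
    # re-evaluate the reported superposition by the closed-form sum
    qi = np.array([q for q, _ in res.mapping])
    ti = np.array([t for _, t in res.mapping])
    moved = trace100.positions[qi] @ res.rotation.T + res.translation
    d = np.linalg.norm(moved - other.positions[ti], axis=1)
    assert res.tm_query == pytest.approx(tm_score_sum(d, len(trace100)),
                                         abs=1e-9)


def test_short_traces_rejected():
    t = C3Trace("s", np.random.default_rng(0).uniform(0, 10, (4, 3)), "GGGG")
    with pytest.raises(ValueError):
        align_structures(t, t)


# --- clustering / search ----------------------------------------------------


def _line_trace(n, cid="line"):
    return C3Trace(cid, np.array([[5.9 * i, 0.0, 0.0] for i in range(n)]),
                   "G" * n)


def test_identical_traces_one_cluster(trace26):
    copy = C3Trace("c2", trace26.positions.copy(), trace26.sequence)
    clusters = cluster_representatives([trace26, copy])
    assert len(clusters) == 1
    assert len(clusters[0].members) == 2


def test_unrelated_shapes_two_singletons():
    hp, _ = fixtures.make_hairpin(8, 4)
    folded = trace_from_chain(hp.chains[0])
    extended = _line_trace(20)
    clusters = cluster_representatives([extended, folded])
    assert len(clusters) == 2
    # representatives pairwise below the cutoff, by direct computation
    from ribannot.structalign import _tm_by_shorter
    reps = [c.representative for c in clusters]
    assert _tm_by_shorter(reps[0], reps[1]) < 0.5


def test_jittered_copies_collapse(trace26):
    rng = np.random.default_rng(5)
    copies = [C3Trace(f"c{k}", trace26.positions
                      + rng.normal(0, 0.2, trace26.positions.shape),
                      trace26.sequence) for k in range(4)]
    clusters = cluster_representatives(copies)
    assert len(clusters) == 1
    assert len(clusters[0].members) == 4


def test_search_ranks_identical_first(trace26):
    db = cluster_representatives([_line_trace(20), trace26])
    hits = search_structure(trace26, db, top_n=100)
    assert hits[0].target_id == trace26.chain_id
    assert hits[0].tm_query == 1.0
    assert len(hits) <= len(db)
    tms = [h.tm_query for h in hits]
    assert tms == sorted(tms, reverse=True)
    assert trace26.chain_id in hits[0].cluster_members


def test_search_empty_db(trace26):
    assert search_structure(trace26, []) == []


# --- active-site transfer ---------------------------------------------------


def test_transfer_to_self(trace26):
    annots = transfer_active_sites(trace26, [3, 7, 12], [trace26],
                                   rfam_filter=False)
    assert len(annots) == 1
    assert annots[0].transferred_positions == {3: 3, 7: 7, 12: 12}
    assert annots[0].missing_positions == []


def test_transfer_threshold_consistency(trace26):
    """Admission tracks the 0.45 cutoff for candidates across the range."""
    rng = np.random.default_rng(9)
    candidates = []
    for sd in (0.2, 1.0, 2.5, 6.0, 14.0):
        candidates.append(C3Trace(
            f"sd{sd}", trace26.positions
            + rng.normal(0, sd, trace26.positions.shape), trace26.sequence))
    annots = transfer_active_sites(trace26, [5], candidates,
                                   rfam_filter=False)
    admitted = {a.target_id for a in annots}
    for cand in candidates:
        tm = align_structures(trace26, cand).tm_query
        assert (cand.chain_id in admitted) == (tm >= 0.45)


def test_transfer_rfam_family_filter(trace26):
    shared = C3Trace("shared", trace26.positions.copy(), trace26.sequence,
                     rfam=frozenset({"RF00005"}))
    other_family = C3Trace("other", trace26.positions.copy(),
                           trace26.sequence, rfam=frozenset({"RF00001"}))
    no_family = C3Trace("none", trace26.positions.copy(), trace26.sequence)
    template = C3Trace("tmpl", trace26.positions.copy(), trace26.sequence,
                       rfam=frozenset({"RF00005"}))
    annots = transfer_active_sites(template, [2], [shared, other_family,
                                                   no_family])
    # template < 100 nt: the family-less candidate is searched too
    assert {a.target_id for a in annots} == {"shared", "none"}


def test_transfer_long_template_skips_familyless(trace100):
    template = C3Trace("tmpl", trace100.positions.copy(), trace100.sequence,
                       rfam=frozenset({"RF00005"}))
    no_family = C3Trace("none", trace100.positions.copy(), trace100.sequence)
    annots = transfer_active_sites(template, [2], [no_family])
    assert annots == []


def test_transfer_validates_site_positions(trace26):
    with pytest.raises(ValueError):
        transfer_active_sites(trace26, [999], [trace26], rfam_filter=False)
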