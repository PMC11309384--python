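"""C3'-trace RNA structure alignment, clustering, search and site transfer.

RNA chains are reduced to their C3' atom traces.  Alignments are
order-preserving partial bijections scored with the TM-score,

    TM = (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2),
    d0 = max(0.6*sqrt(L_norm - 0.5) - 2.5, 1.0)  [Angstrom],

where the sum runs over aligned residue pairs and L_norm is the length
of whichever chain the score is normalised by.  The alignment heuristic
seeds from gapless threadings and best-fragment superpositions, then
alternates Kabsch superposition on the close subset with dynamic
programming on the TM-score similarity matrix until the mapping is
stable.  Everything is deterministic.

On top of the pairwise engine sit greedy representative clustering
(pairwise representative TM < 0.5), database search (top hits plus
cluster members), and template-based ribozyme active-site transfer at
the TM >= 0.45 significance cutoff, with the <100-nt rule that lets
short templates search Rfam-less chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .model import Chain
from .refdata import component_bases

GAP_PENALTY = 0.6
MAX_ITER = 30
FRAGMENT_LEN = 20


@dataclass
class C3Trace:
    chain_id: str
    positions: np.ndarray            # (N, 3) C3' coordinates
    sequence: str
    rfam: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.shape != (len(self.sequence), 3):
            raise ValueError(
                f"{self.chain_id}: {len(self.sequence)} nt but "
                f"{self.positions.shape[0]} C3' positions")

    def __len__(self) -> int:
        return len(self.sequence)


def trace_from_chain(chain: Chain, rfam: frozenset = frozenset()) -> C3Trace:
    """Extract the C3' trace; nucleotides without a C3' atom are dropped."""
    bases = component_bases()
    coords, letters = [], []
    for res in chain.polymer_residues():
        at = res.atom("C3'")
        if at is None:
            continue
        coords.append(at.coords)
        letters.append(bases.get(res.comp_id.upper(), "N"))
    if not coords:
        return C3Trace(chain.chain_id, np.empty((0, 3)), "", rfam)
    return C3Trace(chain.chain_id, np.asarray(coords), "".join(letters), rfam)


@dataclass
class AlignmentResult:
    mapping: list[tuple[int, int]]   # 0-based (query, target), increasing
    rotation: np.ndarray             # applied to query coordinates
    translation: np.ndarray
    rmsd: float
    tm_query: float
    tm_target: float
    d0_query: float
    d0_target: float

    def aligned_length(self) -> int:
        return len(self.mapping)


@dataclass
class ActiveSiteAnnotation:
    ribozyme_type: str
    template_id: str
    target_id: str
    site_positions: list[int]               # 1-based on the template
    transferred_positions: dict[int, int]   # template pos -> target pos
    missing_positions: list[int]
    tm_score: float


# ---------------------------------------------------------------------------
# superposition and TM-score


def kabsch_superpose(X: np.ndarray, Y: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper-rotation superposition of X onto Y.

    Returns (R, t, rmsd) minimising ||R x_i + t - y_i||; reflections are
    excluded, so mirror images superpose with non-zero rmsd.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("kabsch_superpose needs matching (N,3) point sets")
    if X.shape[0] < 3:
        raise ValueError("kabsch_superpose needs at least 3 points")
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((diff ** 2).sum() / X.shape[0]))
    return R, t, rmsd


def tm_d0(L_norm: int) -> float:
    """TM-score distance scale with the 1.0 A nucleic-acid floor."""
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    return max(0.6 * math.sqrt(L_norm - 0.5) - 2.5, 1.0)


def tm_score_sum(distances: np.ndarray, L_norm: int) -> float:
    """Closed-form TM-score of a fixed superposition's distances."""
    d0 = tm_d0(L_norm)
    distances = np.asarray(distances, float)
    return float(np.sum(1.0 / (1.0 + (distances / d0) ** 2)) / L_norm)


def tm_score(query_xyz: np.ndarray, target_xyz: np.ndarray,
             mapping: Sequence[tuple[int, int]], L_norm: int
             ) -> tuple[float, np.ndarray, np.ndarray]:
    """TM-score of a mapping, maximised over superpositions.

    Standard iterative subset refinement: superpose on a seed subset of
    the mapped pairs, rescore all pairs, re-seed with the close pairs,
    repeat; several seed fragments are tried and the best score wins.
    Returns (score, rotation, translation).
    """
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    mapping = list(mapping)
    n = len(mapping)
    if n == 0:
        return 0.0, np.eye(3), np.zeros(3)
    qi = np.array([q for q, _ in mapping])
    ti = np.array([t for _, t in mapping])
    X = np.asarray(query_xyz, float)[qi]
    Y = np.asarray(target_xyz, float)[ti]
    d0 = tm_d0(L_norm)

    if n < 3:
        # too few pairs to define a superposition: they can always be
        # brought to zero distance by a rigid move
        return n / L_norm, np.eye(3), np.zeros(3)

    seeds = []
    for frac in (1, 2, 4):
        flen = max(n // frac, 3)
        for start in range(0, n - flen + 1, max(flen // 2, 1)):
            seeds.append(np.arange(start, start + flen))
    best = (-1.0, np.eye(3), np.zeros(3))
    for seed in seeds:
        subset = seed
        prev_score = -1.0
        for _ in range(20):
            R, t, _ = kabsch_superpose(X[subset], Y[subset])
            d = np.linalg.norm(X @ R.T + t - Y, axis=1)
            score = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)
            if score > best[0]:
                best = (score, R, t)
            cut = d0
            new = np.where(d < cut)[0]
            while len(new) < 3:
                cut += 0.5
                new = np.where(d < cut)[0]
            if score <= prev_score and np.array_equal(new, subset):
                break
            prev_score = score
            subset = new
    return best


# ---------------------------------------------------------------------------
# pairwise alignment


def _dp_align(S: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Global alignment with free end gaps on a similarity matrix.

    Ties prefer diagonal, then up, then left, making the traceback
    deterministic.
    """
    m, n = S.shape
    H = np.zeros((m + 1, n + 1))
    P = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, m + 1):
        Si = S[i - 1]
        Hi = H[i]
        Hp = H[i - 1]
        for j in range(1, n + 1):
            diag = Hp[j - 1] + Si[j - 1]
            up = Hp[j] - (gap if j < n else 0.0)
            left = Hi[j - 1] - (gap if i < m else 0.0)
            if diag >= up and diag >= left:
                Hi[j] = diag
                P[i, j] = 0
            elif up >= left:
                Hi[j] = up
                P[i, j] = 1
            else:
                Hi[j] = left
                P[i, j] = 2
    i, j = m, n
    mapping = []
    while i > 0 and j > 0:
        if P[i, j] == 0:
            mapping.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif P[i, j] == 1:
            i -= 1
        else:
            j -= 1
    mapping.reverse()
    return mapping


def _score_mapping(query: C3Trace, target: C3Trace,
                   mapping: Sequence[tuple[int, int]], L_norm: int) -> float:
    score, _, _ = tm_score(query.positions, target.positions, mapping, L_norm)
    return score


def _quick_score(query: C3Trace, target: C3Trace,
                 mapping: Sequence[tuple[int, int]], L_norm: int) -> float:
    """One-shot superposition TM-score (cheap seed ranking)."""
    n = len(mapping)
    if n < 3:
        return n / L_norm
    qi = np.array([q for q, _ in mapping])
    ti = np.array([t for _, t in mapping])
    X = query.positions[qi]
    Y = target.positions[ti]
    R, t, _ = kabsch_superpose(X, Y)
    d = np.linalg.norm(X @ R.T + t - Y, axis=1)
    return tm_score_sum(d, L_norm)


def _gapless_seeds(lq: int, lt: int, min_overlap: int = 5
                   ) -> list[list[tuple[int, int]]]:
    seeds = []
    for offset in range(-(lt - min_overlap), lq - min_overlap + 1):
        lo = max(0, offset)
        hi = min(lq, lt + offset)
        if hi - lo >= min_overlap:
            seeds.append([(i, i - offset) for i in range(lo, hi)])
    return seeds


def _fragment_seed(query: C3Trace, target: C3Trace,
                   flen: int = FRAGMENT_LEN) -> Optional[list[tuple[int, int]]]:
    """Gapless seed from the best-superposing fragment pair."""
    lq, lt = len(query), len(target)
    flen = min(flen, lq, lt)
    if flen < 3:
        return None
    best = None
    best_rmsd = math.inf
    step = max(1, flen // 4)
    for qs in range(0, lq - flen + 1, step):
        Xf = query.positions[qs:qs + flen]
        for ts in range(0, lt - flen + 1, step):
            Yf = target.positions[ts:ts + flen]
            _, _, rmsd = kabsch_superpose(Xf, Yf)
            if rmsd < best_rmsd:
                best_rmsd = rmsd
                best = (qs, ts)
    if best is None:
        return None
    qs, ts = best
    return [(qs + k, ts + k) for k in range(flen)]


def align_structures(query: C3Trace, target: C3Trace,
                     config: Optional[PipelineConfig] = None
                     ) -> AlignmentResult:
    """Deterministic TM-score alignment of two C3' traces.

    Seeds (all gapless threadings plus the best 20-mer fragment pair)
    are ranked by their TM-score; the best few are refined by
    alternating superposition with dynamic programming on
    S_ij = 1/(1+(d_ij/d0)^2) (gap penalty 0.6) until the mapping is
    fixed or 30 rounds pass.  The result with the highest
    query-normalised TM-score is returned.
    """
    lq, lt = len(query), len(target)
    if lq < 5 or lt < 5:
        raise ValueError("alignment needs traces of at least 5 nt")
    d0 = tm_d0(min(lq, lt))

    seeds = _gapless_seeds(lq, lt)
    frag = _fragment_seed(query, target)
    if frag is not None:
        seeds.append(frag)
    scored = sorted(
        ((_quick_score(query, target, s, lq), k, s)
         for k, s in enumerate(seeds)),
        key=lambda x: (-x[0], x[1]))
    top_seeds = [s for _, _, s in scored[:5]]

    best_mapping: list[tuple[int, int]] = []
    best_tm = -1.0
    for seed in top_seeds:
        mapping = seed
        for _ in range(MAX_ITER):
            # superpose on the close subset of the current mapping
            qi = np.array([q for q, _ in mapping])
            ti = np.array([t for _, t in mapping])
            X = query.positions[qi]
            Y = target.positions[ti]
            R, t, _ = kabsch_superpose(X, Y)
            d = np.linalg.norm(X @ R.T + t - Y, axis=1)
            close = np.where(d < d0)[0]
            if len(close) >= 3:
                R, t, _ = kabsch_superpose(X[close], Y[close])
            moved = query.positions @ R.T + t
            diff = moved[:, None, :] - target.positions[None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=2))
            S = 1.0 / (1.0 + (dist / d0) ** 2)
            new_mapping = _dp_align(S, GAP_PENALTY)
            if new_mapping == mapping:
                break
            mapping = new_mapping
        tm_q = _quick_score(query, target, mapping, lq)
        if tm_q > best_tm:
            best_tm = tm_q
            best_mapping = mapping

    tm_q, R, t = tm_score(query.positions, target.positions, best_mapping, lq)
    tm_t = _score_mapping(query, target, best_mapping, lt)
    if best_mapping:
        qi = np.array([q for q, _ in best_mapping])
        ti = np.array([tt for _, tt in best_mapping])
        diff = query.positions[qi] @ R.T + t - target.positions[ti]
        rmsd = float(np.sqrt((diff ** 2).sum() / len(best_mapping)))
    else:
        rmsd = float("nan")
    return AlignmentResult(
        mapping=best_mapping, rotation=R, translation=t, rmsd=rmsd,
        tm_query=tm_q, tm_target=tm_t,
        d0_query=tm_d0(lq), d0_target=tm_d0(lt))


# ---------------------------------------------------------------------------
# clustering and search


@dataclass
class StructureCluster:
    representative: C3Trace
    members: list[C3Trace]


def _tm_by_shorter(a: C3Trace, b: C3Trace) -> float:
    res = align_structures(a, b)
    return _score_mapping(a, b, res.mapping, min(len(a), len(b)))


def cluster_representatives(traces: Sequence[C3Trace], tm_cut: float = 0.5
                            ) -> list[StructureCluster]:
    """Greedy clustering: representatives end up pairwise below tm_cut.

    Traces (already deduplicated by sequence) are visited longest-first;
    each joins the first representative reaching the cutoff on the
    TM-score normalised by the shorter chain, otherwise it founds a new
    cluster.
    """
    ordered = sorted(traces, key=lambda tr: (-len(tr), tr.chain_id))
    clusters: list[StructureCluster] = []
    for tr in ordered:
        placed = False
        for cl in clusters:
            if _tm_by_shorter(tr, cl.representative) >= tm_cut:
                cl.members.append(tr)
                placed = True
                break
        if not placed:
            clusters.append(StructureCluster(representative=tr, members=[tr]))
    return clusters


@dataclass
class SearchHit:
    rank: int
    target_id: str
    tm_query: float
    tm_target: float
    rmsd: float
    aligned_length: int
    cluster_members: list[str]


def search_structure(query: C3Trace, db: Sequence[StructureCluster],
                     top_n: int = 100) -> list[SearchHit]:
    """Rank database representatives by query-normalised TM-score.

    Each hit carries the ids of all chains in the representative's
    cluster, mirroring a search report that lists cluster members
    alongside the representative.
    """
    results = []
    for cl in db:
        res = align_structures(query, cl.representative)
        results.append((res.tm_query, cl, res))
    results.sort(key=lambda x: (-x[0], x[1].representative.chain_id))
    hits = []
    for rank, (tm_q, cl, res) in enumerate(results[:top_n], start=1):
        hits.append(SearchHit(
            rank=rank, target_id=cl.representative.chain_id,
            tm_query=tm_q, tm_target=res.tm_target, rmsd=res.rmsd,
            aligned_length=res.aligned_length(),
            cluster_members=[m.chain_id for m in cl.members]))
    return hits


# ---------------------------------------------------------------------------
# active-site transfer


def transfer_active_sites(template: C3Trace, site_positions: Sequence[int],
                          candidates: Sequence[C3Trace],
                          tm_cut: float = 0.45,
                          ribozyme_type: str = "",
                          rfam_filter: bool = True,
                          short_template_nt: int = 100
                          ) -> list[ActiveSiteAnnotation]:
    """Template-based annotation of putative ribozyme active sites.

    Candidates sharing an Rfam family with the template are searched;
    when the template is shorter than 100 nt, candidates with no Rfam
    family at all are searched too (short ribozymes often miss family
    assignment).  The template is the alignment query and an annotation
    is emitted only at TM-score >= tm_cut; site positions are carried
    through the residue mapping, with unmapped positions reported as
    missing.
    """
    site_positions = sorted(set(int(p) for p in site_positions))
    for p in site_positions:
        if not 1 <= p <= len(template):
            raise ValueError(f"site position {p} outside template "
                             f"(length {len(template)})")
    out = []
    for cand in candidates:
        if rfam_filter:
            shares_family = bool(template.rfam & cand.rfam)
            rfam_free_ok = (len(template) < short_template_nt
                            and not cand.rfam)
            if not (shares_family or rfam_free_ok):
                continue
        res = align_structures(template, cand)
        if res.tm_query < tm_cut:
            continue
        pos_map = {q + 1: t + 1 for q, t in res.mapping}
        transferred = {p: pos_map[p] for p in site_positions if p in pos_map}
        missing = [p for p in site_positions if p not in pos_map]
        out.append(ActiveSiteAnnotation(
            ribozyme_type=ribozyme_type, template_id=template.chain_id,
            target_id=cand.chain_id, site_positions=site_positions,
            transferred_positions=transferred, missing_positions=missing,
            tm_score=res.tm_query))
    return out
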