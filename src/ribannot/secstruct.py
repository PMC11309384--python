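"""Canonical base pairs from 3D coordinates, dot-bracket, pseudoknot removal.

Only canonical pairs are assigned: Watson-Crick A:U and G:C plus the G:U
wobble.  The geometric test is a standard stereochemical screen — C1'-C1'
distance window, at least two canonical donor-acceptor heavy-atom pairs
within the hydrogen-bond cutoff, near-coplanar base planes, and a minimum
intra-chain separation — with one partner per nucleotide (conflicts are
resolved in favour of the smallest mean hydrogen-bond distance).

Pseudoknots are removed with the incremental-length rule: maximal stacked
paired regions are added longest-first, skipping any region that crosses
an already accepted one.  Equal-length ties go to the region whose 5'
start comes first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .config import PipelineConfig
from .model import Chain, Residue
from .refdata import component_bases

PAIR_TYPES = {"AU", "UA", "GC", "CG", "GU", "UG"}

# donor/acceptor heavy-atom pairs per ordered base combination
_HBOND_ATOMS = {
    ("A", "U"): [("N6", "O4"), ("N1", "N3")],
    ("G", "C"): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    ("G", "U"): [("N1", "O2"), ("O6", "N3")],
}
for (x, y), pairs in list(_HBOND_ATOMS.items()):
    _HBOND_ATOMS[(y, x)] = [(b, a) for a, b in pairs]

_RING_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "U": ["N1", "C2", "N3", "C4", "C5", "C6"],
}

_LAYERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]


@dataclass(frozen=True)
class BasePair:
    i: int                      # 1-based position (global over the chain set)
    j: int                      # i < j
    pair_type: str              # e.g. "GC", "GU"
    mean_hbond_dist: float = 0.0
    chain_i: str = ""
    chain_j: str = ""

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError(f"base pair positions must satisfy i<j: {self}")
        if self.pair_type not in PAIR_TYPES:
            raise ValueError(f"non-canonical pair type {self.pair_type!r}")


@dataclass
class SecondaryStructure:
    length: int
    pairs: list[BasePair]
    dotbracket: str


def _base_letter(res: Residue) -> Optional[str]:
    cid = res.comp_id.upper()
    base = component_bases().get(cid)
    if base in ("A", "C", "G", "U"):
        return base
    if base == "T":
        return None  # deoxy T never forms a canonical RNA pair here
    if cid in ("A", "C", "G", "U"):
        return cid
    return None


def _plane_normal(res: Residue, base: str) -> Optional[np.ndarray]:
    pts = []
    for name in _RING_ATOMS[base]:
        a = res.atom(name)
        if a is not None:
            pts.append(a.coords)
    if len(pts) < 3:
        return None
    pts = np.asarray(pts)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def detect_base_pairs(chains: Union[Chain, Sequence[Chain]],
                      config: Optional[PipelineConfig] = None
                      ) -> list[BasePair]:
    """Canonical base pairs of one RNA chain or an RNA-RNA chain pair.

    Positions are 1-based over the concatenation of the chains' polymer
    residues in the order given.  Residues missing the atoms required by
    the test are skipped.
    """
    cfg = config or PipelineConfig()
    if isinstance(chains, Chain):
        chains = [chains]
    if not 1 <= len(chains) <= 2:
        raise ValueError("detect_base_pairs takes one or two chains")

    # flatten to (global position, chain id, local index, residue, base)
    entries = []
    pos = 0
    for ch in chains:
        for local, res in enumerate(ch.polymer_residues()):
            pos += 1
            base = _base_letter(res)
            entries.append((pos, ch.chain_id, local, res, base))

    candidates = []
    for a in range(len(entries)):
        pi, ci, li, ri, bi = entries[a]
        if bi is None or ri.atom("C1'") is None:
            continue
        for b in range(a + 1, len(entries)):
            pj, cj, lj, rj, bj = entries[b]
            if bj is None or rj.atom("C1'") is None:
                continue
            if ci == cj and (lj - li) < cfg.pair_min_separation:
                continue
            ptype = bi + bj
            if ptype not in PAIR_TYPES:
                continue
            d_c1 = float(np.linalg.norm(
                ri.atom("C1'").coords - rj.atom("C1'").coords))
            if not (cfg.pair_c1_min <= d_c1 <= cfg.pair_c1_max):
                continue
            hb_dists = []
            for an_i, an_j in _HBOND_ATOMS[(bi, bj)]:
                ai, aj = ri.atom(an_i), rj.atom(an_j)
                if ai is None or aj is None:
                    continue
                d = float(np.linalg.norm(ai.coords - aj.coords))
                if d <= cfg.pair_hbond_max:
                    hb_dists.append(d)
            if len(hb_dists) < cfg.pair_min_hbonds:
                continue
            ni, nj = _plane_normal(ri, bi), _plane_normal(rj, bj)
            if ni is None or nj is None:
                continue
            cosang = abs(float(np.dot(ni, nj)))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle > cfg.pair_plane_max_deg:
                continue
            candidates.append(BasePair(pi, pj, ptype,
                                       float(np.mean(hb_dists)), ci, cj))

    # one partner per nucleotide: smallest mean H-bond distance wins
    candidates.sort(key=lambda p: (p.mean_hbond_dist, p.i, p.j))
    taken: set[int] = set()
    result = []
    for p in candidates:
        if p.i in taken or p.j in taken:
            continue
        taken.add(p.i)
        taken.add(p.j)
        result.append(p)
    result.sort(key=lambda p: (p.i, p.j))
    return result


# ---------------------------------------------------------------------------
# dot-bracket


def _as_index_pairs(pairs: Sequence) -> list[tuple[int, int]]:
    out = []
    for p in pairs:
        if isinstance(p, BasePair):
            out.append((p.i, p.j))
        else:
            i, j = p
            out.append((int(i), int(j)))
    return out


def _crossing(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = p, q
    return (i < k < j < l) or (k < i < l < j)


def to_dotbracket(pairs: Sequence, length: int) -> SecondaryStructure:
    """Render a pair set as a multi-layer dot-bracket string.

    Nested pairs use "()"; crossing pairs spill greedily into "[]", "{}"
    and "<>".  More than four mutually crossing layers raises an error.
    """
    idx_pairs = _as_index_pairs(pairs)
    seen: set[int] = set()
    for i, j in idx_pairs:
        if not (1 <= i < j <= length):
            raise ValueError(f"pair ({i},{j}) outside sequence of length {length}")
        if i in seen or j in seen:
            raise ValueError(f"position in more than one pair: ({i},{j})")
        seen.update((i, j))

    layers: list[list[tuple[int, int]]] = [[] for _ in _LAYERS]
    chars = ["."] * length
    for p in sorted(idx_pairs):
        for k, layer in enumerate(layers):
            if all(not _crossing(p, q) for q in layer):
                layer.append(p)
                chars[p[0] - 1] = _LAYERS[k][0]
                chars[p[1] - 1] = _LAYERS[k][1]
                break
        else:
            raise ValueError(
                "secondary structure needs more than 4 bracket layers")
    bp = [p if isinstance(p, BasePair) else BasePair(p[0], p[1], "GC")
          for p in pairs]
    return SecondaryStructure(length=length, pairs=sorted(bp, key=lambda p: p.i),
                              dotbracket="".join(chars))


def parse_dotbracket(dotbracket: str) -> list[tuple[int, int]]:
    """Pair list from a (possibly multi-layer) dot-bracket string."""
    opens = {o: k for k, (o, _) in enumerate(_LAYERS)}
    closes = {c: k for k, (_, c) in enumerate(_LAYERS)}
    stacks: list[list[int]] = [[] for _ in _LAYERS]
    pairs = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch in opens:
            stacks[opens[ch]].append(pos)
        elif ch in closes:
            stack = stacks[closes[ch]]
            if not stack:
                raise ValueError(f"unbalanced {ch!r} at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch not in ".-:,_~":
            raise ValueError(f"unexpected character {ch!r} at position {pos}")
    for k, stack in enumerate(stacks):
        if stack:
            raise ValueError(f"unclosed {_LAYERS[k][0]!r} at {stack}")
    return sorted(pairs)


# ---------------------------------------------------------------------------
# paired regions and pseudoknot removal


@dataclass(frozen=True)
class PairedRegion:
    start_i: int
    start_j: int
    length: int

    def member_pairs(self) -> list[tuple[int, int]]:
        return [(self.start_i + k, self.start_j - k) for k in range(self.length)]


def paired_regions(pairs: Sequence) -> list[PairedRegion]:
    """Group pairs into maximal stacked runs (i+k, j-k), no bulges."""
    idx_pairs = sorted(_as_index_pairs(pairs))
    pair_set = set(idx_pairs)
    used: set[tuple[int, int]] = set()
    regions = []
    for i, j in idx_pairs:
        if (i, j) in used or (i - 1, j + 1) in pair_set:
            continue
        length = 0
        while (i + length, j - length) in pair_set:
            used.add((i + length, j - length))
            length += 1
        regions.append(PairedRegion(i, j, length))
    return regions


def remove_pseudoknots(pairs: Sequence) -> list:
    """Crossing-free subset by the incremental-length rule.

    Maximal stacked regions are accepted in order of decreasing length
    (ties: 5'-most start first); a region crossing any accepted pair is
    dropped wholesale.  The output is a subset of the input.
    """
    original = {(_as_index_pairs([p])[0]): p for p in pairs}
    regions = paired_regions(pairs)
    regions.sort(key=lambda r: (-r.length, r.start_i, r.start_j))
    kept: list[tuple[int, int]] = []
    for region in regions:
        members = region.member_pairs()
        if any(_crossing(m, q) for m in members for q in kept):
            continue
        kept.extend(members)
    kept.sort()
    return [original[p] for p in kept]


# ---------------------------------------------------------------------------
# text output


def dotbracket_record(name: str, sequence: str, ss: SecondaryStructure) -> str:
    """FASTA-like record: header, sequence line, structure line."""
    if len(sequence) != ss.length:
        raise ValueError("sequence/structure length mismatch")
    return f">{name}\n{sequence}\n{ss.dotbracket}\n"


def write_stockholm(name: str, sequence: str, ss: SecondaryStructure,
                    path) -> None:
    """Single-sequence Stockholm alignment with an SS_cons line.

    The structure written must be pseudoknot-free (covariance-model
    builders reject crossing pairs); callers remove pseudoknots first.
    """
    idx_pairs = _as_index_pairs(ss.pairs)
    for a in range(len(idx_pairs)):
        for b in range(a + 1, len(idx_pairs)):
            if _crossing(idx_pairs[a], idx_pairs[b]):
                raise ValueError(
                    "Stockholm SS_cons requires a pseudoknot-free structure")
    cons = ss.dotbracket.replace(".", ":").replace("(", "<").replace(")", ">")
    width = max(len(name), len("#=GC SS_cons")) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n\n")
        fh.write(f"{name:<{width}}{sequence}\n")
        fh.write(f"{'#=GC SS_cons':<{width}}{cons}\n")
        fh.write("//\n")
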