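"""Forward-strand PWM scanning of RNA sequences with exact p-values.

Motif occurrences are scored as log-odds (bits) of the PWM against a
0-order background over A/C/G/U.  P-values are exact tail probabilities
of the score under i.i.d. background windows, computed by convolving the
per-position score distributions on a fine integer score lattice — the
same construction FIMO uses.  Scanning is forward-strand only (RNA has
no reverse complement to scan), so reversing a sequence changes the
result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACGU"
SCORE_RESOLUTION = 20000      # integer lattice points per bit
PROB_FLOOR = 1e-4             # floor for zero PWM probabilities
DEFAULT_P_CUT = 1e-4


@dataclass
class Background:
    freq: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.freq) != set(ALPHABET):
            raise ValueError(f"background must cover {ALPHABET}")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")
        if any(v <= 0 for v in self.freq.values()):
            raise ValueError("background frequencies must be positive "
                             "(use a pseudocount)")

    @classmethod
    def uniform(cls) -> "Background":
        return cls({b: 0.25 for b in ALPHABET})


@dataclass
class PWM:
    motif_id: str
    matrix: np.ndarray              # (k, 4) probabilities, columns A C G U
    species_taxid: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be (k, 4)")
        if self.matrix.shape[0] < 3:
            raise ValueError(f"{self.motif_id}: motif must be >= 3 long")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"{self.motif_id}: PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass
class MotifHit:
    motif_id: str
    start: int                      # 1-based
    end: int                        # inclusive
    matched: str
    score: float                    # log-odds, bits
    p_value: float


# ---------------------------------------------------------------------------
# background estimation


def background_from_fasta(path, pseudocount: float = 0.1) -> Background:
    """0-order background from a FASTA file (T read as U, others skipped)."""
    counts = {b: 0 for b in ALPHABET}
    nseq = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        nseq += 1
        for ch in str(rec.seq).upper():
            if ch == "T":
                ch = "U"
            if ch in counts:
                counts[ch] += 1
    if nseq == 0:
        raise ValueError(f"{path}: no sequences in FASTA")
    total = sum(counts.values()) + 4 * pseudocount
    return Background({b: (counts[b] + pseudocount) / total for b in ALPHABET})


def background_from_counts(counts: dict[str, float],
                           pseudocount: float = 0.1) -> Background:
    total = sum(counts.get(b, 0) for b in ALPHABET) + 4 * pseudocount
    return Background({b: (counts.get(b, 0) + pseudocount) / total
                       for b in ALPHABET})


# ---------------------------------------------------------------------------
# PWM file parsing (ATtRACT-style matrix text)


def parse_pwms(path) -> list[PWM]:
    """Parse ATtRACT-style PWM text.

    Each motif is a ``>motif_id[<tab>taxid]`` header followed by k rows
    of 4 whitespace-separated probabilities (columns A, C, G, U).
    """
    pwms: list[PWM] = []
    motif_id: Optional[str] = None
    taxid = ""
    rows: list[list[float]] = []

    def flush():
        nonlocal rows
        if motif_id is not None:
            pwms.append(PWM(motif_id, np.array(rows), taxid))
        rows = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("\t")
                motif_id = parts[0].strip()
                taxid = parts[1].strip() if len(parts) > 1 else ""
            else:
                try:
                    vals = [float(x) for x in line.split()]
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad PWM row") from exc
                if len(vals) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                rows.append(vals)
    flush()
    return pwms


# ---------------------------------------------------------------------------
# scanning


def _int_scores(pwm: PWM, bg: Background) -> np.ndarray:
    """Per-position integer log-odds on the score lattice, shape (k, 4)."""
    probs = np.maximum(pwm.matrix, PROB_FLOOR)
    bgvec = np.array([bg.freq[b] for b in ALPHABET])
    bits = np.log2(probs / bgvec)
    return np.rint(bits * SCORE_RESOLUTION).astype(np.int64)


def score_distribution(pwm: PWM, bg: Background
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of integer window scores under the background.

    Returns (scores, probabilities) with scores ascending; probabilities
    sum to 1 up to floating-point rounding.
    """
    iscores = _int_scores(pwm, bg)
    bgvec = np.array([bg.freq[b] for b in ALPHABET])
    lo = int(iscores.min(axis=1).sum())
    hi = int(iscores.max(axis=1).sum())
    dist = {0: 1.0}
    for pos in range(len(pwm)):
        new: dict[int, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + int(iscores[pos, b])
                new[key] = new.get(key, 0.0) + p * bgvec[b]
        dist = new
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    assert lo <= scores[0] and scores[-1] <= hi
    return scores, probs


def _survival(scores: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """P(S >= scores[i]) for each i."""
    return probs[::-1].cumsum()[::-1]


def scan(sequence: str, pwm: PWM, bg: Background,
         p_cut: float = DEFAULT_P_CUT) -> list[MotifHit]:
    """Scan one RNA sequence with one PWM on the forward strand.

    Windows containing letters outside A/C/G/U (after T->U) are skipped.
    Hits with exact p-value <= p_cut are returned sorted by position.
    """
    seq = sequence.upper().replace("T", "U")
    k = len(pwm)
    if k > len(seq):
        return []
    iscores = _int_scores(pwm, bg)
    dscores, dprobs = score_distribution(pwm, bg)
    sf = _survival(dscores, dprobs)

    index = {b: i for i, b in enumerate(ALPHABET)}
    codes = np.array([index.get(ch, -1) for ch in seq])
    hits = []
    for start in range(len(seq) - k + 1):
        window = codes[start:start + k]
        if np.any(window < 0):
            continue
        s = int(iscores[np.arange(k), window].sum())
        pos = np.searchsorted(dscores, s, side="left")
        p = float(sf[pos]) if pos < len(dscores) else 0.0
        p = max(p, 0.0)
        if p <= p_cut:
            hits.append(MotifHit(
                motif_id=pwm.motif_id, start=start + 1, end=start + k,
                matched=seq[start:start + k],
                score=s / SCORE_RESOLUTION, p_value=p))
    return hits


def scan_by_species(rnas: dict[str, tuple[str, str]],
                    pwms: Sequence[PWM], bg: Background,
                    p_cut: float = DEFAULT_P_CUT) -> dict[str, list[MotifHit]]:
    """Scan a set of RNAs with the motifs of matching species.

    ``rnas`` maps a chain key to (sequence, taxid).  A motif is applied
    to a chain only when the taxids agree; motifs whose species matches
    no chain are skipped with a log message.  Motifs with no species set
    are applied to every chain.
    """
    taxids_present = {tax for _, tax in rnas.values()}
    out: dict[str, list[MotifHit]] = {key: [] for key in rnas}
    for pwm in pwms:
        if pwm.species_taxid and pwm.species_taxid not in taxids_present:
            logger.info("motif %s: species %s has no RNA chain, skipped",
                        pwm.motif_id, pwm.species_taxid)
            continue
        for key, (seq, tax) in rnas.items():
            if pwm.species_taxid and pwm.species_taxid != tax:
                continue
            out[key].extend(scan(seq, pwm, bg, p_cut))
    for key in out:
        out[key].sort(key=lambda h: (h.start, h.motif_id))
    return out
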