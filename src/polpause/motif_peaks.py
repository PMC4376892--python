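"""PWM scanning with exact p-value calibration and binding-site annotation.

The position weight matrix is built from a count matrix with a
background-distributed pseudocount; scores are log2 odds against a 0-order
background.  P-values are exact under the background model: per-column
scores are discretized onto a lattice (step chosen so the accumulated
distribution stays small) and the null score distribution is computed by
dynamic-programming convolution over columns.  Scanning scores every
position of both strands on the same lattice, so scan p-values agree
exactly with the DP tail.

Peak-level operations: location classification against gene annotations
(promoter = within 500bp upstream of a TSS, with precedence over gene
body), high-confidence designation (external-dataset overlap AND a
contained motif hit), and orientation by the majority motif strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, Interval

__all__ = [
    "PWM",
    "MotifHit",
    "Peak",
    "pwm_from_counts",
    "pwm_score_threshold",
    "scan_sequence",
    "classify_peak_location",
    "designate_hcgaf",
    "orient_peak",
    "annotate_peaks",
    "MOTIF_ALPHA",
    "PROMOTER_UPSTREAM",
]

MOTIF_ALPHA = 1e-4
PROMOTER_UPSTREAM = 500

_BASES = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int          # 0-based genomic start of the motif match
    strand: str
    score: float        # bits
    p: float            # P(score >= observed) under the background model


@dataclass
class Peak:
    """A binding-site interval with summit and per-condition intensities."""

    chrom: str
    start: int
    end: int
    summit: int
    name: str = "."
    intensity: dict = field(default_factory=dict)
    n_motifs: int = 0
    orientation: str = "+"
    orientation_tie: bool = False
    location: str = ""
    is_hc: bool = False

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside peak {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_interval(cls, iv: Interval) -> "Peak":
        summit = iv.summit if iv.summit is not None else (iv.start + iv.end) // 2
        return cls(iv.chrom, iv.start, iv.end, summit, name=iv.name)


class PWM:
    """Log-odds matrix with a discretized exact null score distribution.

    ``log_odds`` is 4 x w in bits.  ``lattice`` holds per-column integer
    scores ``round(log_odds / step)``; the null distribution of the lattice
    score sum under the background model is computed once by DP and cached.
    The absolute p-value discretization error is bounded by the probability
    mass within w*step of any lattice point.
    """

    def __init__(self, log_odds: np.ndarray, background: np.ndarray,
                 max_bins: int = 10_000) -> None:
        self.log_odds = np.asarray(log_odds, dtype=float)
        if self.log_odds.shape[0] != 4:
            raise ValueError("log-odds matrix must have 4 rows (A, C, G, T)")
        self.background = np.asarray(background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        self.width = self.log_odds.shape[1]
        span = float((self.log_odds.max(axis=0) - self.log_odds.min(axis=0)).sum())
        self.score_step = max(span / max_bins, 1e-12)
        self.lattice = np.round(self.log_odds / self.score_step).astype(np.int64)
        self._null_pmf: np.ndarray | None = None
        self._null_offset: int = 0
        self._tail: np.ndarray | None = None

    # -- null distribution --------------------------------------------------

    def _compute_null(self) -> None:
        lo = int(self.lattice.min(axis=0).sum())
        hi = int(self.lattice.max(axis=0).sum())
        pmf = np.zeros(hi - lo + 1)
        pmf[0] = 1.0
        offset = 0
        filled = 1
        for j in range(self.width):
            col = self.lattice[:, j]
            new = np.zeros_like(pmf)
            for b in range(4):
                shift = int(col[b] - col.min())
                new[shift:shift + filled] += self.background[b] * pmf[:filled]
            offset += int(col.min())
            filled += int(col.max() - col.min())
            pmf = new
        self._null_pmf = pmf
        self._null_offset = offset
        # tail[i] = P(lattice score >= offset + i)
        self._tail = np.cumsum(pmf[::-1])[::-1]

    @property
    def null_pmf(self) -> tuple[np.ndarray, int]:
        if self._null_pmf is None:
            self._compute_null()
        return self._null_pmf, self._null_offset

    def lattice_pvalue(self, lattice_score: int) -> float:
        """Exact P(lattice score sum >= observed) under the background model."""
        pmf, offset = self.null_pmf
        i = lattice_score - offset
        if i <= 0:
            return 1.0
        if i >= self._tail.size:
            return 0.0
        return float(self._tail[i])

    def score_word(self, word: str) -> float:
        """Continuous log-odds score of a width-w word, in bits."""
        idx = _ENCODE[np.frombuffer(word.encode(), dtype=np.uint8)]
        if idx.size != self.width or np.any(idx < 0):
            raise ValueError("word length/alphabet mismatch")
        return float(self.log_odds[idx, np.arange(self.width)].sum())

    def lattice_score_word(self, word: str) -> int:
        idx = _ENCODE[np.frombuffer(word.encode(), dtype=np.uint8)]
        if idx.size != self.width or np.any(idx < 0):
            raise ValueError("word length/alphabet mismatch")
        return int(self.lattice[idx, np.arange(self.width)].sum())


def pwm_from_counts(counts: np.ndarray, pseudocount: float = 1.0,
                    background: Sequence[float] | None = None,
                    max_bins: int = 10_000) -> PWM:
    """Build a PWM from a 4 x w count matrix.

    Column probabilities are (count + pseudocount*background) / (colsum +
    pseudocount); the matrix holds log2(probability / background).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4:
        raise ValueError("count matrix must have 4 rows (A, C, G, T)")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    log_odds = np.log2(probs / bg[:, None])
    return PWM(log_odds, bg, max_bins=max_bins)


def pwm_score_threshold(pwm: PWM, alpha: float) -> float:
    """Smallest score s with P(score >= s) <= alpha under the background null.

    Returned on the continuous (bits) scale as lattice_score * step.  When
    alpha is below the minimal attainable p, the threshold is pushed just
    above the maximum score (no word can reach it) with a warning.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    pmf, offset = pwm.null_pmf
    tail = pwm._tail
    ok = np.flatnonzero(tail <= alpha)
    if ok.size == 0:
        warnings.warn("alpha below minimal attainable p-value; threshold unattainable")
        return (offset + pmf.size) * pwm.score_step
    return (offset + ok[0]) * pwm.score_step


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes >= 0, 3 - codes, -1)
    return out[::-1]


def _scan_codes(codes: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Lattice scores at every start of a coded sequence; invalid starts masked."""
    w = pwm.width
    n = codes.size - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    safe = np.where(codes >= 0, codes, 0)
    for j in range(w):
        window = safe[j:j + n]
        scores += pwm.lattice[window, j]
        valid &= codes[j:j + n] >= 0
    return scores, valid


def scan_sequence(seq: str, pwm: PWM, alpha: float = MOTIF_ALPHA,
                  chrom: str = ".", offset: int = 0) -> list[MotifHit]:
    """Scan both strands of ``seq``; keep hits with exact p <= alpha.

    Overlapping hits are retained.  Positions containing non-ACGT letters
    never match.  ``offset`` shifts reported coordinates (scanning an
    extracted region of a chromosome).
    """
    codes = _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    pmf, null_offset = pwm.null_pmf
    tail = pwm._tail
    min_lattice = null_offset + int(np.flatnonzero(tail <= alpha)[0]) \
        if np.any(tail <= alpha) else None

    hits: list[MotifHit] = []
    L = codes.size
    w = pwm.width
    for strand, strand_codes in (("+", codes), ("-", _revcomp_codes(codes))):
        scores, valid = _scan_codes(strand_codes, pwm)
        if min_lattice is None:
            continue
        idx = np.flatnonzero(valid & (scores >= min_lattice))
        for i in idx:
            start = int(i) if strand == "+" else L - int(i) - w
            hits.append(MotifHit(
                chrom, offset + start, strand,
                score=float(scores[i]) * pwm.score_step,
                p=pwm.lattice_pvalue(int(scores[i])),
            ))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# peak-level annotation


def _promoter_interval(gene: GeneModel, upstream: int = PROMOTER_UPSTREAM) -> tuple[int, int]:
    # the `upstream` bases strictly upstream of the TSS, half-open genomic
    if gene.strand == "+":
        return gene.tss - upstream, gene.tss
    return gene.tss + 1, gene.tss + 1 + upstream


def classify_peak_location(peak: Peak, genes: Sequence[GeneModel],
                           upstream: int = PROMOTER_UPSTREAM) -> str:
    """promoter / gene_body / intergenic, with promoter precedence.

    Promoter = overlapping the strand-aware ``upstream`` bases before any
    TSS; otherwise gene_body if overlapping any gene interval; otherwise
    intergenic.
    """
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        ps, pe = _promoter_interval(gene, upstream)
        if peak.start < pe and ps < peak.end:
            return "promoter"
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        if peak.start < gene.end and gene.start < peak.end:
            return "gene_body"
    return "intergenic"


def _hits_inside(peak: Peak, hits: Sequence[MotifHit], width: int) -> list[MotifHit]:
    return [h for h in hits
            if h.chrom == peak.chrom and h.start >= peak.start and h.start + width <= peak.end]


def designate_hcgaf(peaks: Sequence[Peak], external_regions: Sequence[Interval],
                    hits: Sequence[MotifHit], motif_width: int) -> list[bool]:
    """High-confidence flags: external-region overlap AND a contained motif.

    A peak is high-confidence when it shares >= 1 base with any region from
    the independent dataset and fully contains >= 1 motif hit.
    """
    flags = []
    for peak in peaks:
        overlap = any(r.chrom == peak.chrom and peak.start < r.end and r.start < peak.end
                      for r in external_regions)
        has_motif = len(_hits_inside(peak, hits, motif_width)) > 0
        flags.append(overlap and has_motif)
    return flags


def orient_peak(peak: Peak, hits: Sequence[MotifHit], motif_width: int) -> tuple[str, bool]:
    """Majority strand of contained motif hits; ties and no-hit cases are '+'.

    Returns (strand, tie_flag); the flag marks ties and empty peaks.
    """
    inside = _hits_inside(peak, hits, motif_width)
    n_plus = sum(1 for h in inside if h.strand == "+")
    n_minus = len(inside) - n_plus
    if n_plus > n_minus:
        return "+", False
    if n_minus > n_plus:
        return "-", False
    return "+", True


def annotate_peaks(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                   external_regions: Sequence[Interval], hits: Sequence[MotifHit],
                   motif_width: int) -> pd.DataFrame:
    """Full per-peak annotation table (location, motifs, orientation, hc flag)."""
    hc = designate_hcgaf(peaks, external_regions, hits, motif_width)
    rows = []
    for peak, flag in zip(peaks, hc):
        inside = _hits_inside(peak, hits, motif_width)
        strand, tie = orient_peak(peak, inside, motif_width)
        peak.n_motifs = len(inside)
        peak.orientation, peak.orientation_tie = strand, tie
        peak.location = classify_peak_location(peak, genes)
        peak.is_hc = flag
        rows.append({
            "name": peak.name, "chrom": peak.chrom, "start": peak.start,
            "end": peak.end, "summit": peak.summit, "n_motifs": peak.n_motifs,
            "orientation": strand, "orientation_tie": tie,
            "location": peak.location, "is_hc": flag,
        })
    return pd.DataFrame(rows)
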