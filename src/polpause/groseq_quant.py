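"""Quantify engaged-polymerase reads in promoter windows and gene bodies.

A read is assigned to the single base of its 5' end on its strand; all
window statistics count assigned bases.  The promoter-proximal signal of a
gene is the 100bp window with the most sense-strand reads among all 100bp
windows fully contained in the 500bp search space centred on the TSS
(mirrored for minus-strand genes).  The gene body runs from 500bp downstream
of the TSS to the polyadenylation site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, LibraryStats, ReadTrack

__all__ = [
    "PromoterWindow",
    "RegionCount",
    "find_promoter_window",
    "count_region",
    "rpm_normalize",
    "replicate_correlation",
    "genome_bin_counts",
    "quantify_genes",
    "PROMOTER_SEARCH_FLANK",
    "PROMOTER_WINDOW",
    "BODY_OFFSET",
]

PROMOTER_SEARCH_FLANK = 250   # search space: 500bp centred on the TSS
PROMOTER_WINDOW = 100         # window width, bases
BODY_OFFSET = 500             # gene body starts this far downstream of the TSS


@dataclass(frozen=True)
class PromoterWindow:
    """The max-read 100bp promoter window of one gene (genomic, half-open)."""

    gene_id: str
    win_start: int
    win_end: int
    xp: int
    tie: bool = False


@dataclass(frozen=True)
class RegionCount:
    region_id: str
    count: int
    length: int

    @property
    def density(self) -> float:
        return self.count / self.length

    def rpm(self, stats: LibraryStats) -> float:
        return rpm_normalize(self.count, stats)


def _candidate_offsets(window: int = PROMOTER_WINDOW,
                       flank: int = PROMOTER_SEARCH_FLANK) -> np.ndarray:
    # offset o = window's most-upstream base relative to the TSS, in
    # transcription direction; windows fully inside [-flank, +flank)
    return np.arange(-flank, flank - window + 1)


def find_promoter_window(track: ReadTrack, gene: GeneModel,
                         window: int = PROMOTER_WINDOW,
                         flank: int = PROMOTER_SEARCH_FLANK,
                         chrom_len: int | None = None) -> PromoterWindow:
    """Max-count 100bp sense-strand window within ``flank`` of the TSS.

    Ties are broken by proximity of the window centre to the TSS, then by
    the more upstream window.  Windows falling off the chromosome (when
    ``chrom_len`` is given, or upstream of base 0) are clipped out of the
    candidate set.
    """
    offsets = _candidate_offsets(window, flank)
    tss, strand = gene.tss, gene.strand
    if strand == "+":
        starts = tss + offsets
    else:
        starts = tss - offsets - (window - 1)
    valid = starts >= 0
    if chrom_len is not None:
        valid &= starts + window <= chrom_len
    offsets, starts = offsets[valid], starts[valid]

    lo = int(starts.min())
    hi = int(starts.max()) + window
    dense = track.dense(gene.chrom, strand, lo, hi)
    cums = np.concatenate(([0], np.cumsum(dense)))
    counts = cums[starts - lo + window] - cums[starts - lo]

    best = counts.max() if counts.size else 0
    cand = np.flatnonzero(counts == best)
    centers = np.abs(offsets[cand] + (window - 1) / 2.0)
    cand = cand[centers == centers.min()]
    tie = cand.size > 1
    pick = cand[np.argmin(offsets[cand])]  # more upstream = smaller offset
    s = int(starts[pick])
    return PromoterWindow(gene.gene_id, s, s + window, int(counts[pick]), tie=tie)


def count_region(track: ReadTrack, chrom: str, start: int, end: int,
                 strand: str, region_id: str = "",
                 chrom_len: int | None = None) -> RegionCount:
    """Sum assigned read positions on ``strand`` within [start, end).

    ``strand`` may be '+', '-' or '.' (both).  Regions extending off the
    chromosome are clipped with a warning; the reported length is the
    clipped length.
    """
    if start >= end:
        raise ValueError(f"empty region {chrom}:{start}-{end}")
    cstart, cend = max(0, start), end if chrom_len is None else min(end, chrom_len)
    if (cstart, cend) != (start, end):
        warnings.warn(f"region {chrom}:{start}-{end} clipped to [{cstart},{cend})")
    if strand == ".":
        n = track.range_sum(chrom, "+", cstart, cend) + track.range_sum(chrom, "-", cstart, cend)
    else:
        n = track.range_sum(chrom, strand, cstart, cend)
    return RegionCount(region_id or f"{chrom}:{start}-{end}", n, cend - cstart)


def rpm_normalize(count: float, stats: LibraryStats) -> float:
    """Reads per million mapped (denominator per ``stats.norm_mode``)."""
    return 1e6 * count / stats.norm_total


def replicate_correlation(counts_a: Sequence[float], counts_b: Sequence[float]) -> float:
    """Pearson correlation of paired region counts from two libraries."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired count vectors must have equal length")
    return float(np.corrcoef(a, b)[0, 1])


def genome_bin_counts(track: ReadTrack, chrom_sizes: dict[str, int],
                      bin_size: int = 500) -> np.ndarray:
    """Unstranded read counts in fixed genome-wide bins (replicate QC mode)."""
    parts = []
    for chrom in sorted(chrom_sizes):
        nbins = -(-chrom_sizes[chrom] // bin_size)
        binned = np.zeros(nbins, dtype=np.int64)
        for strand in "+-":
            pos, cnt = track.arrays(chrom, strand)
            if pos.size:
                np.add.at(binned, pos // bin_size, cnt)
        parts.append(binned)
    return np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64)


def quantify_genes(genes: Sequence[GeneModel], tracks: dict[str, ReadTrack],
                   window_labels: Sequence[str] | None = None,
                   chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-gene promoter-window and gene-body counts across libraries.

    The promoter window of each gene is located once, on the track pooled
    over ``window_labels`` (default: all tracks), then the same window is
    counted in every library so per-library counts are comparable.  Genes
    whose body has non-positive length are dropped.
    """
    if window_labels is None:
        window_labels = list(tracks)
    pooled = ReadTrack.merge([tracks[l] for l in window_labels])
    rows = []
    for gene in genes:
        if gene.body_length <= 0:
            continue
        clen = chrom_sizes.get(gene.chrom) if chrom_sizes else None
        win = find_promoter_window(pooled, gene, chrom_len=clen)
        bstart, bend = gene.body_interval()
        row: dict[str, object] = {
            "gene_id": gene.gene_id, "chrom": gene.chrom, "strand": gene.strand,
            "tss": gene.tss, "win_start": win.win_start, "win_end": win.win_end,
            "Lp": win.win_end - win.win_start,
            "body_start": bstart, "body_end": bend, "Lb": bend - bstart,
        }
        for label, track in tracks.items():
            xp = track.range_sum(gene.chrom, gene.strand, win.win_start, win.win_end)
            xb = track.range_sum(gene.chrom, gene.strand, bstart, bend)
            row[f"xp_{label}"] = xp
            row[f"xb_{label}"] = xb
            if track.total_mapped:
                row[f"xp_rpm_{label}"] = 1e6 * xp / track.total_mapped
                row[f"xb_rpm_{label}"] = 1e6 * xb / track.total_mapped
        rows.append(row)
    return pd.DataFrame(rows)
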