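"""MNase / histone-variant paired-end fragment processing.

Mononucleosome-sized fragments (120-180bp inclusive) are selected
computationally; composite profiles and heatmaps use whole-fragment
coverage, while significance testing of occupancy changes counts fragment
*centers* in fixed windows: [TSS-100, TSS+50) in the direction of
transcription for promoters, and [summit-100, summit+100) for binding-site
summits.  Change calling delegates to the exact pooled test in
:mod:`polpause.differential`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import DIFF_Q, call_changed_regions
from .genome_io import GeneModel, GenomeIOError
from .motif_peaks import Peak

__all__ = [
    "FragmentSet",
    "filter_fragments",
    "fragment_coverage",
    "fragment_center_counts",
    "tss_fillin_test",
    "peak_fillin_test",
    "read_bedpe",
    "write_bedpe",
    "NUC_SIZE_MIN",
    "NUC_SIZE_MAX",
    "TSS_WINDOW",
    "SUMMIT_FLANK",
]

NUC_SIZE_MIN = 120
NUC_SIZE_MAX = 180
TSS_WINDOW = (-100, 50)   # transcription-direction offsets, half-open
SUMMIT_FLANK = 100


@dataclass
class FragmentSet:
    """Paired-end fragment intervals for one library.

    ``fragments`` is a DataFrame with columns chrom, start, end (0-based
    half-open outer spans).
    """

    fragments: pd.DataFrame
    label: str = ""
    assay: str = "MNase"

    def __post_init__(self) -> None:
        df = self.fragments
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise ValueError("fragments need chrom/start/end columns")
        if len(df) and not (df["end"] > df["start"]).all():
            raise ValueError("fragment end must exceed start")

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def lengths(self) -> np.ndarray:
        return (self.fragments["end"] - self.fragments["start"]).to_numpy()

    @property
    def centers(self) -> np.ndarray:
        """Fragment centers; even lengths take the left-of-middle base."""
        df = self.fragments
        return ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)


def filter_fragments(fs: FragmentSet, lo: int = NUC_SIZE_MIN,
                     hi: int = NUC_SIZE_MAX) -> FragmentSet:
    """Keep mononucleosome-sized fragments with lo <= length <= hi (inclusive)."""
    keep = (fs.lengths >= lo) & (fs.lengths <= hi)
    return FragmentSet(fs.fragments[keep].reset_index(drop=True), fs.label, fs.assay)


def fragment_coverage(fs: FragmentSet,
                      chrom_sizes: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Unstranded per-base coverage: each fragment adds 1 to every base it spans."""
    cov: dict[str, np.ndarray] = {}
    for chrom, grp in fs.fragments.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        n = chrom_sizes[chrom] if chrom_sizes else int(ends.max())
        delta = np.zeros(n + 1, dtype=np.int64)
        np.add.at(delta, np.clip(starts, 0, n), 1)
        np.add.at(delta, np.clip(ends, 0, n), -1)
        cov[chrom] = np.cumsum(delta)[:n]
    return cov


def fragment_center_counts(fs: FragmentSet, windows: pd.DataFrame) -> np.ndarray:
    """Fragment-center counts per half-open window.

    ``windows`` needs chrom/start/end columns; the result aligns with its
    row order.
    """
    counts = np.zeros(len(windows), dtype=np.int64)
    centers_by_chrom = {
        chrom: np.sort(((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2))
        for chrom, grp in fs.fragments.groupby("chrom")
    }
    for i, (chrom, start, end) in enumerate(
            zip(windows["chrom"], windows["start"], windows["end"])):
        centers = centers_by_chrom.get(chrom)
        if centers is None:
            continue
        counts[i] = np.searchsorted(centers, end) - np.searchsorted(centers, start)
    return counts


def tss_windows(genes: Sequence[GeneModel],
                window: tuple[int, int] = TSS_WINDOW) -> pd.DataFrame:
    """Strand-aware promoter windows covering offsets [window[0], window[1])."""
    lo, hi = window
    rows = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss + lo, g.tss + hi
        else:
            # downstream offset d maps to tss - d; offsets [lo, hi) mirror to
            # genomic [tss - hi + 1, tss - lo + 1)
            start, end = g.tss - hi + 1, g.tss - lo + 1
        rows.append({"region_id": g.gene_id, "chrom": g.chrom, "start": start, "end": end})
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def summit_windows(peaks: Sequence[Peak], flank: int = SUMMIT_FLANK) -> pd.DataFrame:
    rows = [{"region_id": p.name, "chrom": p.chrom,
             "start": p.summit - flank, "end": p.summit + flank} for p in peaks]
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def _fillin_test(fs_ctrl: Sequence[FragmentSet], fs_kd: Sequence[FragmentSet],
                 windows: pd.DataFrame, q_threshold: float) -> pd.DataFrame:
    counts = windows[["region_id"]].copy()
    totals: dict[str, int] = {}
    labels_ctrl, labels_kd = [], []
    for group, sets in (("ctrl", fs_ctrl), ("kd", fs_kd)):
        for i, fs in enumerate(sets):
            label = fs.label or f"{group}_{i}"
            (labels_ctrl if group == "ctrl" else labels_kd).append(label)
            counts[label] = fragment_center_counts(fs, windows)
            totals[label] = len(fs)
    return call_changed_regions(counts, labels_ctrl, labels_kd, totals,
                                q_threshold=q_threshold)


def tss_fillin_test(fs_ctrl: Sequence[FragmentSet], fs_kd: Sequence[FragmentSet],
                    genes: Sequence[GeneModel], q_threshold: float = DIFF_Q,
                    window: tuple[int, int] = TSS_WINDOW) -> pd.DataFrame:
    """Test promoters for nucleosome occupancy changes after knock-down.

    Fragment centers in [TSS-100, TSS+50) (transcription direction) per
    library, pooled within condition, exact test + BH; ``direction == "up"``
    rows are promoters filling in with nucleosomes.
    """
    return _fillin_test(fs_ctrl, fs_kd, tss_windows(genes, window), q_threshold)


def peak_fillin_test(fs_ctrl: Sequence[FragmentSet], fs_kd: Sequence[FragmentSet],
                     peaks: Sequence[Peak], q_threshold: float = DIFF_Q,
                     flank: int = SUMMIT_FLANK) -> pd.DataFrame:
    """Same machinery on [summit-100, summit+100) windows of binding sites."""
    return _fillin_test(fs_ctrl, fs_kd, summit_windows(peaks, flank), q_threshold)


# ---------------------------------------------------------------------------
# BEDPE


def read_bedpe(path: str | Path, label: str = "", assay: str = "MNase") -> FragmentSet:
    """Read BEDPE; each fragment is the outer span of the two read intervals."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise GenomeIOError(f"{path} line {lineno}: expected >=6 BEDPE fields")
            if f[0] != f[3]:
                raise GenomeIOError(f"{path} line {lineno}: interchromosomal pair")
            start = min(int(f[1]), int(f[4]))
            end = max(int(f[2]), int(f[5]))
            if end <= start:
                raise GenomeIOError(f"{path} line {lineno}: empty fragment")
            rows.append((f[0], start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return FragmentSet(df, label=label, assay=assay)


def write_bedpe(fs: FragmentSet, path: str | Path, read_len: int = 50) -> None:
    """Write fragments as read pairs covering each fragment's two ends."""
    with open(path, "w") as fh:
        for chrom, start, end in fs.fragments[["chrom", "start", "end"]].itertuples(index=False):
            r = min(read_len, end - start)
            fh.write(f"{chrom}\t{start}\t{start + r}\t{chrom}\t{end - r}\t{end}\n")
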