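"""Readers and writers for the plain-text genomic formats the pipeline touches.

Every coordinate in the package is 0-based, half-open (BED convention):
an interval ``[start, end)`` covers ``end - start`` bases.  The TSS of a
minus-strand gene is ``end - 1`` so that half-open arithmetic works the same
on both strands.

Strand-specific single-base read tracks are held as sparse per-base counts
(:class:`ReadTrack`); the bedGraph pair dialect common for nascent-RNA data
(one file per strand, minus-strand values possibly negative) is rectified on
read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyfaidx import Fasta

__all__ = [
    "GeneModel",
    "ReadTrack",
    "LibraryStats",
    "Interval",
    "GenomeIOError",
    "read_gene_table",
    "write_gene_table",
    "read_bedgraph_pair",
    "write_bedgraph_pair",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_jaspar_counts",
    "write_jaspar_counts",
]

VALID_STRANDS = ("+", "-")


class GenomeIOError(ValueError):
    """Malformed input file (carries the offending line number when known)."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates, strand, TSS and polyadenylation site.

    ``start``/``end`` are 0-based half-open transcript borders.  The TSS is
    ``start`` on the plus strand and ``end - 1`` on the minus strand.  The
    gene body used for pausing analysis runs from 500bp downstream of the
    TSS to the polyadenylation site, in the direction of transcription.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    polya: int

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise GenomeIOError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if not self.start < self.end:
            raise GenomeIOError(f"start >= end for {self.gene_id}")
        if not (self.start <= self.polya < self.end):
            raise GenomeIOError(f"polya outside gene for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tss_polya_distance(self) -> int:
        """Distance from the TSS to the polyadenylation site, in bases."""
        return abs(self.polya - self.tss)

    @property
    def body_length(self) -> int:
        """Length of the gene body ([TSS+500, polyA) in transcription direction)."""
        return self.tss_polya_distance - 500

    def body_interval(self) -> tuple[int, int]:
        """Genomic half-open interval of the gene body.

        Covers transcription offsets ``d in [500, D)`` where ``D`` is the
        TSS-to-polyA distance; raises when the body has non-positive length
        (such genes are excluded from pausing analysis).
        """
        d = self.tss_polya_distance
        if d <= 500:
            raise ValueError(f"gene {self.gene_id} has no gene body (polyA within 500bp of TSS)")
        if self.strand == "+":
            return self.tss + 500, self.tss + d
        return self.tss - d + 1, self.tss - 499

    def downstream(self, offset: int) -> int:
        """Genomic position ``offset`` bases downstream of the TSS (strand-aware)."""
        return self.tss + offset if self.strand == "+" else self.tss - offset


@dataclass
class LibraryStats:
    """Library-level normalization constants.

    ``background_density`` follows the convention that 1% of mapped reads
    are background distributed uniformly over the mappable genome.
    ``norm_mode`` selects the per-million denominator: the library total
    (``total``) or an externally supplied engaged-Pol-II-only total
    (``polII_only`` with ``polII_mapped`` set).
    """

    total_mapped: int
    genome_len: int
    norm_mode: str = "total"
    polII_mapped: int | None = None

    @property
    def background_density(self) -> float:
        return 0.01 * self.total_mapped / self.genome_len

    @property
    def norm_total(self) -> int:
        if self.norm_mode == "polII_only":
            if self.polII_mapped is None:
                raise ValueError("norm_mode=polII_only requires polII_mapped")
            return self.polII_mapped
        return self.total_mapped


class ReadTrack:
    """Strand-specific per-base read counts for one library.

    Internally sparse: for each ``(chrom, strand)`` key a sorted array of
    base positions and a matching array of positive integer counts, plus a
    cumulative sum for O(log n) range queries.
    """

    def __init__(self, counts: Mapping[tuple[str, str], tuple[np.ndarray, np.ndarray]] | None = None,
                 label: str = "") -> None:
        self.label = label
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if counts:
            for key, (pos, cnt) in counts.items():
                self._set(key, np.asarray(pos, dtype=np.int64), np.asarray(cnt, dtype=np.int64))

    def _set(self, key: tuple[str, str], pos: np.ndarray, cnt: np.ndarray) -> None:
        if pos.size and not np.all(np.diff(pos) > 0):
            order = np.argsort(pos, kind="stable")
            pos, cnt = pos[order], cnt[order]
            if np.any(np.diff(pos) == 0):
                raise ValueError("duplicate positions in track data")
        if np.any(cnt < 0):
            raise ValueError("negative counts in track data")
        keep = cnt > 0
        pos, cnt = pos[keep], cnt[keep]
        self._data[key] = (pos, cnt, np.concatenate(([0], np.cumsum(cnt))))

    @classmethod
    def from_positions(cls, reads: Mapping[tuple[str, str], np.ndarray], label: str = "") -> "ReadTrack":
        """Build a track from raw (unsorted, repeated) read 5'-end positions."""
        track = cls(label=label)
        for key, raw in reads.items():
            raw = np.asarray(raw, dtype=np.int64)
            pos, cnt = np.unique(raw, return_counts=True)
            track._set(key, pos, cnt)
        return track

    @property
    def total_mapped(self) -> int:
        return int(sum(cum[-1] for _, _, cum in self._data.values()))

    def keys(self) -> list[tuple[str, str]]:
        return list(self._data.keys())

    def chroms(self) -> list[str]:
        return sorted({c for c, _ in self._data})

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        pos, cnt, _ = self._data.get((chrom, strand), (np.empty(0, np.int64),) * 2 + (np.zeros(1),))
        return pos, cnt

    def range_sum(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Total reads on one strand within [start, end)."""
        entry = self._data.get((chrom, strand))
        if entry is None or start >= end:
            return 0
        pos, _, cum = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(cum[hi] - cum[lo])

    def dense(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Per-base counts over [start, end) as a dense vector."""
        out = np.zeros(end - start, dtype=np.int64)
        entry = self._data.get((chrom, strand))
        if entry is None:
            return out
        pos, cnt, _ = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        out[pos[lo:hi] - start] = cnt[lo:hi]
        return out

    def dense_unstranded(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.dense(chrom, "+", start, end) + self.dense(chrom, "-", start, end)

    @classmethod
    def merge(cls, tracks: Sequence["ReadTrack"], label: str = "pooled") -> "ReadTrack":
        """Sum several tracks base-by-base (e.g. pooling replicates)."""
        merged = cls(label=label)
        keys = {k for t in tracks for k in t._data}
        for key in keys:
            parts_p = [t._data[key][0] for t in tracks if key in t._data]
            parts_c = [t._data[key][1] for t in tracks if key in t._data]
            allpos = np.concatenate(parts_p)
            allcnt = np.concatenate(parts_c)
            pos, inv = np.unique(allpos, return_inverse=True)
            cnt = np.bincount(inv, weights=allcnt).astype(np.int64)
            merged._set(key, pos, cnt)
        return merged

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadTrack):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(
            np.array_equal(self._data[k][0], other._data[k][0])
            and np.array_equal(self._data[k][1], other._data[k][1])
            for k in self._data
        )


@dataclass
class Interval:
    """A BED-style interval, optionally with name, score, strand, summit.

    The summit, when present, is an absolute genomic coordinate inside
    ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GenomeIOError(f"interval end <= start: {self.chrom}:{self.start}-{self.end}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise GenomeIOError(
                f"summit {self.summit} outside interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# gene table


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "polya"]


def read_gene_table(path: str | Path, reject_overlaps: bool = False) -> list[GeneModel]:
    """Read a TSV gene table (header: gene_id chrom start end strand polya).

    Coordinates are 0-based half-open.  With ``reject_overlaps`` set, any two
    genes sharing a base on the same chromosome raise an error.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GENE_TABLE_COLUMNS:
            raise GenomeIOError(f"bad gene table header {header} in {path}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise GenomeIOError(f"{path} line {lineno}: expected 6 fields")
            try:
                gene = GeneModel(fields[0], fields[1], int(fields[2]), int(fields[3]),
                                 fields[4], int(fields[5]))
            except (ValueError, GenomeIOError) as exc:
                raise GenomeIOError(f"{path} line {lineno}: {exc}") from exc
            genes.append(gene)
    if reject_overlaps:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                if b.start < a.end:
                    raise GenomeIOError(f"overlapping genes {a.gene_id} and {b.gene_id} on {chrom}")
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.polya}\n")


# ---------------------------------------------------------------------------
# bedGraph pairs


def _read_bedgraph_strand(path: str | Path, strand: str,
                          out: dict[tuple[str, str], list[np.ndarray]]) -> None:
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise GenomeIOError(f"{path} line {lineno}: expected 4 bedGraph fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            value = float(fields[3])
            if value != int(value):
                raise GenomeIOError(f"{path} line {lineno}: non-integer count {value}")
            count = abs(int(value))  # minus-strand dialects store negative values
            if end <= start:
                raise GenomeIOError(f"{path} line {lineno}: end <= start")
            if start < last_end.get(chrom, 0):
                raise GenomeIOError(f"{path} line {lineno}: overlapping/unsorted intervals on {chrom}")
            last_end[chrom] = end
            if count == 0:
                continue
            key = (chrom, strand)
            lists = out.setdefault(key, [[], []])
            lists[0].append(np.arange(start, end, dtype=np.int64))
            lists[1].append(np.full(end - start, count, dtype=np.int64))


def read_bedgraph_pair(plus_path: str | Path, minus_path: str | Path, label: str = "") -> ReadTrack:
    """Read one strand-specific bedGraph pair into a ReadTrack.

    Intervals expand to per-base counts; negative values on the minus-strand
    file (the "plotted below zero" dialect) are rectified to their absolute
    value.  Overlapping intervals within one strand are an error.
    """
    raw: dict[tuple[str, str], list[np.ndarray]] = {}
    _read_bedgraph_strand(plus_path, "+", raw)
    _read_bedgraph_strand(minus_path, "-", raw)
    track = ReadTrack(label=label)
    for key, (pos_parts, cnt_parts) in raw.items():
        pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        cnt = np.concatenate(cnt_parts) if cnt_parts else np.empty(0, np.int64)
        track._set(key, pos, cnt)
    return track


def _write_bedgraph_strand(track: ReadTrack, strand: str, path: str | Path, sign: int = 1) -> None:
    with open(path, "w") as fh:
        for (chrom, s), (pos, cnt, _) in sorted(track._data.items()):
            if s != strand or pos.size == 0:
                continue
            # merge runs of consecutive bases with equal counts
            breaks = np.flatnonzero((np.diff(pos) != 1) | (np.diff(cnt) != 0))
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [pos.size - 1]))
            for i, j in zip(starts, ends):
                fh.write(f"{chrom}\t{pos[i]}\t{pos[j] + 1}\t{sign * cnt[i]}\n")


def write_bedgraph_pair(track: ReadTrack, plus_path: str | Path, minus_path: str | Path,
                        negate_minus: bool = False) -> None:
    _write_bedgraph_strand(track, "+", plus_path)
    _write_bedgraph_strand(track, "-", minus_path, sign=-1 if negate_minus else 1)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 (+ optional absolute summit in column 7)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise GenomeIOError(f"{path} line {lineno}: expected >=3 BED fields")
            try:
                iv = Interval(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    name=f[3] if len(f) > 3 else ".",
                    score=float(f[4]) if len(f) > 4 else 0.0,
                    strand=f[5] if len(f) > 5 else ".",
                    summit=int(f[6]) if len(f) > 6 else None,
                )
            except (ValueError, GenomeIOError) as exc:
                raise GenomeIOError(f"{path} line {lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name,
                      f"{iv.score:g}", iv.strand]
            if iv.summit is not None:
                fields.append(str(iv.summit))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into a chrom -> uppercase sequence mapping."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    for ext in (".fai",):
        idx = Path(str(path) + ext)
        if idx.exists():
            idx.unlink()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# JASPAR count matrices

_ROW_RE = re.compile(r"^\s*([ACGT])?\s*\[?\s*([-\d.eE+\s]+?)\s*\]?\s*$")
_BASES = "ACGT"


def read_jaspar_counts(path: str | Path) -> np.ndarray:
    """Read a JASPAR-style count matrix: 4 rows (A, C, G, T) x motif width.

    Accepts both the bracketed dialect (``A [ 0 3 79 ... ]``) and plain
    whitespace-separated rows; column sums need not be equal.
    """
    rows: list[np.ndarray] = []
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            m = _ROW_RE.match(line)
            if m is None:
                raise GenomeIOError(f"malformed matrix row in {path}: {line!r}")
            base = m.group(1)
            try:
                vals = np.array([float(x) for x in m.group(2).split()])
            except ValueError as exc:
                raise GenomeIOError(f"non-numeric cell in {path}: {line!r}") from exc
            rows.append(vals)
            order.append(base if base else _BASES[len(order)])
    if len(rows) != 4:
        raise GenomeIOError(f"expected 4 matrix rows in {path}, got {len(rows)}")
    widths = {r.size for r in rows}
    if len(widths) != 1:
        raise GenomeIOError(f"unequal row widths in {path}")
    mat = np.zeros((4, rows[0].size))
    for base, row in zip(order, rows):
        mat[_BASES.index(base)] = row
    if np.any(mat < 0):
        raise GenomeIOError(f"negative counts in {path}")
    return mat


def write_jaspar_counts(counts: np.ndarray, path: str | Path, name: str = "motif") -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, base in enumerate(_BASES):
            cells = " ".join(f"{v:g}" for v in counts[i])
            fh.write(f"{base} [ {cells} ]\n")
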