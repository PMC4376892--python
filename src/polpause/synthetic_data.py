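"""Synthetic annotation, sequence, read tracks, peaks and fragments.

The generator emulates the statistical structure the analysis assumes for a
nascent-transcription knock-down study in a fly-sized genome:

* a few thousand non-overlapping genes in three transcriptional classes
  (paused+active, non-paused+active, inactive);
* GRO-seq-like strand-specific single-base reads: a promoter-proximal
  Poisson pause peak 20-70bp downstream of the TSS, uniform gene-body
  density, and uniform background on both strands totalling ~1% of reads;
* knock-down effects as multiplicative factors on the pause peak and gene
  body of a designated affected subset;
* GAGA-factor-like binding-site peaks (promoter-proximal and intergenic)
  with GA-repeat element clusters embedded on a recorded strand, plus an
  independent-dataset region for most peaks (for high-confidence
  designation);
* MNase-like paired-end fragments: phased nucleosome arrays downstream of
  active TSSs, a depleted promoter zone whose rate is multiplied by
  ``fillin_factor`` at affected promoters/peaks after knock-down, and
  near-nucleosomal fragment lengths from a truncated normal.

Everything is deterministic under the master seed; each stage/condition/
replicate derives an independent substream by hashing its labels into the
seed sequence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .genome_io import (GeneModel, Interval, ReadTrack, write_bed,
                        write_bedgraph_pair, write_fasta, write_gene_table)
from .chromatin import FragmentSet, write_bedpe
from .motif_peaks import Peak

__all__ = ["SynthConfig", "simulate_genome", "simulate_groseq_track",
           "simulate_mnase_fragments", "write_dataset", "gaga_count_matrix",
           "GENE_CLASSES", "PAUSE_ZONE", "GAGA_PWM_WIDTH"]

GENE_CLASSES = ("paused_active", "nonpaused_active", "inactive")
PAUSE_ZONE = (20, 70)   # true pause zone, offsets downstream of the TSS
GAGA_PWM_WIDTH = 10


def gaga_count_matrix(width: int = GAGA_PWM_WIDTH) -> np.ndarray:
    """Count matrix for a GA-repeat motif (synthetic GAGA-element PWM).

    97 observations of the alternating GA consensus per column plus one of
    each other base; with the default uniform background this gives a sharp
    width-10 PWM whose exact p-value at the consensus is 0.25**10.
    """
    counts = np.ones((4, width))
    consensus = ("GA" * width)[:width]
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 97.0
    return counts


@dataclass(frozen=True)
class SynthConfig:
    """Desk-scale study conditions (see docs/methods.md for rationale)."""

    seed: int = 0
    n_paused_active: int = 800
    n_nonpaused_active: int = 600
    n_inactive: int = 600
    gene_len_range: tuple[int, int] = (2000, 8000)
    chrom_sizes: dict = field(default_factory=lambda: {"chr2L": 10_000_000,
                                                       "chr2R": 10_000_000})
    gap_range: tuple[int, int] = (1500, 4500)

    # GRO-seq structure (per library at depth 1)
    pause_rate: float = 120.0          # expected reads in the 50bp pause zone
    body_density: float = 0.25         # reads per base of gene body
    background_density: float = 0.0005  # reads per base per strand
    knockdown_factor_promoter: float = 0.4
    knockdown_factor_body: float = 0.7
    n_affected: int = 150

    # binding sites
    n_promoter_peaks: int = 300
    n_intergenic_peaks: int = 200
    n_intergenic_affected: int = 100
    unbound_intergenic_frac: float = 0.1
    external_frac: float = 0.9          # peaks covered by the independent dataset
    motif_repeat: int = 4               # GAGAG copies per bound peak

    # nucleosomes
    nfr_halfwidth: int = 100
    nfr_center_rate: float = 20.0       # fragment centers per library in the zone
    fillin_factor: float = 3.0
    frag_len_mean: float = 147.0
    frag_len_sd: float = 15.0
    frag_len_bounds: tuple[int, int] = (100, 220)
    mnase_background_rate: float = 0.002  # centers per base genome-wide
    nuc_array_n: int = 8
    nuc_spacing: int = 175
    nuc_first_offset: int = 135
    nuc_jitter_sd: float = 20.0
    nuc_rate: float = 6.0               # fragments per nucleosome per library

    n_replicates: int = 2
    depth: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pause_rate", "body_density", "background_density",
                     "nfr_center_rate", "fillin_factor", "mnase_background_rate",
                     "nuc_rate", "depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_affected > self.n_paused_active:
            raise ValueError("n_affected exceeds the paused-active class size")
        if self.n_intergenic_affected > self.n_intergenic_peaks:
            raise ValueError("n_intergenic_affected exceeds n_intergenic_peaks")

    @property
    def n_genes(self) -> int:
        return self.n_paused_active + self.n_nonpaused_active + self.n_inactive

    @property
    def genome_len(self) -> int:
        return sum(self.chrom_sizes.values())

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


def _rng(seed: int, *parts: str) -> np.random.Generator:
    entropy = [seed] + [zlib.crc32(p.encode()) for p in parts]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# genome / annotation / peaks


def simulate_genome(config: SynthConfig):
    """Generate annotation, sequence and truth tables.

    Returns ``(genes, seqs, truth)`` where ``truth`` is a dict holding the
    per-gene truth table, the Peak objects with their per-peak truth table,
    the synthetic independent-dataset regions, and the chromosome sizes.
    """
    rng = _rng(config.seed, "genome")
    classes = (["paused_active"] * config.n_paused_active
               + ["nonpaused_active"] * config.n_nonpaused_active
               + ["inactive"] * config.n_inactive)
    rng.shuffle(classes)

    chrom_names = sorted(config.chrom_sizes)
    margin = 5000
    genes: list[GeneModel] = []
    gaps: list[tuple[str, int, int]] = []
    ci, cursor = 0, margin
    for i, cls in enumerate(classes):
        length = int(rng.integers(*config.gene_len_range))
        gap = int(rng.integers(*config.gap_range))
        while ci < len(chrom_names) and cursor + gap + length + margin > config.chrom_sizes[chrom_names[ci]]:
            ci += 1
            cursor = margin
        if ci >= len(chrom_names):
            raise ValueError("genome too small to place all genes without overlap")
        chrom = chrom_names[ci]
        gaps.append((chrom, cursor, cursor + gap))
        start = cursor + gap
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        tail = int(rng.integers(50, 200))
        polya = start + (length - tail) if strand == "+" else start + tail - 1
        genes.append(GeneModel(f"g{i:05d}", chrom, start, end, strand, polya))
        cursor = end
    paused_ids = [g.gene_id for g, c in zip(genes, classes) if c == "paused_active"]
    affected_ids = set(rng.choice(paused_ids, size=config.n_affected, replace=False)) \
        if config.n_affected else set()
    gene_truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "chrom": [g.chrom for g in genes],
        "strand": [g.strand for g in genes],
        "tss": [g.tss for g in genes],
        "cls": classes,
        "affected": np.array([g.gene_id in affected_ids for g in genes], dtype=bool),
    })

    peaks, peak_truth = _place_peaks(config, rng, genes, gene_truth, gaps)
    seqs = _make_sequences(config, rng, peaks, peak_truth)

    ext_mask = rng.random(len(peaks)) < config.external_frac
    external = [Interval(p.chrom, p.summit - 150, p.summit + 150,
                         name=f"ext_{p.name}")
                for p, m in zip(peaks, ext_mask) if m]
    peak_truth["has_external"] = ext_mask

    truth = {"genes": gene_truth, "peaks": peaks, "peak_truth": peak_truth,
             "external_regions": external, "chrom_sizes": dict(config.chrom_sizes)}
    return genes, seqs, truth


def _place_peaks(config, rng, genes, gene_truth, gaps):
    peaks: list[Peak] = []
    rows = []
    # promoter peaks: every affected gene, then random other paused-active genes
    paused = gene_truth[gene_truth["cls"] == "paused_active"]
    aff_ids = list(paused[paused["affected"]]["gene_id"])
    other_ids = list(paused[~paused["affected"]]["gene_id"])
    n_extra = min(max(0, config.n_promoter_peaks - len(aff_ids)), len(other_ids))
    chosen = aff_ids + (list(rng.choice(other_ids, size=n_extra, replace=False))
                        if n_extra else [])
    by_id = {g.gene_id: g for g in genes}
    for j, gid in enumerate(chosen):
        g = by_id[gid]
        summit = g.downstream(-75)
        strand = "+" if rng.random() < 0.5 else "-"
        peak = Peak(g.chrom, summit - 100, summit + 100, summit, name=f"pk_prom_{j:04d}")
        peaks.append(peak)
        rows.append({"name": peak.name, "kind": "promoter", "gene_id": gid,
                     "bound": True, "motif_strand": strand, "affected_fillin": False})
    # intergenic peaks in inter-gene gaps, away from promoters
    wide = [(c, s, e) for c, s, e in gaps if e - s >= 3000]
    if config.n_intergenic_peaks > len(wide):
        raise ValueError("not enough inter-gene gaps for the requested intergenic peaks")
    picks = (rng.choice(len(wide), size=config.n_intergenic_peaks, replace=False)
             if config.n_intergenic_peaks else np.zeros(0, dtype=int))
    unbound = rng.random(config.n_intergenic_peaks) < config.unbound_intergenic_frac
    bound_idx = [i for i in range(config.n_intergenic_peaks) if not unbound[i]]
    n_fill = min(config.n_intergenic_affected, len(bound_idx))
    fill_idx = set(rng.choice(bound_idx, size=n_fill, replace=False)) if n_fill else set()
    for j, (gi, ub) in enumerate(zip(picks, unbound)):
        chrom, s, e = wide[gi]
        summit = (s + e) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        peak = Peak(chrom, summit - 100, summit + 100, summit, name=f"pk_int_{j:04d}")
        peaks.append(peak)
        rows.append({"name": peak.name, "kind": "intergenic", "gene_id": "",
                     "bound": not ub, "motif_strand": strand if not ub else ".",
                     "affected_fillin": j in fill_idx})
    return peaks, pd.DataFrame(rows, columns=["name", "kind", "gene_id", "bound",
                                              "motif_strand", "affected_fillin"])


_REVCOMP = str.maketrans("ACGT", "TGCA")


def _make_sequences(config, rng, peaks, peak_truth):
    seqs = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, size in sorted(config.chrom_sizes.items()):
        arr = bases[rng.integers(0, 4, size=size)]
        seqs[chrom] = arr
    # a (GA)_m run long enough that the width-10 GA-repeat PWM matches it at
    # exactly `motif_repeat` starts (every second position of the run)
    motif = "GA" * (config.motif_repeat + GAGA_PWM_WIDTH // 2 - 1)
    for peak, bound, strand in zip(peaks, peak_truth["bound"], peak_truth["motif_strand"]):
        if not bound:
            continue
        ins = motif if strand == "+" else motif.translate(_REVCOMP)[::-1]
        start = peak.summit - len(ins) // 2
        seqs[peak.chrom][start:start + len(ins)] = np.frombuffer(ins.encode(), dtype=np.uint8)
    return {c: a.tobytes().decode() for c, a in seqs.items()}


# ---------------------------------------------------------------------------
# GRO-seq tracks


def simulate_groseq_track(genes: Sequence[GeneModel], truth: pd.DataFrame,
                          config: SynthConfig, condition: str,
                          replicate: int) -> ReadTrack:
    """One strand-specific single-base read track for condition/replicate.

    ``condition`` is ``control`` or ``kd``; knock-down multiplies the pause
    peak and gene body of affected genes by the configured factors.
    """
    rng = _rng(config.seed, "groseq", condition, str(replicate))
    depth = config.depth
    kd = condition == "kd"
    info = truth.set_index("gene_id")
    pos: dict[tuple[str, str], list[np.ndarray]] = {}

    def emit(chrom, strand, positions):
        if positions.size:
            pos.setdefault((chrom, strand), []).append(positions)

    for g in genes:
        row = info.loc[g.gene_id]
        cls, affected = row["cls"], bool(row["affected"])
        fp = config.knockdown_factor_promoter if (kd and affected) else 1.0
        fb = config.knockdown_factor_body if (kd and affected) else 1.0
        if cls != "inactive":
            bstart, bend = g.body_interval()
            n = rng.poisson(config.body_density * (bend - bstart) * fb * depth)
            emit(g.chrom, g.strand, rng.integers(bstart, bend, size=n))
        if cls == "paused_active":
            n = rng.poisson(config.pause_rate * fp * depth)
            offs = rng.integers(PAUSE_ZONE[0], PAUSE_ZONE[1], size=n)
            gpos = g.tss + offs if g.strand == "+" else g.tss - offs
            emit(g.chrom, g.strand, gpos)
    for chrom, size in sorted(config.chrom_sizes.items()):
        for strand in "+-":
            n = rng.poisson(config.background_density * size * depth)
            emit(chrom, strand, rng.integers(0, size, size=n))

    reads = {k: np.concatenate(v) for k, v in pos.items()}
    return ReadTrack.from_positions(reads, label=f"{condition}_{replicate}")


# ---------------------------------------------------------------------------
# MNase fragments


def _truncated_lengths(rng, config: SynthConfig, n: int) -> np.ndarray:
    lo, hi = config.frag_len_bounds
    a = (lo - 0.5 - config.frag_len_mean) / config.frag_len_sd
    b = (hi + 0.5 - config.frag_len_mean) / config.frag_len_sd
    draws = truncnorm.rvs(a, b, loc=config.frag_len_mean, scale=config.frag_len_sd,
                          size=n, random_state=rng)
    return np.clip(np.rint(draws).astype(np.int64), lo, hi)


def simulate_mnase_fragments(genes: Sequence[GeneModel], truth: dict,
                             config: SynthConfig, condition: str, replicate: int,
                             assay: str = "MNase") -> FragmentSet:
    """Paired-end nucleosome fragments for one condition/replicate.

    Mixture per library: uniform genomic background; phased nucleosome
    arrays downstream of active TSSs; a promoter zone of half-width
    ``nfr_halfwidth`` around active TSSs with a depleted center rate that is
    multiplied by ``fillin_factor`` at affected genes under knock-down; the
    same zone/fill-in structure around bound intergenic peak summits.
    """
    rng = _rng(config.seed, "mnase", assay, condition, str(replicate))
    depth = config.depth
    kd = condition == "kd"
    gene_truth = truth["genes"].set_index("gene_id")
    chroms: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    chrom_codes = sorted(config.chrom_sizes)
    code = {c: i for i, c in enumerate(chrom_codes)}

    def emit(chrom, arr):
        if arr.size:
            centers.append(arr.astype(np.int64))
            chroms.append(np.full(arr.size, code[chrom], dtype=np.int16))

    for g in genes:
        row = gene_truth.loc[g.gene_id]
        if row["cls"] == "inactive":
            continue
        affected = bool(row["affected"])
        # phased array downstream of the TSS
        for k in range(config.nuc_array_n):
            mean = g.downstream(config.nuc_first_offset + k * config.nuc_spacing)
            n = rng.poisson(config.nuc_rate * depth)
            emit(g.chrom, np.rint(rng.normal(mean, config.nuc_jitter_sd, size=n)))
        # promoter zone (depleted; fills in at affected genes under KD)
        rate = config.nfr_center_rate * (config.fillin_factor if (kd and affected) else 1.0)
        n = rng.poisson(rate * depth)
        emit(g.chrom, rng.integers(g.tss - config.nfr_halfwidth,
                                   g.tss + config.nfr_halfwidth + 1, size=n))
    for peak, bound, aff in zip(truth["peaks"], truth["peak_truth"]["bound"],
                                truth["peak_truth"]["affected_fillin"]):
        if not bound or not peak.name.startswith("pk_int"):
            continue
        rate = config.nfr_center_rate * (config.fillin_factor if (kd and aff) else 1.0)
        n = rng.poisson(rate * depth)
        emit(peak.chrom, rng.integers(peak.summit - config.nfr_halfwidth,
                                      peak.summit + config.nfr_halfwidth, size=n))
    for chrom, size in sorted(config.chrom_sizes.items()):
        n = rng.poisson(config.mnase_background_rate * size * depth)
        emit(chrom, rng.integers(200, size - 200, size=n))

    if centers:
        cen = np.concatenate(centers)
        chr_idx = np.concatenate(chroms)
    else:
        cen = np.zeros(0, dtype=np.int64)
        chr_idx = np.zeros(0, dtype=np.int16)
    lengths = _truncated_lengths(rng, config, cen.size)
    starts = cen - lengths // 2
    ends = starts + lengths
    ok = starts >= 0
    df = pd.DataFrame({
        "chrom": np.array(chrom_codes, dtype=object)[chr_idx[ok]],
        "start": starts[ok],
        "end": ends[ok],
    })
    return FragmentSet(df, label=f"{assay}_{condition}_{replicate}", assay=assay)


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(outdir: str | Path, config: SynthConfig) -> dict:
    """Simulate everything and write the formats the readers consume.

    Writes the gene table, truth tables, FASTA, one bedGraph pair per
    GRO-seq library, peak/external BED files and one BEDPE per MNase
    library; returns the in-memory objects for downstream stages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, seqs, truth = simulate_genome(config)
    write_gene_table(genes, outdir / "genes.tsv")
    truth["genes"].to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth["peak_truth"].to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
    write_fasta(seqs, outdir / "genome.fa")
    write_bed([Interval(p.chrom, p.start, p.end, p.name, 0.0, ".", p.summit)
               for p in truth["peaks"]], outdir / "peaks.bed")
    write_bed(truth["external_regions"], outdir / "external_regions.bed")

    tracks: dict[str, ReadTrack] = {}
    for condition in ("control", "kd"):
        for rep in range(1, config.n_replicates + 1):
            track = simulate_groseq_track(genes, truth["genes"], config, condition, rep)
            tracks[track.label] = track
            write_bedgraph_pair(track,
                                outdir / f"groseq_{track.label}_plus.bedgraph",
                                outdir / f"groseq_{track.label}_minus.bedgraph",
                                negate_minus=True)
    fragsets: dict[str, FragmentSet] = {}
    for condition in ("control", "kd"):
        for rep in range(1, config.n_replicates + 1):
            fs = simulate_mnase_fragments(genes, truth, config, condition, rep)
            fragsets[fs.label] = fs
            write_bedpe(fs, outdir / f"mnase_{condition}_{rep}.bedpe")
    return {"genes": genes, "seqs": seqs, "truth": truth,
            "tracks": tracks, "fragments": fragsets}
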