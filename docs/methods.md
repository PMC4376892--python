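# Methods

## Coordinate and counting conventions

All coordinates are 0-based, half-open.  The TSS of a minus-strand gene is
`end - 1`, so upstream/downstream arithmetic mirrors cleanly.  A sequencing
read contributes a single count at the base of its 5′ end on its strand;
windows count assigned bases.  This makes window statistics well defined
and lets a strand-specific bedGraph pair represent a library exactly; it
differs from whole-read-overlap counting only at window edges, by at most
one read length.  Fragment (paired-end) data are the exception: composite
profiles use whole-fragment coverage, while significance tests use the
fragment center, `floor((start+end)/2)` (deterministic left-of-middle for
even lengths).

## Pausing and activity classification

The promoter signal of a gene is the maximum-count 100 bp sense-strand
window among the 401 windows fully contained in the 500 bp search space
centred on the TSS.  Ties are broken by proximity of the window center to
the TSS, then by the more upstream window, so an empty track yields the
window centred on the TSS.  The search space deliberately includes the
region upstream of the TSS; divergent upstream transcription lands on the
opposite strand and is excluded by sense-strand counting.

The pausing test compares the observed `(x_p, x_b)` against the expected
uniform split of the same `N = x_p + x_b` reads by region length, with the
expected promoter count rounded to the nearest integer (ties to even —
Fisher's test needs integer cells; the rounding direction is immaterial at
the counts involved).  The test is one-sided for promoter excess: a gene
whose promoter density is below its body density can never be called
paused.  The activity test is the upper Poisson tail with mean equal to
the background density — 1% of mapped reads uniform over the mappable
genome — times the mappable body length.  Both flags use strict `p < 0.01`.
Both tests are discrete and therefore conservative: under their own nulls
the realized false-positive rates are below the nominal level (measured at
≲0.1% and ≲0.7% respectively by the acceptance script).  No
multiple-testing correction is applied to these per-gene calls.

Genes whose polyadenylation site lies within 500 bp of the TSS have no
gene body under the `[TSS+500, polyA)` definition and are excluded from
pausing analysis.  The pausing index uses the sentinel `-1` when the body
has zero reads, keeping the column numeric in exported tables.

## Differential analysis

Replicates are pooled within condition and each region is tested with the
exact conditional binomial split test; conditioning on the region total
removes the nuisance scale and the library-size ratio enters as the null
success probability.  This deliberately models no biological
over-dispersion — with two replicates a dispersion estimate would be
essentially prior-driven — and the package's validation is therefore by
truth recovery on simulation (sensitivity and empirical FDR against the
generator's truth tables), not by matching any particular fitted count
model.  Two-sided p-values are by tail doubling (simple and conservative);
q-values are Benjamini–Hochberg (via statsmodels); calls use `q < 0.01`.
Log2 fold changes add 0.5 to each pooled count so that zero-count regions
remain finite and plottable.

The promoter window of each gene is located once on the pooled control
track and then counted identically in every library, so the max-window
selection inflates all libraries equally and cancels from the
between-condition comparison.

Direction bias among significant changes uses the exact binomial tail in
the direction of the observed majority under a fair-coin null; the
function is symmetric in its two arguments.

## Motif scanning

PWMs are built from count matrices with a background-distributed
pseudocount (default 1) and a 0-order background (default uniform 0.25,
configurable to sequence composition).  Scores are log2 odds in bits.
P-values are exact under the background model: per-column scores are
rounded onto a lattice whose step is the total score span divided by 10⁴,
and the null distribution of the lattice score sum is computed by
dynamic-programming convolution over columns.  Scanning scores every
position of both strands *on the same lattice*, so scan p-values agree
bit-exactly with the DP tail (verified against full 4^w enumeration for
widths ≤ 6); the only approximation relative to continuous scores is the
rounding itself, bounded by half a step per column.  Non-ACGT letters
never match.  The hit threshold is `p ≤ 1e-4`; overlapping hits are kept.

High-confidence binding sites must overlap (≥ 1 shared base) a region
from an independent dataset *and* fully contain at least one motif hit.
Peak location classification gives promoters (the 500 bp strand-aware
upstream of any TSS) precedence over gene bodies.  Peak orientation is
the majority strand of contained hits, with ties and hit-less peaks
assigned "+" plus an explicit tie flag rather than being dropped.

## Nucleosome occupancy

Mononucleosome size selection keeps fragment lengths in [120, 180]
inclusive.  Fill-in testing counts fragment centers in
`[TSS-100, TSS+50)` (transcription direction; for a minus-strand TSS at
position t this is the genomic interval `[t-49, t+101)`) or in
`[summit-100, summit+100)` around binding-site summits, then delegates to
the differential machinery; promoters "filling in" are the significant
increases.  The same windows are used for histone-variant (H2AvD-style)
fragment sets.

## Composite profiles

Anchored matrices extract `[anchor-flank, anchor+flank)` in fixed bins
(default 10 bp), reversing minus-strand rows so downstream is rightward,
scaled per million mapped reads when the signal source is a read track.
The subsampling composite draws, for each of 1000 samples, 10% of anchors
*without replacement* (subsets, matching the natural reading of
"samplings of genes"), takes the column-mean profile, and reports the
per-column median with 10th/90th percentile bands (linear interpolation).
Samples are drawn sequentially from one seeded generator, which makes the
profile reproducible and lets an independent re-implementation of the
loop match it exactly.  At `frac = 1` every sample is the full anchor set
taken in natural row order, so the center equals the plain column mean
bit-exactly.

## Synthetic study conditions

The generator emulates the data structure the analysis assumes, at a
scale that runs in seconds-to-minutes:

* **Genes** — 2,000 non-overlapping genes (800 paused+active, 600
  non-paused+active, 600 inactive) of 2–8 kb on a 20 Mb two-chromosome
  genome, placed left to right with random 1.5–4.5 kb gaps; random strand;
  polyadenylation site 50–200 bp inside the 3′ end.
* **Nascent reads** — per library: Poisson pause-zone counts (mean 120) in
  the true pause zone TSS+20..70, inside the ±250 bp search space;
  uniform gene-body density 0.25 reads/base on active genes; uniform
  background 0.0005 reads/base/strand on both strands, which makes
  background ≈ 1% of the ~1.6 M mapped reads per library — matching the
  activity test's null construction.  Knock-down multiplies the pause
  rate of 150 affected (paused-active) genes by 0.4 and their body
  density by 0.7, coupling promoter and body reductions the way a
  recruitment/initiation defect would.
* **Binding sites** — 300 promoter peaks (every affected gene plus random
  other paused-active genes; summit 75 bp upstream of the TSS) and 200
  intergenic peaks in gene-free gaps.  Bound peaks (all promoter peaks;
  90% of intergenic) carry a planted (GA)_n run on a recorded strand,
  sized so the width-10 GA-repeat PWM matches it at exactly
  `motif_repeat` = 4 starts.  90% of peaks get a synthetic
  independent-dataset region (summit ± 150) for high-confidence
  designation; the 10% without one, and the unbound 10%, provide the
  negative cases.
* **Nucleosome fragments** — per library: phased arrays downstream of
  active TSSs (8 nucleosomes, first center +135, spacing 175 bp, jitter
  SD 20 bp, mean 6 fragments each); a depleted promoter zone (TSS ± 100)
  of active genes with 20 expected centers per library, multiplied by
  `fillin_factor` = 3 at affected genes under knock-down; the same
  zone/fill-in structure at bound intergenic summits (100 of 200 planted
  to fill in, the rest serving as nulls); uniform genomic background
  0.002 centers/base.  Fragment lengths are a truncated normal —
  `truncnorm` on [99.5, 220.5) with mean 147 and SD 15, then rounded —
  so the 120–180 bp mass has a closed form for testing.

Determinism: one master seed; every stage/assay/condition/replicate
derives an independent generator by appending CRC32 hashes of its labels
to the seed sequence, so replicates are independent but a rerun is
byte-identical, including the written files.

What the generator does **not** emulate — and what passing recovery tests
therefore do not show about real data: mappability variation and repeats,
sequencing error, GC and MNase digestion bias, divergent/antisense
transcription at promoters, correlated biological replicate variation
(counts are independent Poisson, so the dispersion-free differential test
is exactly calibrated here but would be anti-conservative on
over-dispersed real replicates), and peak-calling noise (peaks are
consumed as given, never called).

## Numerical choices and degenerate inputs

Zero-read genes: pausing p = 1, activity p = 1, pausing index −1.  Empty
fragment sets and zero-depth libraries are valid and propagate as zero
counts.  Regions extending beyond a chromosome are clipped with a warning
and their clipped length is used.  An alpha below the minimal attainable
PWM p-value yields an unattainable threshold (above the maximum score)
with a warning rather than an error.  BH on an empty p-vector returns an
empty vector.  The gene table reader reports the first offending line
number; overlap rejection is opt-in since overlapping annotations are
legitimate in other contexts.

## Known limitations

The differential stage pools replicates and therefore cannot separate
biological from technical variability; the exact binomial split test is
anti-conservative under over-dispersion.  Single-base read assignment
makes results depend on the track convention used upstream.  The PWM
scanner's p-values are exact only under the 0-order background model.
Composite-profile bands are sampling percentiles, not confidence
intervals for the mean profile.
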