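# Methods

fitflow implements four statistical procedures for studying growth-rate
heterogeneity in isogenic microbial populations and its transcriptomic
consequences, together with synthetic-data generators that let every stage
be verified against planted ground truth.

## Transcriptome error rate from pileups

Aligned RNA-seq reads are summarised per genomic position in
samtools-mpileup 6-column text. The parser implements the full base-string
dialect: `.`/`,` count as reference matches (the two strands are pooled),
`ACGTacgt` as substitutions, `^X` (read start plus mapping quality), `$`
(read end) and `+n…`/`-n…` indel annotations are skipped, and `*`/`<`/`>`
placeholders count toward depth but neither matches nor mismatches.
Reference-N sites are excluded.

Because per-position error counts are tiny relative to coverage, rates are
only defined pooled: *rate = Σ mismatches / Σ depth* over the retained
sites of a transcriptome, a transcript, a coverage bin or a conservation
stratum. Before pooling, any site where **more than half** of the reads
mismatch is discarded as a presumed fixed genetic difference between the
sequenced strain and the reference (the inequality is strict, so
exactly-half sites are kept). Under this rule a homozygous variant —
emitted by the generator as 100 % mismatching reads — is removed exactly
and cannot bias the estimate.

Depth stratification groups sites by exact coverage and merges adjacent
depth levels in increasing order until every bin holds at least 100 000
positions (configurable); a short remainder is attached to the last bin and
flagged. Raw rates are dominated by lab-specific technical error, so
cross-experiment comparisons divide each experiment's rate by the mean rate
of its batch ("lab"); within a batch the relative rates average to 1 by
construction. A ratio rather than a difference keeps the normalisation
scale-free across labs whose baselines differ severalfold.

Numerical notes: parsing has a fast counting path for lines without dialect
markers and a character-level scanner otherwise; strict mode aborts on
malformed lines with the line number, tolerant mode (the default for real
data) skips them with a log entry. The streaming `estimate_error_rate`
never materialises sites and handles genome-scale input in flat memory.

## Growth-correlated expression metrics

Two per-gene metrics quantify expression change with growth:

* **subpopulation**: `log2(FPKM_fast + c) − log2(FPKM_slow + c)` between
  sorted fast- and slow-growing bins of one culture. The pseudocount
  `c = 0.1` FPKM removes zeros; with `c = 0` any zero FPKM is an error
  naming the offending genes. The metric is exactly antisymmetric under
  swapping the labels.
* **mean population**: for chemostat microarray data expressed as
  `log2(S_sample) − log2(S_ref)`, the mean log-ratio over all conditions at
  dilution rate 0.3 h⁻¹ minus the mean over conditions at 0.05 h⁻¹. The
  dilution rate imposes the culture's steady-state growth rate, so this is
  the classical whole-culture growth response. Genes missing in a required
  condition are excluded (microarray missingness).

Comparing the metrics uses Pearson correlation over shared genes plus
per-gene quadrant labels for scatter exports. Gene-set behaviour is tested
with a two-sample Kolmogorov–Smirnov statistic of the set against all
remaining genes, signed by the median difference; the pairing of samples is
absorbed into the per-gene log-ratio, which is the only well-defined
construction we found for a "paired" distributional shift test on such
data. Single-gene sets are computed but flagged low-power.

Expression-diversity summaries: per-sample gene counts in half-open FPKM
bands (default <5, [5, 30), ≥30); the transcriptome concentration curve
(cumulative expression fraction vs descending gene rank — monotone, concave,
ending at (1, 1)); a high/mid/low classification by mean log2 expression
across samples at ±1 s.d. (computed on the log scale; a zero-spread table
yields all "mid"); and per-replicon medians of a metric with z-scores
against the mean ± s.d. of the core nuclear chromosomes, which makes
selfish elements (2-micron plasmid, narnavirus, mitochondrion) directly
comparable to the chromosomal background.

## Microcolony imaging

Segmentation is per-frame and scale-free: a pixel is foreground if its
intensity lies beyond mean ± 2.5 s.d. of its frame, or its Sobel gradient
magnitude exceeds the frame's gradient mean + 3 s.d. (the union of the
three criteria). The intensity thresholds follow the stated procedure; the
edge threshold's form is ours, chosen σ-relative so the whole mask is
invariant under affine intensity rescaling. Foreground pixels are grouped
by 8-connected component labelling (diagonal cell contacts are physical);
components under 5 px are dropped as noise.

Tracking matches cluster centroids between consecutive frames by
mutual-nearest-neighbour with a 15 px displacement cap, ties broken by
smaller distance then smaller area change; unmatched clusters start new
tracks and gap frames are not bridged. Tracks that fail to at least double
in area over the observation (final ≥ 2 × initial, inclusive) are flagged
and excluded from growth statistics. When colonies touch — detected as
8-adjacency of clusters from distinct tracks or as one cluster overlapping
the dilated previous footprints of two or more tracks (a merger) — all
involved tracks keep only records strictly before the touch time.

GFP quantification per colony and frame: signal pixels are those above the
GFP frame's mean + 2 s.d. intersected with the colony; sum and mean are
over signal pixels, while the maximum is over the full colony area so that
a single bright punctum (a Rad52-style repair focus) always registers.

**Measurement limitation.** Threshold segmentation includes a ~1.5 px rim
of partially covered and edge pixels around every colony. The relative
area error is therefore large for small colonies (+50 % at radius 4 px)
and falls below 15 % only for radii ≳ 25 px; the rim also biases the
log-area slope low by roughly `1.5/R` per unit time at radius `R`. The
synthetic generator's defaults give every colony a common final area of
6000 px so that the max-slope window always sits at large radius, keeping
the recovered rates within ~4–5 % of truth; with other geometries the bias
can be larger and should be checked against the generator's truth table.

## Growth rates and the slow-growing fraction

The growth rate of a colony is the maximum OLS slope of ln(area) against
time over any contiguous window of ≥ 3 records spanning ≥ 180 min with
R² ≥ 0.95, converted to h⁻¹. The max-slope rule ignores lag phases and
late crowding. A window with zero log-area variance is treated as a perfect
fit (R² := 1, slope 0), which is harmless under the max rule. Tracks with
no qualifying window report `qualified = False`.

The slow-growing fraction is read from the empirical CDF of the qualified
rates (n ≥ 50 required). The CDF's local slope is estimated by OLS over a
sliding window of `max(11, 5 % of n)` consecutive order statistics; the
steepest window (ties broken toward the median rate) defines the tangent
point x₀ and slope s, and the tangent `t(x) = F(x₀) + s(x − x₀)` crosses 0
and 1 at x_lo and x_hi. Mass below x_lo is unexplained slow, mass above
x_hi unexplained fast, and

    fraction_slow = max(0, F(x_lo) − (1 − F(x_hi))).

For an exact uniform grid the tangent explains 100 % of the data; for a
single Gaussian the two leftover masses cancel by symmetry. The statistic
is invariant under shifting all rates and equivariant under positive
scaling. Windows of tied rates are rejected by a relative variance cutoff
(10⁻¹²), and an all-tied sample raises a degenerate-distribution error.

**Conservatism.** For a mixture with a well-separated slow component of
weight w, the ECDF at the tangent point is 0.5 + w rather than 0.5, so the
tangent's intercepts are asymmetric about the mode and the majority
component leaks more mass below x_lo than above x_hi. The statistic
therefore under-reports the planted weight — analytically 0.062 for
w = 0.10 with components N(0.35, 0.02) and N(0.15, 0.02) — while remaining
zero for symmetric unimodal samples and monotone in w. The implementation
is tested against this analytic value (computed by an independent oracle on
the exact mixture CDF), not against w itself. The smoothing window barely
affects the value (0.052–0.067 over windows of 100–5000 order statistics),
so this is a property of the tangent construction, not of our smoothing
choice.

## Synthetic data

Generators are deterministic given a seed and emit truth tables sufficient
to score every downstream estimate.

* **Pileups**: per-position depth is negative-binomial (mean 30,
  dispersion 0.3 by default — overdispersed RNA-seq coverage), mismatches
  binomial at the planted rate with the substituted base uniform over the
  three alternatives, planted variant positions emit 100 % mismatches, and
  ~1 % of lines carry dialect markers to exercise parsers.
* **Expression**: baseline log2 FPKM is normal (mean 5, s.d. 2 — heavy
  tailed on the linear scale so concentration curves are realistically
  skewed); the subpopulation and mean-population signals are bivariate
  normal with configurable correlation and s.d. 0.5 log2 units, plus
  per-set planted effects applied to both contrasts; the chemostat table
  has six conditions per dilution rate (the crossed nutrient-limitation
  design of the study it emulates) with 0.2 log2 units of condition noise.
* **Time-lapse**: colonies are anti-aliased dark disks (intensity 60 on a
  200 ± 4 background) growing as `A₀·e^{rt}` with rates uniform on
  0.15–0.40 h⁻¹, 13 frames at 60-min spacing; the truth mask is coverage
  > 0.5 and the recorded truth area is the realized pixel count, so
  segmentation is scored against what was actually rendered. The GFP
  channel carries a uniform histone-like colony signal plus optional
  single-pixel foci at mean + 10 s.d. Collision plans reposition a colony
  pair so their disks first overlap at a chosen frame with a clean > 3 px
  gap one frame earlier.
* **Growth rates**: i.i.d. draws from a Gaussian mixture, with the
  analytic tangent-statistic value of the exact mixture CDF recorded as the
  oracle.

What the generators do not emulate: read-level sequencing artifacts
(quality decay, strand bias, PCR duplicates), spatially varying
illumination or focus drift in imaging, cell-level texture inside colonies,
and microarray normalisation artifacts in the chemostat tables. Passing
tests therefore demonstrate the correctness of the computations under the
stated statistical assumptions, not robustness to every instrumental
artifact of real data.

## Problem sizes used in tests

The shipped tests and the acceptance script run at: 10⁶ pileup positions ×
depth 30 for rate recovery (binomial s.e. ≈ 1.8 × 10⁻⁶ at a planted 10⁻⁴);
10⁵ positions × depth 900/225 for the two-lab normalisation (≈ 1.5 %
rate s.e., so the ± 5-point excess check sits at ≈ 3 σ); a 15-colony
1200 × 1200 stack for imaging; n = 10⁴ rate samples for the tangent
statistic; and 5000 genes for the expression metrics. These sizes make all
sampling-noise tolerances ≥ 3 σ margins.
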