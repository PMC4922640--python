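# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data design, and the limits of what the test suite demonstrates.

## Count model and dispersion estimation

Window (or gene) counts are modelled as negative binomial: for window *w*,
sample *i* in group *g*,

    y_wi ~ NB(mean = mu_wg * N_i,  dispersion = phi_w)

with N_i the effective library size (library size × normalization factor)
and Var(y) = mu + phi·mu². Counts are first equalized to a common library
size N\* (the geometric mean of the effective sizes) as continuous
pseudo-counts y·N\*/N_i; the gamma-function form of the NB likelihood is
evaluated directly at non-integer values. This plain rescaling keeps the
estimator exactly invariant to jointly scaling one sample's counts and
library size, at the cost of a mild global pseudo-scale dependence on the
geometric mean (covered by a tolerance in the tests).

Dispersion is estimated from the conditional (qCML) log-likelihood of each
group's counts given its sum, which is free of mu under equalized sizes.
Per window (dropping phi-free terms, r = 1/phi, n samples, z the group sum):

    l_w(phi) = sum_g [ sum_i lgamma(y_i + r) − n·lgamma(r)
                       + lgamma(n·r) − lgamma(z + n·r) ]

* **Common dispersion** maximizes `sum_w l_w(phi)`.
* **Tagwise dispersion** maximizes, per window, the weighted likelihood
  `l_w(phi) + prior_df · (1/W)·sum_v l_v(phi)` — the window's own evidence
  plus `prior_df` windows' worth of the average (common) evidence. As
  `prior_df → ∞` every window collapses onto the common estimate; the
  default `prior_df = 10` follows the long-standing convention for this
  class of estimator.

**Numerics.** Both maximizations are performed on a fixed 121-point
log-spaced grid over phi ∈ [1e-6, 10], followed by quadratic interpolation
of the maximizer in log-phi (clamped to ±half a grid step; boundary maxima
return the bound). The grid makes the shared average-likelihood term in
the tagwise objective an O(W·P) computation instead of O(W²) and is fully
vectorized; interpolation error is orders of magnitude below the sampling
error of any realistic data set (common-dispersion recovery lands within
[0.15, 0.25] when the truth is 0.2 with 2000 windows). A cross-check
against the canonical qCML implementation on a 300-window fixture agreed
to four decimals on the common dispersion.

## Exact test

With equalized sizes, group sums are NB with sizes n_A/phi and n_B/phi and
a common per-sample mean, so conditional on the total t the split follows
a negative hypergeometric law independent of the mean (binomial with
proportion n_A/(n_A+n_B) when phi = 0). Group pseudo-sums are rounded to
the nearest integer, the conditional pmf is computed in log space and
normalized by log-sum-exp, and the two-sided p-value is twice the smaller
tail, capped at 1 (`doubling`; the sum-of-smaller-probabilities rule is
available as `smallp`). Doubling is the default because it is monotone in
the observed split. The implementation matches brute-force enumeration of
the conditional distribution to 1e-8 and yields a null p < 0.05 rate of
~0.05 at mean 50, phi 0.1, 6 vs 6.

Fold changes are `log2((S_B/n_B + 0.5)/(S_A/n_A + 0.5))` on pseudo-counts
(the 0.5 prior guards empty groups); direction is hyper iff log2FC > 0,
with the second group of every comparison the higher-dose group.

## Normalization

* `libsize` (methylation default): factors 1, effective size = library size.
* `tmm` (RNA-seq default): trimmed mean of M-values — reference sample is
  the one whose upper-quartile relative abundance is closest to the mean
  upper quartile; per sample, log2 ratios against the reference are
  trimmed 30% (two-sided) by M and 5% by A, averaged with delta-method
  inverse-variance weights, and factors scaled to geometric mean 1.

TMM exists because composition differences (a few very abundant or
systematically shifted features) bias pure library-size scaling; the
expression fixtures demonstrate this concretely (see below).

## RAM calling filters

Candidates are windows with nominal p < alpha (default 0.001; BH q
thresholding is a flag). The two post-filters:

1. **Consistency (i).** Per candidate, each sample's CPM is compared to
   the *other* group's median CPM: a higher-group sample agrees with a
   hyper call if it exceeds the lower group's median, a lower-group
   sample if it falls below the higher group's median (reversed for
   hypo). Retained iff at least `min_fraction` (default ½) of the samples
   agree in *both* groups. Medians of CPM were chosen because the filter
   exists to guard against single-sample outliers that NB testing is
   sensitive to; a ties-exactly-at-half case counts as agreeing.
2. **Flanking (ii).** Retained iff (a) one of the two overlapping
   neighbour windows (starts ±50 bp) has p < 0.05 in the same direction,
   or (b) another *candidate* of the same direction starts within 500 bp
   ("two windows in a 500 bp stretch" = the pair including the candidate
   itself). Same-direction is required in both branches so corroboration
   means the same methylation change, and branch (b) demands candidacy
   (not mere sub-threshold significance) of the partner window.

Both filters only remove windows and are idempotent. Overlapping RAM
windows are merged only for BED reporting, never before statistics.

`alpha = 0.001` on nominal p is the package default: with the two filters
it produces sex-contrast empirical FDR estimates in the ~10% regime on
realistic synthetic signal fractions, and it is a config knob, not a
constant.

## Sex-based empirical FDR

Eight random sets of six males and six females (drawn without replacement
within a set, independently across sets) are pushed through the identical
pipeline object (same coverage filter, alpha, filters). The estimate is
the mean over sets of the autosomal fraction of RAM windows; sets with no
hits are excluded with a warning. The estimate is an upper bound on the
pipeline's FDR exactly to the extent that autosomal sex differences are
absent; injected autosomal sex effects raise the estimate, not the
exposure contrast's realized FDR, which the tests verify (20 replicates,
one-sided sign test).

Because the eight sets share subjects and windows, per-set hit counts are
positively correlated; calibration checks therefore compare the mean
autosomal fraction against a binomial envelope built at single-set scale
rather than pooling sets as if independent.

## Annotation

All intervals are 0-based half-open; tracks are merged on load.

* CGI context: island on any overlap; otherwise shore at edge distance
  ≤ 2 kb, shelf ≤ 4 kb, else open sea. Distances are measured from island
  *edges* (the standard shore/shelf convention); a window merely touching
  an island is a shore at distance 0, not an island.
* Nearest TSS: from the window midpoint (a point-to-point distance is
  cleanest for a constant-width window), signed positive downstream in
  the gene's reading direction; ties break to the lower TSS coordinate,
  then the lexicographically smaller gene id. The within flag defaults to
  5 kb.
* Features: promoter −500..+100 bp of the TSS in reading direction
  (reflected on the minus strand); TSR ±50 bp of the TSS (a configurable
  stand-in for experimentally curated transcription start regions, which
  depend on proprietary databases); exon/intron from exon models; gene
  locus = transcript extent; intergenic = none of the genic/promoter/TSR
  classes; repeat overlap is an orthogonal flag.
* Set accounting reports per-set sizes, pooled total (sum of sizes),
  union, all k-way intersections, exact Venn cells, and the
  exactly-one-set count.

Interval classes are resolved by binary search on merged sorted intervals
and are property-tested against brute-force oracles on hundreds of random
toy instances (which caught the touching-island edge case above).

## Expression integration

Gene-level differential expression runs the same NB machinery with TMM
normalization; all-zero genes are dropped with a log entry; `is_de`
requires q < 0.10 *and* fold change ≥ 2. Integration pairs each gene with
its strongest (smallest p) RAM within 5 kb of the TSS when the gene's
expression is nominally significant (p < 0.05, configurable) and the
expression and methylation effect signs oppose. "Inverse correlation" is
implemented as sign opposition of effect estimates, not a sample-level
correlation coefficient: with ≤ 6 samples per group a per-gene correlation
is unstable, and the scientific claim is directional.

## Synthetic-data design

The generator is first-class, tested code; fixed seeds give byte-identical
output, and per-sample PRNG streams are keyed by (seed, sample id) so
adding samples never perturbs existing ones.

* **Genome.** Chromosome lengths uniform within ±20% of the requested
  mean; optional X-like and Y-like chromosomes. CGI and gene counts are
  exactly Poisson per chromosome (features are placed by a uniform-spacing
  construction that preserves the drawn count while guaranteeing
  non-overlap); repeats are placed independently and may overlap anything.
  Gene models carry strand, TSS at the 5' end, and alternating exon/intron
  partitions.
* **Reads.** Each chromosome is divided into 50 bp cells. Cell rates are
  proportional to length, boosted by the CGI enrichment factor on island
  overlap, adjusted for sex (Y-like × leakage, default 0, in females;
  X-like × dosage, default 2, in females), scaled to the requested depth,
  and then multiplied by 2^log2FC in spiked regions for the affected
  group. Each cell draws an independent Gamma(1/(M·phi), mean 1)
  multiplier (M = cells per window) and Poisson reads given its rate, so
  the count in any window-aligned run of M cells is *exactly*
  NB(mean, phi); reads are placed uniformly within their cell. Depth is
  normalized before spike multipliers so spikes change local, not global,
  abundance.
* **Exposure cohort.** 6 samples per trichotomized group (non-detect
  < 0.83, low 3.50–5.79, high 35.44–96.76 ng/g), concentrations uniform
  within each range, sexes alternating within groups. Concentrations in
  the inter-group gaps map to "unassigned" and are excluded from
  comparisons. Default simulated depth gives a mean of ~50 reads per
  window — deep enough for the coverage filter to retain most windows, and
  a config knob rather than a claim about any particular study.
* **Truth.** Spikes are runs of k consecutive grid windows (default 4)
  sharing one signed log2FC; optionally centred on gene TSSs and coupled
  to expression effects of the opposite sign. Truth windows are the
  fully-inside tiled windows; windows half-overlapping a spiked region
  carry a diluted effect and are scored as neither required recoveries
  nor false calls.
* **Expression.** Per-gene log-normal baselines around the requested
  mean; NB sampling per gene × sample; truth genes shifted by 2^log2FC in
  the higher group of their comparison. Fixtures pad the annotated genes
  with a few hundred null genes: a transcriptome that is mostly null is
  what makes normalization meaningful (a degenerate fixture in which every
  gene was differential in the same direction shifted all fold changes by
  ~1.25 log2 units and motivated this rule).

**Sex-balance in FDR fixtures.** Calibration fixtures give the X-like and
Y-like chromosomes equal lengths so the female 2× X dosage exactly offsets
the missing Y reads. Without that balance, per-sample depth normalization
turns the sex-structural signal into a genome-wide composition shift that
makes every autosomal window truly non-null (≈ −0.18 log2FC at miniature
scale) — a real phenomenon, but one that would invalidate the premise of
an "all autosomal hits are false" calibration check. On a human-scale
genome the imbalance is negligible (chrY ≈ 2% of the genome).

## What the synthetic tests do and do not show

They demonstrate the pipeline's statistical correctness under its own
model: calibrated type-I error, dispersion recovery, high power on clean
rectangular spikes, a conservative FDR bound, and exact interval
arithmetic. They do not emulate mappability gaps, GC or fragment-length
bias, spatially autocorrelated background methylation, duplicated reads,
or irregular region shapes, so real-data performance — in particular the
post-filters' behaviour on ragged true regions — is not certified by a
green suite.

## Problem sizes and defaults

Simulated studies use miniature genomes (hundreds of kb across a few
chromosomes, mean ~50 reads per window, 6 samples per group; 4 per group
for expression), 10–30 spiked regions, and 3–20 replicates per check —
sizes chosen so the full suite exercises every pathway end to end while
each individual check remains a well-powered hypothesis test. Every
default (window 100/step 50, coverage >20 in ≥3 samples, alpha 0.001,
prior_df 10, flank p 0.05, 500 bp stretch, FDR 0.10/2-fold, 5 kb TSS
rule) is a `PipelineConfig` field or function argument.

## Known limitations

* Two-group exact testing only; the multi-factor GLM route (covariates,
  gestational age adjustment) is out of scope, with a config flag reserved.
* The exact test's pseudo-count rounding introduces sub-ulp-of-p
  discreteness at very low counts; at the coverage-filter floor (>20
  reads) the effect is negligible.
* Spatial correlation between overlapping windows is not modelled;
  overlapping RAM windows are reported individually (merged only in BED
  output), so window counts are not independent discoveries.
* The empirical FDR transfers to exposure contrasts only insofar as the
  sex contrast's signal structure resembles the exposure signal; it is an
  upper bound, not an estimate of the realized rate.
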