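# Methods

## Relative quantification

Amplification efficiency is estimated per gene from a dilution standard
curve by ordinary least squares of Cq on log10 input: `E = 10^(-1/slope)`,
with perfect doubling at slope −3.3219 (E = 2).  Curves with r² ≤ 0.99
are accepted with a warning rather than rejected, mirroring common assay
acceptance practice; non-negative slopes are errors because more template
must lower Cq.  Genes without a curve default to E = 2 (logged).

Technical replicates are collapsed to their arithmetic mean; the quality
filter keeps a sample×gene measurement only when the *sample* SD
(n−1 denominator) of its replicates is strictly below 0.05 cycles.  The
sample SD is the conservative reading of an unqualified "SD" and matches
common qPCR software.  For duplicates this means an absolute difference
below 0.0707 cycles.  The threshold applies on the Cq scale, where the
filter is stated alongside the duplicate design.  A single replicate has
SD 0 and passes, with a logged note.

The efficiency-corrected ratio is computed in log2 space
(`log2 R = ΔCq_t·log2 E_t − ΔCq_r·log2 E_r`, `ΔCq = calibrator − sample`)
to avoid overflow, and exported on the linear scale.  The calibrator is a
modelling choice the original instrument software hides; the default —
per-gene mean of QC-passing control-group mean Cq — centres control-group
ratios near 1, which reproduces the conventional reporting scale.  A named
calibrator sample and the grand mean are available alternatives.

Outlier removal is a single pass: mean and sample SD are computed once
over all candidate ratios and values beyond 1.96·SD are dropped, with no
re-iteration.  This is the minimal reading of "removed from the analysis";
iterating would remove more.  The pass is pooled across groups by default
(per-group available), and the small-n masking effect — a gross outlier
inflating the SD enough to retain itself — is deliberately left visible
and is demonstrated in the tests.

## Two-group inference

The rank-sum test enumerates the exact null distribution of the
Mann–Whitney U (counting recursion, exact integer arithmetic) whenever the
pooled sample is tie-free, min(n) ≤ 10 and max(n) ≤ 20; otherwise it uses
the normal approximation with tie-corrected variance and a 0.5 continuity
correction.  Two-sided p doubles the smaller tail, capped at 1.  Ties
always route to the approximation (midranks); a fully tied pooled sample
returns p = 1 with method "degenerate".

The Hodges–Lehmann shift is the median of all n_x·n_y pairwise
differences, oriented treatment − control.  CI endpoints are the order
statistics at ranks obtained by inverting the same null distribution
(exact where available, else approximate); the discrete inversion makes
the interval mildly conservative — simulated coverage at n = 10 per group
is ≈ 95.9% for a nominal 95%.  Quartiles use linear interpolation between
order statistics, the default of mainstream statistical software, so
reported medians/IQRs are reproducible elsewhere.

## Stability scoring

A normalizer's stability is the sample SD of its log2 signal across a
compendium of independent arrays of the relevant tissue; the *expected
maximal fold change* converts it to the user-facing scale as
`2^(z·SD)` with z = 1.96 (central 95% normal mass; configurable).  The
original web-tool computation is replaced by the same statistic on any
local or simulated compendium matrix; tissue/platform filtering is
metadata the user applies upstream.  Candidate ranking sorts ascending by
SD (ties broken by gene id for determinism) and, when two-group labels
are supplied, vetoes genes whose rank-sum p-value falls below a floor
(default 0.05) — a very stable gene that responds to the treatment must
not be the normalizer.

## Moderated-t differential expression

Quantile normalization replaces each column's order statistics by the
cross-column mean of sorted values; within-column ties receive the mean of
the reference values their positions span.  On tie-free data the
operation is idempotent and equalizes column distributions exactly.

The DE stage implements the standard hierarchical model for per-gene
variances: s²_g on d df around a scaled-F prior (d0, s0²), estimated by
moment-matching on log s² (digamma/trigamma identities; the trigamma
inverse by Newton iteration).  The posterior variance
`s̃² = (d0·s0² + d·s²)/(d0 + d)` yields a moderated t on d0 + d df (capped
at the pooled residual df).  The B statistic uses the mixture-quantile
estimate of the prior effect variance with default prior DE proportion
0.01.  This is an independent implementation, not a wrapper; a test
verifies numerical agreement with the Bioconductor reference
implementation on a simulated fixture (t and p to ~1e-6, prior moments to
~1e-4).  Degenerate inputs: all-equal variances are read as a point-mass
prior (d0 = ∞, s0² = the common value, so shrinkage is a no-op); a
negative moment estimate also takes d0 = ∞ with a warning.  BH adjustment
delegates to statsmodels and is verified against a hand-rolled step-up.

Probe-level preprocessing (background correction, summarization) is out
of scope; the stage consumes pre-summarized log2 matrices, so third-decimal
differences from pipelines that re-summarize raw arrays are expected.

## Synthetic data

The qPCR generator draws latent log2 expression
`x_ij = μ_j + β_j·treated + a_i + ε_ij` and inverts it through the
efficiency to Cq with replicate noise:
`Cq_ijr = c_j − x_ij/log2(E_j) + τ_ijr`.  The animal-level effect `a_i`
enters every gene of a sample identically — exactly the variation
normalization exists to cancel — so the expected log2 Pfaffl ratio is
`β_target − β_reference`, making both unbiased recovery (null reference)
and the sign flip (affected reference) provable predictions rather than
tuning targets.  Defaults describe a realistic chronic-treatment rodent
design: 13 animals per group, duplicate wells, animal-scaling SD 0.3,
per-gene biological SD 0.2 (log2 units), replicate noise 0.02 cycles,
Cq intercept 28 cycles.  Noise is Gaussian on the log2/Cq scales; the
generator does not emulate amplification kinetics, plate spatial effects,
heavy-tailed biological variation, or RNA-quality covariation across
genes, so passing tests demonstrate correctness of the computation under
the stated model, not robustness to every real-data pathology.

The compendium generator draws independent Normal(median, SD) log2
signals per gene across 80 arrays by default; the DE generator draws
per-gene variances from a scaled inverse chi-square (d0 = 4, s0² = 0.05
by default) and shifts a chosen fraction of genes by ±1 log2 unit.  All
generators are deterministic given their seed.

## Evidence curation

The packaged evidence table codes one printed line of the source review —
a tissue × dose × duration × assay combination within a study — as one
experimental set-up, the granularity that reconciles to the published
totals (49 set-ups: 31 NS, 15 significant upregulation, 1 significant
downregulation, 2 direction-only).  Lines reporting a direction without
statistics, or with n = 1, are coded `direction_only`; two lines that
print two fold changes for one set-up (dose ranges) carry both values and
count once.  The affected-normalizer tally counts, by default, distinct
(study, canonical normalizer) combinations among significant-upregulation
set-ups — the reading that reproduces the published count of 4 — and a
per-entry variant (`distinct=False`, yielding 5 on the packaged table) is
provided because the granularity of that published count is ambiguous.
Alias matching (β-Actin ↔ Actb, β-tubulin ↔ Tubb, …) is explicit packaged
data, case-insensitive, never heuristic.  A checksum test pins the
transcription.

## Known limitations

* The wet-lab Cq values behind the motivating experiments are not public;
  the qPCR stages are therefore validated by parameter recovery on the
  generative model, not against the original instrument output.
* Exact rank-sum inference refuses ties; with heavily tied data all
  inference is approximate.
* The B statistic's prior effect variance uses the mixture-quantile
  estimator with default limits; with very few genes it is noisy (a
  warning fires below 10 genes).
* Multi-plate designs are checked for group balance only; no between-plate
  batch correction is attempted.
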