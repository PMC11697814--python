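# Methods

This note documents the statistical models, the synthetic-data generator
and the numerical choices behind `oostage`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Differential expression

Raw counts are modelled per transcript as negative binomial with a
log-linear mean, `log mu = log s_j + b0 + b1 * x_j`, where `s_j` is the
median-of-ratios size factor of sample `j` and `x_j` indicates the SN
stage.  `b1 / ln 2` is the log2 fold change (positive = higher in SN).

* **Dispersion.**  Per-transcript method-of-moments estimates are computed
  within each stage (so the condition effect does not inflate them) and
  pooled, then a parametric trend `alpha(mu) = a0 + a1/mu` is fitted by
  least squares over transcripts with base mean > 1; the trend value at a
  transcript's base mean is used in the GLM (floor 1e-8).  The generator
  draws its dispersions from the same family, so the test is correctly
  specified on synthetic data; on real data the trend is the usual
  variance-stabilising compromise.
* **Fitting.**  Fisher scoring, vectorized across all transcripts at once;
  convergence at max |Δβ| < 1e-10 (hard cap 200 iterations).  The run on a
  5,000 × 25 matrix takes well under a second.
* **Hauck–Donner guard.**  Coefficients are clamped to |LFC| ≤ 10.  Without
  the clamp, a group with all-zero counts drives `b1 → −∞`, the scoring
  weights collapse, and the Wald statistic loses power exactly where the
  signal is strongest (the "SN-missing" transcripts).  At the cap the Wald
  z remains large and such transcripts rank correctly.
* **Inference.**  Two-sided Wald p-values, Benjamini–Hochberg adjustment.
  Rows are ordered by padj, ties broken by |LFC| descending, then
  transcript id — the ranking consumed by the classifier is therefore
  invariant to input row order.
* **Shrinkage.**  An optional normal-prior shrinkage reports
  `lfc * tau^2 / (tau^2 + se^2)`; the prior width `tau` is matched to the
  90th percentile of |LFC| among transcripts above the median base mean,
  which keeps the prior from collapsing under the very large standard
  errors of low-expression transcripts.  Shrunken values are reported
  only; ranking always uses the raw Wald results.

The label-swap identity (exchanging NSN and SN negates every LFC) holds to
1e-6 and is enforced in the tests.

### Detected transcripts, SN-missing filter, quartile bias

A transcript is "detected" in a sample at ≥ 1 count.  The depth-matched
comparison restricts samples to a total-read band and applies the Wilcoxon
rank-sum test, exact for group sizes ≤ 25, otherwise the normal
approximation with continuity correction.  The SN-missing rule generalizes
the 7-of-9 / 10-of-16 thresholds to fractions with `ceil(frac × n)`, so it
scales to other cohort sizes while reproducing the original integers at
9 NSN / 16 SN.  Expression quartiles are assigned over transcripts
expressed in the chosen stage, ranked by mean normalized expression with
ties broken by row order; quartile sizes differ by at most one.  The
quartile-bias test is a Pearson chi-square of the selected set's quartile
counts against the quartile proportions of all expressed transcripts.

### Over-dispersion screen

Within each stage a log-log linear trend of CV² on mean is fitted across
transcripts on normalized counts; transcript variance is compared to its
trend expectation with `(n−1) s² / σ²_trend ~ χ²_{n−1}` (upper tail), and
BH-adjusted at q < 0.05.  This is a documented stand-in for an unnamed
published procedure: its flagged counts are calibrated on synthetic data
(type-I ≤ 7% at q < 0.05; a 10× variance inflation is flagged in ≥ 18/20
replicates) and are not expected to match any particular published count.

## Stage classifier

Panel: significant transcripts (padj < 0.05) intersected by identity with
an external reference DEG list (direction agreement optional via a flag —
the overlap definition does not require it), split by LFC sign, top 65
down / top 35 up by FDR.  Construction errors out rather than emitting an
undersized panel.

Reference fit: median-of-ratios normalization, per-marker Z-score (mean/sd
stored), PCA by SVD with a deterministic sign convention (largest-|loading|
entry positive), default k = 2 components, per-stage centroids.
Zero-variance markers are dropped with a warning.

Calling: query samples are normalized against the *reference* geometric
means (median ratio over shared positive transcripts), scaled with the
stored statistics (markers absent from the query — at most 20% of the
panel — are imputed at the reference mean, i.e. Z = 0), projected with the
stored loadings, and assigned the nearer centroid when
`d_near / d_far ≤ 0.8`, else `unclassified`.  The published analogue
assigned stage by visual cluster membership in UMAP/PCA, which is not
reproducible; the distance-ratio rule is the deterministic, thresholded
replacement, and the 0.8 default is a free parameter.  Equidistant samples
are always unclassified.  UMAP (fixed seed 42) is provided for
visualization only and never enters the call path.  Bulk samples are
classified identically to single cells; low replicate numbers deserve the
usual caution.

## Methylome

Coordinates are BED-style 0-based half-open internally; Bismark-style
1-based inputs are converted on read.  QC keeps libraries with mapping
efficiency > 10% and > 500,000 distinct CpGs (both strict), and flags
somatic contamination when global non-CpG methylation falls below 1%
(the published bounds are not quantified; 1% sits well below the 4–5%
non-CpG level of genuine oocytes).  An MII comparison needs no special
handling — MII is just another stage label.

Domain segmentation classifies a pooled-methylation tiling at < 25% /
> 70% and merges contiguous same-class runs (uncovered windows break
runs); merging is idempotent and the classes partition covered territory.

The DMR procedure:

* Per iteration, pseudobulk groups (3 × 4 cells per stage) are drawn
  without replacement; iteration *i* uses sub-seed `(seed, i)` so any
  iteration is independently reproducible.
* A domain is testable in an iteration only if all 6 groups have ≥ 10
  pooled calls in it; the consensus denominator is the number of testable
  iterations.
* The per-iteration test is a binomial GLM (logit link) on group-level
  counts with stage as the only predictor.  Because stage is the only
  covariate, the MLE is saturated in stage and the Wald test reduces
  exactly to the pooled log-odds-ratio z test — implemented in closed form
  and cross-checked against an iteratively fitted GLM in the tests.
  Perfect separation (a zero margin) falls back to Fisher's exact test on
  the pooled 2×2 table.
* The stage difference is computed on counts pooled across each stage's
  three groups (robust to uneven group coverage, switchable), and a call
  requires p < 0.05 **and** a strictly greater than 10-point difference.
  The per-iteration alpha is deliberately plain: the consensus-over-100-
  iterations rule, not the per-iteration threshold, carries the error
  control.
* Consensus: a domain enters the DMR table when called with its dominant
  sign in ≥ 50% of testable iterations.  The reported mean difference is
  averaged over the calling iterations, so every table row satisfies
  |mean difference| > threshold.

Feature enrichment draws `n_random` count-matched random domain sets from
the universe; Fisher's exact test uses the query column against the
per-draw-scale mean random column (a LOLA-style same-size background),
log2 fold enrichment compares the query overlap fraction to the mean
random fraction, and zero margins receive the Haldane–Anscombe 0.5
correction.

## Chromatin windows

"Running windows" are non-overlapping 2-kb tiles (a ~1.36 M window count
over the mouse genome is consistent with a plain 2-kb tiling; the step is
configurable).  RPKM = count / (width/1000) / (library/1e6).  Validity:
0.04 ≤ input RPKM ≤ 2 (exclusion strict on both sides, so boundary values
are retained).  Enrichment: mark RPKM strictly > 1; a window's category is
the exact combination of enriched marks — seven named classes plus an
explicit "none" (valid windows without any enriched mark must go
somewhere).  Window→domain assignment uses midpoint containment.  Random
interval sets for category enrichment are count-matched with the query's
(permuted) length distribution, placed uniformly over merged valid-window
territory; overhang into invalid territory is harmless since only valid
windows are tallied.  Replicate tracks may be supplied merged or averaged
with equal weight; a pairwise Pearson report is provided for QC.

Interval overlap everywhere uses binary search over per-chromosome sorted,
merged arrays and is verified against a brute-force all-pairs oracle.

## Synthetic data

One `SimConfig` seeds all three generators through per-modality
sub-streams; identical configs give byte-identical outputs.

* **Counts.**  Base transcript abundances are log-normal (sd 2) and drawn
  from a dedicated `abundance_seed`, so cohorts generated under different
  seeds share one underlying transcriptome — the property that makes
  cross-cohort classification meaningful.  Library depths are uniform over
  1.9–5.3 M reads.  The SN signature: 20% of transcripts degraded (means
  × 0.25), an "SN-missing" subset (5%) drawn from the bottom two
  base-expression quartiles and zeroed in ≥ 10/16 of SN cells, and an
  explicitly up-regulated subset (7%, × 4) — a degradation-only model
  yields no strong up-regulated candidates, yet the marker panel needs 35
  of them, so up-regulation (transcript stabilisation relative to the
  degrading pool) is a generator parameter.  Counts are negative binomial
  with an `a0 + a1/mu` dispersion trend.  `frac_silenced = 0` switches the
  entire signature off, giving an exact two-group null.  Degradation
  magnitudes are free parameters of the generator, not literature claims.
* **Methylomes.**  Domains are tiled per chromosome by drawing classes
  (30% unmethylated / 49% intermediate / 21% methylated — the GV-oocyte
  class proportions) with exponential lengths (means 80/60/80 kb, minimum
  35 kb, the tens-of-kb scale of oocyte methylation domains).  True
  methylation per domain: U(0,25) / U(25,70) / U(70,100).  Twenty planted
  hyper-DMRs raise the SN truth of intermediate domains by 30 points
  (their NSN base is drawn low enough never to clip).  Each of 12 NSN +
  28 SN cells observes an independent 15% Bernoulli subsample of the
  ~8-per-kb CpG sites; calls are single-read 0/1 draws ("read" mode) or
  exact fractional expectations ("expectation" mode, used for limit
  tests).  Non-CpG sites methylate at 4% (0.2% in planted contaminated
  cells, which also get boosted CpG methylation).  The default genome is
  2 × 42 Mb: large enough for ≥ 500 *null* intermediate domains per seed,
  and with per-domain call depths at which a persistent sampling offset —
  the finite-cell artefact that dominates false calls, since the 12 NSN
  cells are reused in every iteration — rarely exceeds the 10-point rule.
  These sizes are the package's benchmark conditions, stated here so the
  planted-truth results are interpretable.
* **ChIP windows.**  Category proportions default to the valid-window
  shares of the seven joint categories in GV oocytes, "none" the
  remainder.  Enriched marks draw RPKM log-uniformly from (1.5, 6), absent
  marks from (0.02, 0.8); degenerate ranges (lo = hi) give exact constants
  for forced-separation tests.  A 10% fraction of windows gets input RPKM
  forced outside the validity band (half below, half above).

**What the generator does not emulate:** read-level errors and bisulfite
conversion failure, within-stage biological heterogeneity of methylation
(cells share their stage's domain truth), linked CpG co-methylation,
genuine coupling between expression, methylation and chromatin categories
(each modality is planted independently unless a test constructs the
coupling), and batch effects between cohorts.  Passing the planted-truth
benchmarks therefore demonstrates correctness of the procedures under
their stated assumptions, not performance on real oocyte data.

## Known limitations

* The NB dispersion trend is global; transcripts with idiosyncratic
  dispersion far above the trend are tested slightly liberally (the
  over-dispersion screen exists to find them).
* The DMR caller tests pre-defined domains only; it neither merges nor
  splits intervals, and single-CpG resolution is out of scope.
* With few cells per stage, persistent pool offsets bound achievable
  false-positive control for small, shallow domains regardless of the
  iteration count; domains below the coverage rule are simply reported
  untestable.
* The classifier assumes the query shares the reference's expression
  scale after median-ratio normalization; strong global distortions
  (e.g. uncoupled silencing) shift calls, which is intended behaviour —
  the call reflects the transcriptional, not the cytological, state.
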