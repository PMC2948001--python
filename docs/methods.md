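# Methods

## Setting

Children hospitalized for intravenous corticosteroid treatment of acute severe
ulcerative colitis either respond — disease activity (PUCAI, 0–85) at or below
45 by day 5 with no second-line therapy or surgery — or are corticosteroid-
resistant. Whole-blood expression was profiled in two batches of 20 patients
(10 responders, 10 non-responders each) on day 3 of therapy; only samples with
RNA Integrity Number strictly above 5.5 enter analysis. The package
reimplements the downstream statistics on gene-level matrices; probe-level
array processing (CEL parsing, RMA's background convolution and median
polish, annotation-based probeset filtering) is out of scope, and background
correction is reduced to a configurable additive offset (default 1) before
log2.

## Normalization

Quantile normalization forces every sample onto the across-sample mean of
order statistics. Ties within a column receive the average of the
corresponding reference values ("ties = average"): deterministic and
permutation-invariant, at the cost of exact idempotence in the (measure-zero)
presence of ties. Before pooling the two batches, each gene is centered and
scaled to unit variance *within* batch (the R `scale` convention applied
gene-wise). The stated purpose of that step is batch-effect control, and
gene-wise centering removes additive per-gene batch offsets exactly, whereas
sample-wise scaling would not; both axes and centering-only variants are
exposed in configuration. Genes constant within a batch fall below an SD floor
of 1e-8 and standardize to 0 rather than ±∞.

## The local-pooled-error test

With 10–20 replicates per group, per-gene variances are too noisy to test on
directly. LPE pools them across genes of similar expression: within each
group, genes are assigned to quantile bins of their mean log2 intensity A
(default `min(100, n_genes // 50)` bins, keeping ≥ 50 genes per bin so the
bin statistic is stable), the bin's pooled variance is the **median** of the
per-gene sample variances it contains, and a monotone-safe piecewise-cubic
(PCHIP) interpolant through the (bin-median A, bin variance) points gives
σ²(A), clamped to the outermost bin values beyond the observed range and
floored at 1e-6. The test statistic compares group medians with the median's
asymptotic standard-error inflation π/2:

    z = (med_NR − med_R) / sqrt( (π/2)(σ²_NR(Ā_NR)/n_NR + σ²_R(Ā_R)/n_R) ),

two-sided p from the standard normal, Benjamini–Hochberg step-up q-values.
Both the median location and the π/2 factor are configurable (a mean-based
variant drops both). Ranking ties on p break by larger |z|, then gene id —
the top-5% cut is deterministic.

Calibration at these sample sizes is imperfect in two known, opposite-signed
ways: the π/2 factor is asymptotic (the variance of a median of 10–20 normal
observations is ~10–15% below π/2·σ²/n, making the per-batch test mildly
conservative), and the median-of-variances underestimates σ² by the χ²-median
factor (mildly anticonservative). The test suite measures the net effect on
null cohorts at the pooled design point rather than assuming it away. A
further limitation: the pooled two-batch analysis runs on batch-standardized
values, whose per-gene scale was estimated from ~19 degrees of freedom, so
far-tail p-values behave more like a t than a normal; realized
false-discovery proportions of the pooled route therefore run somewhat above
the per-batch route at very small q. Fold changes are never computed from
standardized values — the pipeline reports 2^(mean_NR − mean_R) from the
per-batch quantile-normalized matrices, where the balanced design cancels
additive batch offsets.

## Cross-batch replication

Each batch's LPE ranking is cut at round-half-up(0.05·G) genes (1,059 of
21,176). The observed intersection is reported as a percent of the batch-1
list size. The null is simulated literally: each Monte-Carlo replicate draws
two independent uniform random subsets of sizes k₁ and k₂ (partial-shuffle
sampling without replacement) and records the intersection size, whose exact
law is hypergeometric with mean k₁k₂/N — the simulation is kept separate from
that closed form so each can check the other. Default 1e6 replicates
(matching a reported precision of ±0.007 given the overlap SD ≈ 7.1);
1e4–2e5 suffice for testing. The chi-squared comparison builds the 2×2 table
[[observed, k−observed], [round(expected), k−round(expected)]] — a
contingency table needs integer counts, and the null median is the integer
next to the mean — and applies Pearson's test without continuity correction.
The analogous published comparison prints a p-value whose construction we
could not reconstruct (a standard Pearson test on this table yields χ² ≈ 259
and a far smaller p); the package reports its own statistic.

## Nearest shrunken centroids

Standard soft-thresholded centroids: pooled within-class SD s_i with
denominator n − K, fudge factor s₀ = median(s_i), class-size factor
m_k = sqrt(1/n_k − 1/n) (the variance factor of x̄_ik − x̄_i, whose overall
mean includes class k), offsets d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s₀)) shrunk
by Δ, discriminant δ_k(x) = Σ (xᵢ − x̄′_ik)²/(sᵢ + s₀)² − 2 log π_k. Priors
default to empirical class proportions; discriminant ties go to the responder
class (fixed class order). Genes constant in every class get their scale
floored at 1e-12 and carry no weight.

Conventions the published tables leave open, resolved as follows and recorded
in every output header:

- **Positive class = non-responder** — sensitivity measures detection of
  corticosteroid resistance.
- **Micro-averaging**: confusion counts are pooled over the 10 folds before
  computing sensitivity/specificity/accuracy (= 100·(TP+TN)/Total); per-fold
  counts are retained so macro-averages can also be derived.
- **Fold construction**: random equal-size folds stratified by class and,
  when available, batch (with 40 samples and k = 10: folds of 4, 2 per
  class); seeded and reproducible.
- **Subset sweep at Δ = 0**: the top-N lists (N = 41…5) are already selected
  externally by LPE rank, so no further shrinkage is applied by default;
  inner selection is the Δ-path's job.
- **Selection bias is reproduced deliberately**: the default sweep ranks
  genes on *all* samples, as the original analysis did; an honest mode that
  re-ranks genes inside each training fold (memoized per fold) is also
  computed and written alongside (`classifier_sweep_honest.tsv`).

The unbiased Δ-path evaluates a grid from 0 to the largest |d_ik| of the
full fit: the surviving-gene count comes from the full-data fit, the CV
metrics from fits inside the training folds, and the accuracy-maximizing Δ
is returned with ties resolved toward larger Δ (sparser models). Because CV
accuracy on 40 samples moves in steps of 2.5% and plateaus once the signal
is captured, *which* tied Δ wins — and hence the recall of planted genes at
the optimum — is a noisy quantity; the regression test fixes the seed and
plants effects at 0.9 SD units, below the accuracy-saturation regime, where
the optimum genuinely needs most of the planted set.

## Synthetic cohorts

The generator emulates the study's design points: 21,176 genes; 2 batches ×
(10 + 10) samples; per-gene baseline log2 levels μ_g ~ Normal(8, 2²);
intensity-dependent noise sd(μ) = a + b·exp(−c·μ) with defaults
(0.15, 4.0, 0.5) — a standard microarray-style decreasing mean–variance
stand-in, a free modelling choice rather than a claim about the original
arrays; additive per-gene batch offsets ~ Normal(0, 0.3²); per-sample
multiplicative scale 2^Normal(0, 0.2²); and 200 planted genes, all
up-regulated in non-responders, with log2 fold changes uniform on
[log2 1.2, log2 2.5] (spanning the published fold-change range without
favouring either end). Clinical covariates (PUCAI trajectories, ages, sex
ratios) are drawn around the published batch-specific group summaries,
truncated to their valid ranges and made consistent with the response rule;
they are cosmetic and enter no statistic. Independent RNG sub-streams per
component make cohorts bit-reproducible and leave non-planted genes
untouched when `n_de_genes` changes (the planted set is a nested prefix of a
seed-fixed permutation).

What passing tests on these cohorts show: the machinery is correct (hand
oracles, brute-force classifiers, closed forms), calibrated near nominal on
its own assumptions, and able to recover planted structure at the study's
scale. What they do not show: performance under real microarray phenomena
the generator omits — probe-level artifacts, correlated gene modules,
non-Gaussian heavy tails, signal-correlated batch effects, or confounded
clinical covariates. Published per-gene results (the 41 significant genes,
their fold changes, the measured sensitivities/specificities) depend on the
original deposited arrays and are deliberately not reproduction targets.

## Numerical and interface choices

- Displayed table values use decimal half-up rounding after clearing float
  dust (so a combined mean of 13.55 prints as 13.6); full precision is kept
  internally.
- Characteristics-table p-values default to Welch's t (numeric fields) and
  Fisher's exact test (sex), labelled "method not stated in source table" in
  the output, since the original table does not name its tests; they are
  descriptive only.
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`); the chi-squared test to `scipy.stats.chi2_contingency` without
  continuity correction. Both are pinned by hand-computed oracle tests.
- Matrices travel as tab-separated text with a `#scale=` sidecar line
  (`raw`, `log2`, `log2_qnorm`, `standardized`); operations refuse inputs on
  the wrong scale (e.g. fold change on standardized data). A reader for the
  GEO series-matrix table block is included.
- Default problem sizes in the test suite (2,000–20,000 genes, 1e4–1e5
  Monte-Carlo replicates) were chosen so each property is measured at the
  scale its standard error requires; the full pipeline at the study's
  21,176-gene scale runs in seconds and is exercised directly.
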