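# steroidsig

Gene-signature analysis of intravenous-corticosteroid response in pediatric
acute severe ulcerative colitis — a tested, reusable reimplementation of a
two-batch whole-blood microarray analysis pipeline:

1. **Cohort handling** — responder / non-responder labelling from the clinical
   rule (PUCAI ≤ 45 on day 5 of therapy and no second-line intervention =
   responder), an RNA-quality filter (RIN > 5.5), and batch/combined
   characteristics tables.
2. **Normalization** — gene-level background offset + log2 transform, quantile
   normalization per batch, and per-batch gene standardization (`scale`) before
   pooling, which removes additive per-gene batch effects exactly.
3. **Differential expression by the local-pooled-error (LPE) test** — variance
   is borrowed across genes of similar mean intensity *A*: per group, genes are
   quantile-binned by *A*, each bin's pooled variance is the median of per-gene
   sample variances, and a shape-preserving interpolant gives σ²(*A*). The
   per-gene statistic compares group medians,

   z = (med_NR − med_R) / √( (π/2) · ( σ²_NR(Ā_NR)/n_NR + σ²_R(Ā_R)/n_R ) ),

   with two-sided normal p-values and Benjamini–Hochberg step-up FDR. Fold
   changes are reported as 2^(mean_NR − mean_R), oriented so values > 1 mean
   elevated in corticosteroid-resistant patients.
4. **Cross-batch replication** — the top-5% gene lists of the two independent
   batch analyses are intersected; the null overlap of two uniform random
   subsets (sizes k₁, k₂ from a universe of N genes, analytic mean k₁k₂/N) is
   estimated by Monte-Carlo simulation and compared with the observed count by
   a Pearson chi-squared test.
5. **Nearest-shrunken-centroid (PAM) classification** — standardized centroid
   offsets d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s₀)) are soft-thresholded by Δ,
   samples are assigned by the penalized distance
   δ_k(x) = Σᵢ (xᵢ − x̄′_ik)²/(sᵢ + s₀)² − 2·log π_k, and performance is
   measured by stratified 10-fold cross-validation: a top-N gene-subset sweep
   (N = 41…5) and an unbiased Δ-path over all genes. The positive class is the
   non-responder (resistant) group throughout.

A synthetic-cohort generator reproduces the statistical structure the analysis
relies on — two batches of 20 samples (10 responders / 10 non-responders
each), ~21k genes, intensity-dependent noise, additive batch effects, and
planted genes up-regulated in non-responders at fold changes 1.2–2.5 — with
full ground truth, so every stage is testable without the original arrays.

## Worked example

```python
from steroidsig import SyntheticSpec, run_pipeline
from steroidsig.pipeline import PipelineConfig, ReplicationConfig, ClassifierConfig

config = PipelineConfig(
    seed=7,
    synthetic=SyntheticSpec(n_genes=4000, n_de_genes=80, seed=7),
    replication=ReplicationConfig(mc_reps=50_000),
    classifier=ClassifierConfig(sizes=[30, 20, 10, 5], folds=10),
)
report = run_pipeline(config)
print(report.summary_dict())
```

prints (reformatted):

```
n_samples 40   n_genes 4000   n_significant 78
replication: observed_overlap 69 (34.5%)  expected_mean 10.008  expected_median 10
             chi2 54.9  chi2_p 1.3e-13
classifier:  best_sweep_n 5 (accuracy 100.0)  best_delta 4.41 -> 8 genes, accuracy 100.0
```

Reading: 78 of the 80 planted genes reach FDR < 0.05 in the pooled two-batch
analysis; the two batches' top-5% lists share 69 genes where unrelated lists
would share ~10, and the chi-squared test rejects chance overlap; the shrunken
-centroid classifier separates responders from non-responders perfectly at
this (deliberately strong) synthetic effect size. `report.sweep` holds the
top-N sweep table (N, specificity, sensitivity, accuracy from pooled confusion
counts, positive class = non-responder), `report.threshold_table` the Δ-path.

The same run is available from the shell:

```sh
steroidsig run-all --seed 7 --out results/run7
steroidsig report --run-dir results/run7
```

with per-stage tables (`cohort_summary.tsv`, `lpe_batch*.tsv`,
`replication.json`, `significant_genes.tsv`, `classifier_sweep.tsv`,
`threshold_path.tsv`) plus a `manifest.json` recording config and seeds; a run
is byte-reproducible from its manifest.

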