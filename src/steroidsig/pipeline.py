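"""End-to-end orchestration of the corticosteroid-response analysis.

Stage order mirrors the study design: QC and response labelling; per-batch
normalization (background/log2/quantile); per-batch LPE ranking; cross-batch
replication at the top-5% cut; per-batch gene standardization, pooling and a
pooled LPE with BH-FDR; a shrunken-centroid classifier sweep over the ranked
significant genes plus the unbiased shrinkage path; report writing.

Every stage is a pure function of (inputs, config, seeds); the manifest
records enough to re-run any stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    NON_RESPONDER,
    RESPONDER,
    SampleRecord,
    classify_response,
    format_summary,
    qc_filter_rin,
    read_metadata,
    summarize_cohort,
    write_metadata,
)
from .lpe import LPE, LPEResults, estimate_baseline_variance, lpe_test
from .matrix import ExpressionMatrix
from .nsc import (
    DEFAULT_SIZES,
    NearestShrunkenCentroid,
    stratified_folds,
    subset_sweep,
    threshold_path,
)
from .preprocess import (
    background_correct_and_log,
    pool_batches,
    quantile_normalize,
    standardize_within_batch,
)
from .replication import OverlapResult, replication_analysis
from .simulate import SyntheticSpec, generate_cohort

logger = logging.getLogger("steroidsig")


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PreprocessConfig:
    offset: float = 1.0
    center: bool = True
    scale: bool = True
    axis: str = "genes"


@dataclass
class LPEConfig:
    n_bins: int | None = None
    use_median: bool = True
    median_inflation: bool = True


@dataclass
class ReplicationConfig:
    fraction: float = 0.05
    mc_reps: int = 1_000_000
    seed: int | None = None


@dataclass
class ClassifierConfig:
    sizes: list[int] = field(default_factory=lambda: list(DEFAULT_SIZES))
    folds: int = 10
    delta: float = 0.0
    seed: int | None = None
    honest_selection: bool = True  # also run the within-fold-ranking sweep
    threshold_grid_size: int = 21


@dataclass
class PipelineConfig:
    """Full run configuration; every field has a default."""

    seed: int = 0
    fdr: float = 0.05
    rin_threshold: float = 5.5
    matrix_path: str | None = None  # raw genes x samples TSV; None => synthetic
    metadata_path: str | None = None
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lpe: LPEConfig = field(default_factory=LPEConfig)
    replication: ReplicationConfig = field(default_factory=ReplicationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self):
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")

    def resolved_seeds(self) -> dict:
        """Fill derived sub-seeds from the global seed where unset."""
        return {
            "global": self.seed,
            "synthetic": self.synthetic.seed,
            "replication": self.replication.seed
            if self.replication.seed is not None
            else self.seed + 1,
            "classifier": self.classifier.seed
            if self.classifier.seed is not None
            else self.seed + 2,
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_section(cls, payload: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    return cls(**payload)


def config_from_dict(payload: dict) -> PipelineConfig:
    payload = dict(payload or {})
    sections = {
        "synthetic": SyntheticSpec,
        "preprocess": PreprocessConfig,
        "lpe": LPEConfig,
        "replication": ReplicationConfig,
        "classifier": ClassifierConfig,
    }
    kwargs = {}
    for key, cls in sections.items():
        if key in payload:
            sub = payload.pop(key)
            if isinstance(sub, dict):
                for name in ("fc_range", "baseline_mean_sd", "variance_model"):
                    if name in sub and isinstance(sub[name], list):
                        sub[name] = tuple(sub[name])
                kwargs[key] = _build_section(cls, sub, key)
            else:
                raise ValueError(f"config section {key!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**payload, **kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return config_from_dict(payload or {})


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Everything a run produced, plus the manifest that reproduces it."""

    cohort_summary: pd.DataFrame
    batch_results: dict  # batch id -> LPEResults
    overlap: OverlapResult
    pooled_results: LPEResults
    significant: pd.DataFrame
    sweep: pd.DataFrame
    sweep_honest: pd.DataFrame | None
    threshold_table: pd.DataFrame
    best_delta: float
    best_subset: pd.DataFrame
    manifest: dict

    def summary_dict(self) -> dict:
        sweep_best = self.sweep.sort_values(
            ["accuracy", "n_genes"], ascending=[False, True]
        ).iloc[0]
        best_row = self.threshold_table.loc[
            self.threshold_table["delta"] == self.best_delta
        ].iloc[0]
        return {
            "n_samples": self.manifest["counts"]["n_samples"],
            "n_genes": self.manifest["counts"]["n_genes"],
            "n_significant": int(len(self.significant)),
            "replication": {
                "observed_overlap": self.overlap.observed,
                "observed_percent": self.overlap.observed_percent,
                "expected_mean": self.overlap.mc_mean,
                "expected_median": self.overlap.mc_median,
                "chi2": self.overlap.chi2,
                "chi2_p": self.overlap.chi2_p,
            },
            "classifier": {
                "best_sweep_n": int(sweep_best["n_genes"]),
                "best_sweep_accuracy": float(sweep_best["accuracy"]),
                "best_delta": self.best_delta,
                "best_delta_n_genes": int(best_row["n_genes"]),
                "best_delta_accuracy": float(best_row["accuracy"]),
            },
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        format_summary(self.cohort_summary).to_csv(
            outdir / "cohort_summary.tsv", sep="\t", index=False
        )
        for batch, res in self.batch_results.items():
            res.to_tsv(outdir / f"lpe_batch{batch}.tsv")
        self.overlap.to_json(outdir / "replication.json")
        self.pooled_results.to_tsv(outdir / "lpe_pooled.tsv")
        self.significant.to_csv(outdir / "significant_genes.tsv", sep="\t", index_label="gene_id")
        self.sweep.to_csv(outdir / "classifier_sweep.tsv", sep="\t", index=False)
        if self.sweep_honest is not None:
            self.sweep_honest.to_csv(
                outdir / "classifier_sweep_honest.tsv", sep="\t", index=False
            )
        self.threshold_table.to_csv(outdir / "threshold_path.tsv", sep="\t", index=False)
        self.best_subset.to_csv(outdir / "best_subset.tsv", sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)
            fh.write("\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _load_inputs(config: PipelineConfig):
    if config.matrix_path is not None:
        matrix = ExpressionMatrix.read_tsv(config.matrix_path, scale="raw")
        records = read_metadata(config.metadata_path)
        records = [
            r if r.response_label is not None else classify_response(r) for r in records
        ]
        return matrix, records
    spec = dataclasses.replace(config.synthetic, seed=config.synthetic.seed)
    matrix, records, _truth = generate_cohort(spec)
    return matrix, records


def run_pipeline(config: PipelineConfig, outdir=None) -> RunReport:
    """Execute the full analysis; optionally write the report to ``outdir``.

    Raises :class:`StageError` on failure; partially written outputs are
    removed.
    """
    seeds = config.resolved_seeds()
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc_type is None:  # a failed stage stays out of the manifest
                    timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                    logger.info("stage %s: done in %.2fs", name, timings[name])
                return False

        return _Timer()

    try:
        with stage("cohort"):
            raw, records = _load_inputs(config)
            records = qc_filter_rin(records, config.rin_threshold)
            kept = [r.sample_id for r in records]
            if len(kept) < raw.n_samples:
                logger.info("QC removed %d samples", raw.n_samples - len(kept))
            raw = raw.subset_samples(kept)
            summary = summarize_cohort(records, grouping="both")
            counts["n_samples"] = raw.n_samples
            counts["n_genes"] = raw.n_genes
            batches = sorted({r.batch_id for r in records})
            batch_of = {r.sample_id: r.batch_id for r in records}
            label_of = {r.sample_id: r.response_label for r in records}

        with stage("normalize"):
            per_batch_qnorm: dict[int, ExpressionMatrix] = {}
            for b in batches:
                samples = [s for s in raw.sample_ids if batch_of[s] == b]
                sub = raw.subset_samples(samples)
                logged = background_correct_and_log(sub, config.preprocess.offset)
                per_batch_qnorm[b] = quantile_normalize(logged)

        with stage("batch_lpe"):
            batch_results: dict[int, LPEResults] = {}
            for b, mat in per_batch_qnorm.items():
                grp_r = [s for s in mat.sample_ids if label_of[s] == RESPONDER]
                grp_nr = [s for s in mat.sample_ids if label_of[s] == NON_RESPONDER]
                res = LPE(
                    mat, grp_r, grp_nr,
                    n_bins=config.lpe.n_bins,
                    use_median=config.lpe.use_median,
                    median_inflation=config.lpe.median_inflation,
                ).fit()
                res.add_fold_change(mat)
                batch_results[b] = res

        with stage("replication"):
            if len(batches) != 2:
                raise ValueError(f"replication needs exactly 2 batches, got {len(batches)}")
            overlap = replication_analysis(
                batch_results[batches[0]],
                batch_results[batches[1]],
                fraction=config.replication.fraction,
                reps=config.replication.mc_reps,
                seed=seeds["replication"],
            )
            counts["observed_overlap"] = overlap.observed

        with stage("pooled_lpe"):
            standardized = [
                standardize_within_batch(
                    per_batch_qnorm[b],
                    batch_of,
                    center=config.preprocess.center,
                    scale=config.preprocess.scale,
                    axis=config.preprocess.axis,
                )
                for b in batches
            ]
            pooled = pool_batches(standardized)
            pooled_qnorm = pool_batches([per_batch_qnorm[b] for b in batches])
            grp_r = [s for s in pooled.sample_ids if label_of[s] == RESPONDER]
            grp_nr = [s for s in pooled.sample_ids if label_of[s] == NON_RESPONDER]
            pooled_results = LPE(
                pooled, grp_r, grp_nr,
                n_bins=config.lpe.n_bins,
                use_median=config.lpe.use_median,
                median_inflation=config.lpe.median_inflation,
            ).fit()
            pooled_results.add_fold_change(pooled_qnorm)
            significant = pooled_results.significant(config.fdr)
            counts["n_significant"] = len(significant)

        with stage("classify"):
            labels = pd.Series(label_of)
            folds = stratified_folds(
                label_of, batch_of, k=config.classifier.folds, seed=seeds["classifier"]
            )
            ranked = pooled_results.ranked_gene_ids()
            n_sig = len(significant)
            sizes = [n for n in config.classifier.sizes if n <= max(n_sig, 1)]
            if not sizes:
                sizes = [max(n_sig, 1)]
            if sizes != list(config.classifier.sizes):
                logger.warning(
                    "only %d significant genes; sweep sizes truncated to %s", n_sig, sizes
                )
            sweep = subset_sweep(
                pooled.data, label_of, ranked, sizes, folds, config.classifier.delta
            )
            sweep_honest = None
            if config.classifier.honest_selection:
                sweep_honest = subset_sweep(
                    pooled.data, label_of, ranked, sizes, folds,
                    config.classifier.delta, ranker=_make_lpe_ranker(config),
                )
            model = NearestShrunkenCentroid(pooled.data, labels)
            d_max = model.max_offset()
            grid = np.linspace(0.0, d_max, config.classifier.threshold_grid_size)
            path_table, best_delta = threshold_path(pooled.data, label_of, grid, folds)
            best_n = min(sizes[-1] if sizes else 10, len(ranked))
            best_subset = sweep.loc[sweep["accuracy"].idxmax()].to_frame().T
            best_genes = ranked[: int(best_subset["n_genes"].iloc[0])]
            best_subset = best_subset.assign(genes=",".join(best_genes))

        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "seeds": seeds,
            "counts": counts,
            "timings_s": timings,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        report = RunReport(
            cohort_summary=summary,
            batch_results=batch_results,
            overlap=overlap,
            pooled_results=pooled_results,
            significant=significant,
            sweep=sweep,
            sweep_honest=sweep_honest,
            threshold_table=path_table,
            best_delta=best_delta,
            best_subset=best_subset,
            manifest=manifest,
        )
        if outdir is not None:
            try:
                report.write(outdir)
            except Exception:
                shutil.rmtree(outdir, ignore_errors=True)
                raise
        return report
    except StageError:
        raise
    except Exception as exc:
        failed = next((k for k in ("cohort", "normalize", "batch_lpe", "replication",
                                   "pooled_lpe", "classify") if k not in timings), "report")
        raise StageError(failed, str(exc)) from exc


def _make_lpe_ranker(config: PipelineConfig):
    """Within-training-fold LPE ranking for honest gene selection.

    Results are memoized per training-sample set: the sweep calls the ranker
    once per (fold, size) pair but the ranking depends only on the fold.
    """
    cache: dict[tuple, list[str]] = {}

    def ranker(train_frame: pd.DataFrame, train_labels: pd.Series) -> list[str]:
        key = tuple(train_frame.columns)
        if key not in cache:
            mat = ExpressionMatrix(train_frame, "standardized")
            grp_r = [s for s in train_frame.columns if train_labels[s] == RESPONDER]
            grp_nr = [s for s in train_frame.columns if train_labels[s] == NON_RESPONDER]
            res = LPE(
                mat, grp_r, grp_nr,
                n_bins=config.lpe.n_bins,
                use_median=config.lpe.use_median,
                median_inflation=config.lpe.median_inflation,
            ).fit()
            cache[key] = res.ranked_gene_ids()
        return cache[key]

    return ranker
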