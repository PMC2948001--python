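"""Synthetic two-batch corticosteroid-response cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
relies on, at the study's design points: two batches of 20 samples (10
responders / 10 non-responders each), ~21k genes, intensity-dependent noise
(SD falling with mean log2 level — the assumption the local-pooled-error test
pools on), additive per-gene batch offsets, per-sample multiplicative scale
effects, and a set of planted genes up-regulated in non-responders with fold
changes spanning 1.2-2.5.

Raw intensities are built on the log2 scale and exponentiated:

    raw[g, j] = 2 ** (mu_g + delta_g * 1[j non-responder]
                      + beta[g, batch(j)] + eps[g, j]) * s_j

with ``eps ~ Normal(0, sd(mu_g)^2)``, ``sd(mu) = a + b * exp(-c * mu)``, and
``s_j = 2**eta_j`` a per-sample scale factor. Clinical covariates (PUCAI
trajectories, age, sex ratios) are drawn around the study's batch-specific
group summaries; they are cosmetic and enter no test statistic.

Sub-streams are spawned deterministically per component, so changing
``n_de_genes`` leaves the expression of non-planted genes bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .cohort import NON_RESPONDER, RESPONDER, SampleRecord
from .matrix import ExpressionMatrix

# Batch- and group-specific clinical summaries (mean, sd) used to draw
# cosmetic covariates: keyed (batch, label).
_CLINICAL = {
    (1, RESPONDER): dict(age=(14.4, 2.2), duration=(9, 19), d1=(77, 9), d3=(44, 23), d5=(36, 8), male_frac=0.5),
    (1, NON_RESPONDER): dict(age=(14.6, 2.2), duration=(12, 17), d1=(75, 13), d3=(71, 10), d5=(67, 13), male_frac=0.5),
    (2, RESPONDER): dict(age=(12.7, 2.6), duration=(18, 39), d1=(66, 11), d3=(34, 13), d5=(19, 11), male_frac=0.7),
    (2, NON_RESPONDER): dict(age=(14.6, 2.4), duration=(20, 35), d1=(73, 8), d3=(61, 14), d5=(54, 16), male_frac=0.7),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults are the study's design points; ``variance_model`` is the
    (a, b, c) of ``sd(mu) = a + b * exp(-c * mu)`` on the log2 scale.
    """

    n_genes: int = 21176
    samples_per_group_per_batch: int = 10
    n_de_genes: int = 200
    fc_range: tuple[float, float] = (1.2, 2.5)
    baseline_mean_sd: tuple[float, float] = (8.0, 2.0)
    variance_model: tuple[float, float, float] = (0.15, 4.0, 0.5)
    batch_sd: float = 0.3
    sample_scale_sd: float = 0.2
    low_rin_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.samples_per_group_per_batch <= 0:
            raise ValueError("n_genes and samples_per_group_per_batch must be positive")
        if not (0 <= self.n_de_genes <= self.n_genes):
            raise ValueError("n_de_genes must be in [0, n_genes]")
        if self.fc_range[0] < 1 or self.fc_range[1] < self.fc_range[0]:
            raise ValueError("fc_range must satisfy 1 <= low <= high")
        if any(v < 0 for v in self.variance_model):
            raise ValueError("variance model coefficients must be non-negative")
        if self.variance_model[0] <= 0 and self.variance_model[1] <= 0:
            raise ValueError("variance model must yield sd > 0")

    def noise_sd(self, mu: np.ndarray) -> np.ndarray:
        a, b, c = self.variance_model
        return a + b * np.exp(-c * np.asarray(mu, dtype=float))


@dataclass
class GroundTruth:
    """Planted-effect bookkeeping for recovery evaluation."""

    true_log2_shift: pd.Series  # non-responder minus responder, 0 for non-DE
    batch_offsets: pd.DataFrame  # genes x batches

    @property
    def de_gene_ids(self) -> set[str]:
        return set(self.true_log2_shift.index[self.true_log2_shift > 0])

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(
            {
                "gene_id": self.true_log2_shift.index,
                "true_shift": self.true_log2_shift.values,
                "is_de": (self.true_log2_shift.values > 0).astype(int),
            }
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GroundTruth":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        shift = pd.Series(frame["true_shift"].values, index=frame["gene_id"])
        return cls(shift, pd.DataFrame(index=shift.index))


def _truncated_normal(rng, mean, sd, low, high, size):
    """Rejection-sampled truncated normal (cheap at these sizes)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _sample_records(spec: SyntheticSpec, rng: np.random.Generator) -> list[SampleRecord]:
    n = spec.samples_per_group_per_batch
    records = []
    for batch in (1, 2):
        for label in (RESPONDER, NON_RESPONDER):
            clin = _CLINICAL[(batch, label)]
            tag = "R" if label == RESPONDER else "N"
            n_male = int(round(clin["male_frac"] * n))
            sexes = ["male"] * n_male + ["female"] * (n - n_male)
            ages = _truncated_normal(rng, *clin["age"], 2.0, 18.0, n)
            durations = np.round(np.abs(rng.normal(*clin["duration"], size=n)))
            d1 = np.round(_truncated_normal(rng, *clin["d1"], 0, 85, n))
            d3 = np.round(_truncated_normal(rng, *clin["d3"], 0, 85, n))
            if label == RESPONDER:
                d5 = np.round(_truncated_normal(rng, *clin["d5"], 0, 45, n))
                second_line = np.zeros(n, dtype=bool)
            else:
                d5 = np.round(_truncated_normal(rng, *clin["d5"], 46, 85, n))
                second_line = rng.random(n) < 0.3  # some failures go to rescue therapy
            rin = _truncated_normal(rng, 8.0, 1.0, 5.6, 10.0, n)
            if spec.low_rin_fraction > 0:
                low = rng.random(n) < spec.low_rin_fraction
                rin[low] = rng.uniform(3.0, 5.5, size=int(low.sum()))
            for i in range(n):
                records.append(
                    SampleRecord(
                        sample_id=f"B{batch}_{tag}{i + 1:02d}",
                        batch_id=batch,
                        sex=sexes[i],
                        age=float(np.round(ages[i], 1)),
                        disease_duration=float(durations[i]),
                        pucai_day1=int(d1[i]),
                        pucai_day3=int(d3[i]),
                        pucai_day5=int(d5[i]),
                        second_line_or_surgery=bool(second_line[i]),
                        rin=float(np.round(rin[i], 2)),
                    )
                )
    return [_cohort.classify_response(r) for r in records]


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, list[SampleRecord], GroundTruth]:
    """Draw one cohort: raw expression matrix, sample metadata, ground truth.

    Deterministic given ``spec`` (including its seed); the planted-gene set is
    a nested prefix of a seed-fixed gene permutation, so increasing
    ``n_de_genes`` only adds planted genes.
    """
    root = np.random.SeedSequence(spec.seed)
    keys = ("baseline", "batch", "noise", "de_select", "de_effect", "scale", "meta")
    streams = {k: np.random.default_rng(s) for k, s in zip(keys, root.spawn(len(keys)))}

    n_genes = spec.n_genes
    gene_ids = pd.Index([f"G{str(i + 1).zfill(5)}" for i in range(n_genes)], name="gene_id")
    records = _sample_records(spec, streams["meta"])
    sample_ids = [r.sample_id for r in records]
    is_nr = np.array([r.response_label == NON_RESPONDER for r in records])
    batch_idx = np.array([r.batch_id - 1 for r in records])

    mu = streams["baseline"].normal(*spec.baseline_mean_sd, size=n_genes)
    beta = streams["batch"].normal(0.0, spec.batch_sd, size=(n_genes, 2)) if spec.batch_sd > 0 else np.zeros((n_genes, 2))
    eps = streams["noise"].normal(size=(n_genes, len(records))) * spec.noise_sd(mu)[:, None]

    shift = np.zeros(n_genes)
    de_order = streams["de_select"].permutation(n_genes)
    de_idx = de_order[: spec.n_de_genes]
    lo, hi = np.log2(spec.fc_range[0]), np.log2(spec.fc_range[1])
    shift[de_idx] = streams["de_effect"].uniform(lo, hi, size=spec.n_de_genes)
    if spec.fc_range[0] == 1.0:  # log2-uniform draw can hit 0 only at the boundary
        shift[de_idx] = np.maximum(shift[de_idx], np.finfo(float).tiny)

    eta = streams["scale"].normal(0.0, spec.sample_scale_sd, size=len(records))
    log2_signal = (
        mu[:, None]
        + shift[:, None] * is_nr[None, :]
        + beta[:, batch_idx]
        + eps
    )
    raw = np.exp2(log2_signal + eta[None, :])

    matrix = ExpressionMatrix(pd.DataFrame(raw, index=gene_ids, columns=sample_ids), "raw")
    truth = GroundTruth(
        true_log2_shift=pd.Series(shift, index=gene_ids),
        batch_offsets=pd.DataFrame(beta, index=gene_ids, columns=[1, 2]),
    )
    return matrix, records, truth


def truth_ranks(truth: GroundTruth, results) -> pd.DataFrame:
    """P-value rank (1 = most significant) of each planted gene.

    ``results`` is either an ``LPEResults`` object or an ordered sequence of
    gene ids ranked best-first.
    """
    if hasattr(results, "ranked_gene_ids"):
        ranked = list(results.ranked_gene_ids())
    else:
        ranked = list(results)
    position = {g: i + 1 for i, g in enumerate(ranked)}
    missing = [g for g in truth.de_gene_ids if g not in position]
    if missing:
        raise KeyError(f"gene ids absent from results: {missing[:5]}")
    rows = [
        {"gene_id": g, "rank": position[g], "true_shift": truth.true_log2_shift[g]}
        for g in sorted(truth.de_gene_ids)
    ]
    frame = pd.DataFrame(rows, columns=["gene_id", "rank", "true_shift"])
    return frame.sort_values("rank").reset_index(drop=True)


def recall_top_k(ranks: pd.DataFrame, k: int) -> float:
    """Fraction of planted genes ranked within the top ``k``."""
    if len(ranks) == 0:
        return float("nan")
    return float((ranks["rank"] <= k).mean())
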