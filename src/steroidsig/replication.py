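"""Cross-batch replication: top-fraction gene lists, overlap, Monte-Carlo null.

The two batches are analysed independently; the top 5% of genes by p-value in
each batch are intersected, and the observed overlap is compared with the
overlap expected if the two lists were unrelated — estimated by repeatedly
drawing pairs of uniform random subsets of the gene universe and recording
their intersection size (analytic mean k1*k2/N), then tested with a Pearson
chi-squared on observed-vs-expected counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def top_fraction(ranked_results, fraction: float = 0.05) -> list[str]:
    """First round_half_up(fraction * G) gene ids of a ranked result.

    ``ranked_results`` is an ``LPEResults`` (its deterministic tie-break
    ranking is used) or an ordered sequence of gene ids.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if hasattr(ranked_results, "ranked_gene_ids"):
        ranked = ranked_results.ranked_gene_ids()
    else:
        ranked = list(ranked_results)
    if not ranked:
        raise ValueError("empty results")
    return ranked[: round_half_up(fraction * len(ranked))]


def observed_overlap(
    set_a: Iterable[str], set_b: Iterable[str], k_reference: int
) -> tuple[int, float]:
    """Intersection size and percent of ``k_reference`` (one decimal)."""
    if k_reference <= 0:
        raise ValueError("k_reference must be positive")
    count = len(set(set_a) & set(set_b))
    return count, round(100.0 * count / k_reference, 1)


def mc_expected_overlap(
    n_universe: int,
    k1: int,
    k2: int,
    reps: int = 1_000_000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Monte-Carlo null overlap of two uniform random subsets.

    Each replicate draws two independent uniform subsets (sizes ``k1``,
    ``k2``) of an ``n_universe``-element universe via partial shuffles and
    counts their intersection. Returns (mean, standard error of the mean,
    median) of the replicate counts; the mean converges to ``k1*k2/N``.
    """
    if not (0 <= k1 <= n_universe and 0 <= k2 <= n_universe):
        raise ValueError("subset sizes must lie in [0, N]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    universe = np.arange(n_universe)
    counts = np.empty(reps, dtype=np.int64)
    mask = np.zeros(n_universe, dtype=bool)
    for i in range(reps):
        a = rng.choice(universe, size=k1, replace=False, shuffle=False)
        b = rng.choice(universe, size=k2, replace=False, shuffle=False)
        mask[a] = True
        counts[i] = int(mask[b].sum())
        mask[a] = False
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0
    return mean, se, float(np.median(counts))


def overlap_chi2(observed: int, expected: float, k: int) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2 table
    [[observed, k-observed], [round(expected), k-round(expected)]].
    """
    if not (0 <= observed <= k):
        raise ValueError("observed must lie in [0, k]")
    exp_count = int(round(expected))
    if not (0 < exp_count < k) and not (0 < observed < k):
        raise ValueError("degenerate 2x2 table (zero margin)")
    table = np.array([[observed, k - observed], [exp_count, k - exp_count]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table (zero margin)")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass
class OverlapResult:
    """Full replication report for one pair of ranked batch analyses."""

    universe_size: int
    k1: int
    k2: int
    observed: int
    observed_percent: float
    mc_mean: float
    mc_se: float
    mc_median: float
    mc_reps: int
    mc_seed: int | None
    analytic_mean: float
    chi2: float
    chi2_p: float

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def replication_analysis(
    results_batch1,
    results_batch2,
    fraction: float = 0.05,
    reps: int = 1_000_000,
    seed: int | None = None,
) -> OverlapResult:
    """Top-fraction lists per batch, observed overlap, MC null, chi-squared."""
    list1 = top_fraction(results_batch1, fraction)
    list2 = top_fraction(results_batch2, fraction)
    n1 = len(results_batch1.frame) if hasattr(results_batch1, "frame") else None
    n2 = len(results_batch2.frame) if hasattr(results_batch2, "frame") else None
    if n1 is None:
        raise TypeError("replication_analysis expects LPEResults inputs")
    if n1 != n2:
        raise ValueError("batch universes differ in size; cannot compare 5% cuts")
    k1, k2 = len(list1), len(list2)
    observed, percent = observed_overlap(list1, list2, k1)
    mean, se, median = mc_expected_overlap(n1, k1, k2, reps, seed)
    chi2, p = overlap_chi2(observed, mean, k1)
    return OverlapResult(
        universe_size=n1, k1=k1, k2=k2,
        observed=observed, observed_percent=percent,
        mc_mean=mean, mc_se=se, mc_median=median, mc_reps=reps, mc_seed=seed,
        analytic_mean=k1 * k2 / n1,
        chi2=chi2, chi2_p=p,
    )
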