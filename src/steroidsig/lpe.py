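"""Local-pooled-error (LPE) differential expression between response groups.

Microarray replicates are few (10 per group per batch here), so per-gene
variance estimates are unstable. LPE borrows strength across genes: within
each group, genes are binned by mean log2 intensity A, a pooled variance is
taken per bin (median of the per-gene sample variances), and a smooth
function sigma^2(A) is interpolated through the bins. The test statistic for
a gene compares group *medians*, with the median's asymptotic variance
inflation of pi/2 relative to the mean:

    z = (med_NR - med_R) / sqrt( (pi/2) * ( sigma^2_NR(A_NR)/n_NR
                                           + sigma^2_R(A_R)/n_R ) )

Two-sided p-values come from the standard normal, and multiplicity is
handled by Benjamini-Hochberg step-up FDR. Fold changes are reported on the
linear scale, oriented non-responder over responder, and are computed from
log2-scale (not gene-standardized) data.

The model/results pair follows the statsmodels convention::

    res = LPE(matrix, group_R, group_NR).fit()
    res.frame          # per-gene statistics
    res.significant()  # FDR < 0.05 table
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

VARIANCE_FLOOR = 1e-6

#: Median-versus-mean asymptotic efficiency factor for the group-median SE.
MEDIAN_INFLATION = np.pi / 2.0


def default_n_bins(n_genes: int) -> int:
    """100 quantile bins, or fewer so each bin keeps >= 50 genes."""
    return max(1, min(100, n_genes // 50))


@dataclass
class VarianceFunction:
    """Smoothed pooled variance as a function of mean intensity for one group.

    Piecewise-cubic (shape-preserving) through the per-bin
    (median A, pooled variance) points; constant beyond the outermost bins;
    floored at ``floor``.
    """

    condition: str
    bin_edges: np.ndarray
    bin_centers: np.ndarray  # median A per bin
    bin_variances: np.ndarray
    floor: float = VARIANCE_FLOOR

    def __post_init__(self):
        if len(self.bin_centers) != len(self.bin_variances) or len(self.bin_centers) < 1:
            raise ValueError("need >= 1 (center, variance) bin point")
        if len(self.bin_centers) == 1:
            self._interp = None
        else:
            if not np.all(np.diff(self.bin_centers) > 0):
                raise ValueError("bin centers must be strictly increasing")
            self._interp = PchipInterpolator(self.bin_centers, self.bin_variances)

    def __call__(self, a) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        if self._interp is None:
            out = np.full(a.shape, self.bin_variances[0])
        else:
            out = self._interp(np.clip(a, self.bin_centers[0], self.bin_centers[-1]))
        return np.maximum(out, self.floor)


def estimate_baseline_variance(
    matrix: ExpressionMatrix,
    group_samples: Sequence[str],
    n_bins: int | None = None,
    condition: str = "",
    floor: float = VARIANCE_FLOOR,
) -> VarianceFunction:
    """Fit the intensity-binned pooled variance function for one group.

    Genes are assigned to ``n_bins`` quantile bins of their within-group mean
    intensity; each bin's pooled variance is the median of the per-gene sample
    variances it contains.
    """
    sub = matrix.data.loc[:, list(group_samples)].to_numpy(dtype=float)
    if sub.shape[1] < 2:
        raise ValueError("group needs >= 2 samples to estimate variance")
    n_genes = sub.shape[0]
    if n_bins is None:
        n_bins = default_n_bins(n_genes)
    if not (1 <= n_bins <= n_genes):
        raise ValueError(f"n_bins={n_bins} outside [1, {n_genes}]")

    a = sub.mean(axis=1)
    s2 = sub.var(axis=1, ddof=1)
    edges = np.quantile(a, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)  # ties in A collapse bins
    idx = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, len(edges) - 2)

    centers, variances = [], []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        if not in_bin.any():
            continue
        centers.append(np.median(a[in_bin]))
        variances.append(np.median(s2[in_bin]))
    centers = np.asarray(centers)
    variances = np.asarray(variances)
    order = np.argsort(centers)
    centers, variances = centers[order], variances[order]
    keep = np.concatenate(([True], np.diff(centers) > 0))
    return VarianceFunction(condition, edges, centers[keep], variances[keep], floor)


def lpe_test(
    matrix: ExpressionMatrix,
    group_responder: Sequence[str],
    group_non_responder: Sequence[str],
    varfun_responder: VarianceFunction,
    varfun_non_responder: VarianceFunction,
    use_median: bool = True,
    median_inflation: bool = True,
) -> pd.DataFrame:
    """Per-gene LPE z statistic and two-sided normal p-value.

    ``use_median=False`` switches group location to the mean (and drops the
    pi/2 inflation unless ``median_inflation`` forces it).
    """
    r = matrix.data.loc[:, list(group_responder)].to_numpy(dtype=float)
    nr = matrix.data.loc[:, list(group_non_responder)].to_numpy(dtype=float)
    n_r, n_nr = r.shape[1], nr.shape[1]
    if n_r < 2 or n_nr < 2:
        raise ValueError("each group needs >= 2 samples")

    loc = np.median if use_median else np.mean
    med_r, med_nr = loc(r, axis=1), loc(nr, axis=1)
    a_r, a_nr = r.mean(axis=1), nr.mean(axis=1)
    factor = MEDIAN_INFLATION if (use_median and median_inflation) else 1.0
    se = np.sqrt(factor * (varfun_non_responder(a_nr) / n_nr + varfun_responder(a_r) / n_r))
    z = (med_nr - med_r) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "med_R": med_r, "med_NR": med_nr,
            "abar_R": a_r, "abar_NR": a_nr,
            "n_R": n_r, "n_NR": n_nr,
            "z": z, "p": p,
        },
        index=matrix.data.index,
    )


def fold_change(
    matrix: ExpressionMatrix,
    group_responder: Sequence[str],
    group_non_responder: Sequence[str],
) -> pd.Series:
    """Linear fold change, non-responder over responder: 2**(mean_NR - mean_R).

    Requires a log2-scale matrix; fold changes are meaningless after gene-wise
    standardization.
    """
    if matrix.scale not in ("log2", "log2_qnorm"):
        raise ValueError(
            f"fold change needs a log2-scale matrix, got scale {matrix.scale!r}"
        )
    r = matrix.data.loc[:, list(group_responder)].to_numpy(dtype=float)
    nr = matrix.data.loc[:, list(group_non_responder)].to_numpy(dtype=float)
    fc = np.exp2(nr.mean(axis=1) - r.mean(axis=1))
    return pd.Series(fc, index=matrix.data.index, name="fold_change")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class LPE:
    """Local-pooled-error differential-expression model (statsmodels-style).

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log2-scale (per-batch analysis) or standardized (pooled two-batch
        analysis) expression.
    group_responder, group_non_responder : sequences of sample ids
    n_bins : int, optional
        Quantile bins for the variance function (default
        :func:`default_n_bins`).
    use_median, median_inflation : bool
        Group location statistic and the pi/2 SE inflation that goes with the
        median.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        group_responder: Sequence[str],
        group_non_responder: Sequence[str],
        n_bins: int | None = None,
        use_median: bool = True,
        median_inflation: bool = True,
        variance_floor: float = VARIANCE_FLOOR,
    ):
        overlap = set(group_responder) & set(group_non_responder)
        if overlap:
            raise ValueError(f"samples in both groups: {sorted(overlap)[:5]}")
        self.matrix = matrix
        self.group_responder = list(group_responder)
        self.group_non_responder = list(group_non_responder)
        self.n_bins = n_bins
        self.use_median = use_median
        self.median_inflation = median_inflation
        self.variance_floor = variance_floor

    def fit(self) -> "LPEResults":
        varfun_r = estimate_baseline_variance(
            self.matrix, self.group_responder, self.n_bins, "responder", self.variance_floor
        )
        varfun_nr = estimate_baseline_variance(
            self.matrix, self.group_non_responder, self.n_bins, "non_responder",
            self.variance_floor,
        )
        frame = lpe_test(
            self.matrix, self.group_responder, self.group_non_responder,
            varfun_r, varfun_nr, self.use_median, self.median_inflation,
        )
        frame["q"] = bh_fdr(frame["p"].to_numpy())
        return LPEResults(self, frame, varfun_r, varfun_nr)

    @classmethod
    def from_records(cls, matrix: ExpressionMatrix, records, **kwargs) -> "LPE":
        """Build groups from labeled :class:`~steroidsig.cohort.SampleRecord`s."""
        from .cohort import NON_RESPONDER, RESPONDER

        present = set(matrix.sample_ids)
        grp_r = [r.sample_id for r in records if r.response_label == RESPONDER and r.sample_id in present]
        grp_nr = [r.sample_id for r in records if r.response_label == NON_RESPONDER and r.sample_id in present]
        return cls(matrix, grp_r, grp_nr, **kwargs)


class LPEResults:
    """Per-gene LPE statistics with FDR adjustment and deterministic ranking."""

    def __init__(self, model: LPE, frame: pd.DataFrame,
                 varfun_responder: VarianceFunction,
                 varfun_non_responder: VarianceFunction):
        self.model = model
        self.frame = frame
        self.varfun_responder = varfun_responder
        self.varfun_non_responder = varfun_non_responder

    def add_fold_change(self, log2_matrix: ExpressionMatrix) -> "LPEResults":
        """Attach fold changes computed from a log2-scale matrix.

        For the pooled standardized analysis this is the per-batch
        quantile-normalized matrix, not the matrix the test ran on.
        """
        fc = fold_change(log2_matrix, self.model.group_responder, self.model.group_non_responder)
        self.frame["fold_change"] = fc.reindex(self.frame.index)
        return self

    def ranked_frame(self) -> pd.DataFrame:
        """Genes ranked by p ascending; ties broken by |z| descending, then id."""
        frame = self.frame.copy()
        frame["_absz"] = -frame["z"].abs()
        frame["_gid"] = frame.index
        out = frame.sort_values(["p", "_absz", "_gid"], kind="mergesort")
        return out.drop(columns=["_absz", "_gid"])

    def ranked_gene_ids(self) -> list[str]:
        return list(self.ranked_frame().index)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Ranked table of genes with FDR-adjusted p below ``alpha``."""
        ranked = self.ranked_frame()
        return ranked[ranked["q"] < alpha]

    def to_tsv(self, path) -> None:
        cols = ["q", "fold_change", "z", "p", "med_R", "med_NR", "abar_R", "abar_NR"]
        cols = [c for c in cols if c in self.frame.columns]
        self.ranked_frame()[cols].to_csv(path, sep="\t", index_label="gene_id")

    def summary(self, alpha: float = 0.05, top: int = 10) -> str:
        sig = self.significant(alpha)
        lines = [
            "Local-pooled-error differential expression",
            "==========================================",
            f"genes: {len(self.frame)}   "
            f"responders: {len(self.model.group_responder)}   "
            f"non-responders: {len(self.model.group_non_responder)}",
            f"location: {'median' if self.model.use_median else 'mean'}   "
            f"SE inflation: {'pi/2' if self.model.use_median and self.model.median_inflation else 'none'}",
            f"significant at FDR<{alpha:g}: {len(sig)}",
            "",
            f"top {top} genes (orientation: non-responder minus responder):",
        ]
        cols = [c for c in ("z", "p", "q", "fold_change") if c in self.frame.columns]
        lines.append(self.ranked_frame()[cols].head(top).to_string())
        return "\n".join(lines)
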