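"""Nearest-shrunken-centroid (PAM) classification of corticosteroid response.

Each class centroid is expressed as a standardized offset from the overall
centroid; offsets are soft-thresholded by a shrinkage parameter Delta, which
zeroes uninformative genes (implicit feature selection). A sample is assigned
to the class whose shrunken centroid is nearest in the (s_i + s0)-scaled
squared distance, penalized by -2 log(prior):

    d_ik  = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),  m_k = sqrt(1/n_k - 1/n)
    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0)
    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k

The positive class is the *non-responder* (corticosteroid-resistant) group:
sensitivity measures detection of resistance. Ties in the discriminant go to
the responder class.

Model/results pair in the statsmodels style::

    fitres = NearestShrunkenCentroid(matrix, labels).fit(delta=1.0)
    fitres.predict(matrix)
    fitres.selected_genes
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import NON_RESPONDER, RESPONDER
from .matrix import ExpressionMatrix

POSITIVE_CLASS = NON_RESPONDER

_CONVENTION = (
    "positive class = non_responder (corticosteroid resistance); "
    "sensitivity = TP/(TP+FN) on non-responders, specificity = TN/(TN+FP) on responders"
)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.data
    return pd.DataFrame(matrix)


class NearestShrunkenCentroid:
    """Shrunken-centroid model over a genes x samples matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix or DataFrame
        Genes in rows, samples in columns.
    labels : mapping or Series
        sample id -> class label; every matrix sample must be labeled.
    priors : mapping, optional
        Class priors; default empirical class proportions.
    """

    def __init__(self, matrix, labels, priors: Mapping[str, float] | None = None):
        self.data = _as_frame(matrix)
        labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
        missing = [s for s in self.data.columns if s not in labels.index]
        if missing:
            raise ValueError(f"unlabeled samples: {missing[:5]}")
        self.labels = labels.loc[self.data.columns]
        # responder first => np.argmin tie goes to responder
        uniq = list(pd.unique(self.labels))
        if set(uniq) == {RESPONDER, NON_RESPONDER}:
            self.classes = [RESPONDER, NON_RESPONDER]
        else:
            self.classes = sorted(uniq)
        counts = self.labels.value_counts()
        for k in self.classes:
            if counts.get(k, 0) < 2:
                raise ValueError(f"class {k!r} has fewer than 2 samples")
        if priors is None:
            n = len(self.labels)
            self.priors = {k: counts[k] / n for k in self.classes}
        else:
            total = sum(priors[k] for k in self.classes)
            self.priors = {k: priors[k] / total for k in self.classes}

    def fit(self, delta: float = 0.0) -> "NSCFit":
        if delta < 0:
            raise ValueError("delta must be non-negative")
        X = self.data.to_numpy(dtype=float)
        y = self.labels.to_numpy()
        n = X.shape[1]
        K = len(self.classes)

        overall = X.mean(axis=1)
        class_means = np.column_stack(
            [X[:, y == k].mean(axis=1) for k in self.classes]
        )
        n_k = np.array([(y == k).sum() for k in self.classes])
        # pooled within-class variance, denominator n - K
        ss = np.zeros(X.shape[0])
        for j, k in enumerate(self.classes):
            dev = X[:, y == k] - class_means[:, [j]]
            ss += (dev**2).sum(axis=1)
        s = np.sqrt(ss / (n - K))
        s0 = float(np.median(s))
        m_k = np.sqrt(1.0 / n_k - 1.0 / n)

        # genes constant within every class get a vanishing scale; floor it so
        # they carry no discriminating weight instead of dividing by zero
        scale = np.maximum(s + s0, 1e-12)
        d = (class_means - overall[:, None]) / (m_k[None, :] * scale[:, None])
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
        shrunken_centroids = overall[:, None] + (m_k[None, :] * scale[:, None]) * d_shrunk
        return NSCFit(
            model=self,
            delta=float(delta),
            gene_ids=list(self.data.index),
            overall_centroid=overall,
            class_centroids=class_means,
            shrunken_centroids=shrunken_centroids,
            pooled_sd=s,
            s0=s0,
            offsets=d,
            shrunken_offsets=d_shrunk,
            class_sizes=n_k,
        )

    def max_offset(self) -> float:
        """Largest |d_ik| of the unshrunken fit — the top of any Delta grid."""
        return float(np.abs(self.fit(0.0).offsets).max())


@dataclass
class NSCFit:
    """A fitted shrunken-centroid classifier at one shrinkage level."""

    model: NearestShrunkenCentroid
    delta: float
    gene_ids: list[str]
    overall_centroid: np.ndarray
    class_centroids: np.ndarray  # genes x classes, unshrunken
    shrunken_centroids: np.ndarray  # genes x classes
    pooled_sd: np.ndarray
    s0: float
    offsets: np.ndarray  # d_ik
    shrunken_offsets: np.ndarray  # d'_ik
    class_sizes: np.ndarray

    @property
    def classes(self) -> list[str]:
        return self.model.classes

    @property
    def selected(self) -> np.ndarray:
        """Boolean per gene: any class offset survives shrinkage."""
        return (self.shrunken_offsets != 0).any(axis=1)

    @property
    def selected_genes(self) -> list[str]:
        sel = self.selected
        return [g for g, keep in zip(self.gene_ids, sel) if keep]

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def discriminant(self, matrix) -> pd.DataFrame:
        """Per-sample, per-class penalized distances delta_k(x)."""
        frame = _as_frame(matrix)
        if list(frame.index) != self.gene_ids:
            try:
                frame = frame.loc[self.gene_ids]
            except KeyError as exc:
                raise ValueError("sample gene ids do not align with the model") from exc
        X = frame.to_numpy(dtype=float)
        denom = np.maximum(self.pooled_sd + self.s0, 1e-12) ** 2
        scores = np.empty((X.shape[1], len(self.classes)))
        for j in range(len(self.classes)):
            diff = X - self.shrunken_centroids[:, [j]]
            scores[:, j] = (diff**2 / denom[:, None]).sum(axis=0) - 2.0 * np.log(
                self.model.priors[self.classes[j]]
            )
        return pd.DataFrame(scores, index=frame.columns, columns=self.classes)

    def predict(self, matrix) -> pd.Series:
        """Class of the nearest shrunken centroid; ties -> responder."""
        scores = self.discriminant(matrix)
        idx = np.argmin(scores.to_numpy(), axis=1)
        return pd.Series(
            [self.classes[i] for i in idx], index=scores.index, name="prediction"
        )

    def to_json(self, path=None) -> str:
        payload = {
            "convention": _CONVENTION,
            "delta": self.delta,
            "s0": self.s0,
            "classes": self.classes,
            "priors": self.model.priors,
            "gene_ids": self.gene_ids,
            "overall_centroid": self.overall_centroid.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of samples into k folds, stratified by class (and batch)."""

    fold_of_sample: dict
    k: int
    seed: int | None

    def folds(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.k)]
        for sample, fold in self.fold_of_sample.items():
            out[fold].append(sample)
        return out


def stratified_folds(
    labels: Mapping[str, str],
    batch_of_sample: Mapping[str, int] | None = None,
    k: int = 10,
    seed: int | None = None,
) -> FoldAssignment:
    """Random equal-size folds preserving class (and batch) proportions.

    Samples are grouped into (class, batch) cells; each cell is shuffled and
    dealt round-robin with a carried offset, so fold sizes differ by at most
    one and every fold mirrors the cell composition as closely as possible.
    With 40 samples (20/20 classes over 2 batches) and k=10 each fold gets
    4 samples, 2 per class.
    """
    labels = dict(labels)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds sample count {len(labels)}")
    rng = np.random.default_rng(seed)
    cells: dict[tuple, list[str]] = {}
    for sample, label in labels.items():
        batch = batch_of_sample.get(sample) if batch_of_sample else None
        cells.setdefault((str(label), batch), []).append(sample)
    assignment: dict[str, int] = {}
    offset = 0
    for key in sorted(cells, key=str):
        members = sorted(cells[key])
        rng.shuffle(members)
        for i, sample in enumerate(members):
            assignment[sample] = (offset + i) % k
        offset += len(members)
    return FoldAssignment(assignment, k, seed)


@dataclass
class ClassificationMetrics:
    """Pooled confusion counts and the derived rates.

    Positive class = non-responder; accuracy follows
    ``100 * (TP + TN) / Total``. ``per_fold`` carries the per-fold confusion
    tuples (tp, tn, fp, fn) so macro-averages can be derived.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    per_fold: list[tuple[int, int, int, int]] = field(default_factory=list)
    convention: str = _CONVENTION

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return float("nan") if denom == 0 else 100.0 * self.tp / denom

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return float("nan") if denom == 0 else 100.0 * self.tn / denom

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    def macro_rates(self) -> dict:
        """Per-fold sensitivity/specificity/accuracy averaged over folds."""
        sens, spec, acc = [], [], []
        for tp, tn, fp, fn in self.per_fold:
            if tp + fn:
                sens.append(100.0 * tp / (tp + fn))
            if tn + fp:
                spec.append(100.0 * tn / (tn + fp))
            acc.append(100.0 * (tp + tn) / (tp + tn + fp + fn))
        mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
        return {
            "sensitivity": mean(sens),
            "specificity": mean(spec),
            "accuracy": mean(acc),
        }


def _confusion(truth: pd.Series, predicted: pd.Series) -> tuple[int, int, int, int]:
    tp = int(((truth == POSITIVE_CLASS) & (predicted == POSITIVE_CLASS)).sum())
    tn = int(((truth != POSITIVE_CLASS) & (predicted != POSITIVE_CLASS)).sum())
    fp = int(((truth != POSITIVE_CLASS) & (predicted == POSITIVE_CLASS)).sum())
    fn = int(((truth == POSITIVE_CLASS) & (predicted != POSITIVE_CLASS)).sum())
    return tp, tn, fp, fn


def cv_evaluate(
    matrix,
    labels: Mapping[str, str],
    gene_subset: Sequence[str],
    folds: FoldAssignment,
    delta: float = 0.0,
    priors: Mapping[str, float] | None = None,
    ranker: Callable[[pd.DataFrame, pd.Series], Sequence[str]] | None = None,
    subset_size: int | None = None,
) -> ClassificationMetrics:
    """k-fold cross-validation of the shrunken-centroid classifier.

    Default mode restricts every training fit to ``gene_subset`` (a gene list
    selected outside the CV loop — this reproduces the selection-bias of
    ranking on all samples). Passing ``ranker`` switches to honest selection:
    genes are re-ranked inside each training fold and the top
    ``subset_size`` (default ``len(gene_subset)``) are used.

    Confusion counts are pooled over folds (micro-average); per-fold counts
    are retained for macro-averaging.
    """
    frame = _as_frame(matrix)
    labels = pd.Series(dict(labels))
    if ranker is None and len(gene_subset) == 0:
        raise ValueError("gene_subset must be non-empty")
    size = subset_size if subset_size is not None else len(gene_subset)
    tp = tn = fp = fn = 0
    per_fold = []
    for fold_samples in folds.folds():
        if not fold_samples:
            continue
        train_samples = [s for s in frame.columns if s not in set(fold_samples)]
        train_labels = labels.loc[train_samples]
        if train_labels.nunique() < 2:
            raise ValueError("a training split lacks one of the classes")
        if ranker is not None:
            ranked = list(ranker(frame.loc[:, train_samples], train_labels))
            genes = ranked[:size]
        else:
            genes = list(gene_subset)
        train = frame.loc[genes, train_samples]
        test = frame.loc[genes, fold_samples]
        fitres = NearestShrunkenCentroid(train, train_labels, priors=priors).fit(delta)
        pred = fitres.predict(test)
        ftp, ftn, ffp, ffn = _confusion(labels.loc[fold_samples], pred)
        tp, tn, fp, fn = tp + ftp, tn + ftn, fp + ffp, fn + ffn
        per_fold.append((ftp, ftn, ffp, ffn))
    return ClassificationMetrics(tp, tn, fp, fn, per_fold)


DEFAULT_SIZES = (41, 40, 35, 30, 25, 20, 15, 10, 5)


def subset_sweep(
    matrix,
    labels: Mapping[str, str],
    ranked_genes: Sequence[str],
    sizes: Sequence[int] = DEFAULT_SIZES,
    folds: FoldAssignment | None = None,
    delta: float = 0.0,
    priors: Mapping[str, float] | None = None,
    ranker: Callable | None = None,
) -> pd.DataFrame:
    """CV metrics for the top-N gene subsets, one row per N (largest first).

    Mirrors the published sweep layout: columns N, specificity, sensitivity,
    accuracy (plus confusion counts). ``ranker`` enables honest within-fold
    re-ranking (``ranked_genes`` then only determines the universe).
    """
    if folds is None:
        raise ValueError("fold assignment is required")
    if max(sizes) > len(ranked_genes):
        raise ValueError(
            f"requested top-{max(sizes)} but only {len(ranked_genes)} ranked genes"
        )
    rows = []
    for n in sizes:
        metrics = cv_evaluate(
            matrix, labels, list(ranked_genes[:n]), folds, delta, priors,
            ranker=ranker, subset_size=n,
        )
        rows.append(
            {
                "n_genes": n,
                "specificity": metrics.specificity,
                "sensitivity": metrics.sensitivity,
                "accuracy": metrics.accuracy,
                "tp": metrics.tp, "tn": metrics.tn, "fp": metrics.fp, "fn": metrics.fn,
            }
        )
    return pd.DataFrame(rows)


def threshold_path(
    matrix,
    labels: Mapping[str, str],
    delta_grid: Sequence[float],
    folds: FoldAssignment,
    priors: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Unbiased shrinkage path: gene counts and CV metrics per Delta.

    For each Delta the full-data fit gives the surviving gene count, and the
    CV metrics come from fits on the training folds only (selection happens
    inside the loop, so the path is unbiased). Returns the path table and the
    accuracy-maximizing Delta; ties resolve to the larger Delta (fewer genes).
    """
    if len(delta_grid) == 0:
        raise ValueError("delta_grid must be non-empty")
    if any(d < 0 for d in delta_grid):
        raise ValueError("delta values must be non-negative")
    frame = _as_frame(matrix)
    model = NearestShrunkenCentroid(frame, labels, priors=priors)
    all_genes = list(frame.index)
    rows = []
    for delta in delta_grid:
        n_sel = model.fit(delta).n_selected
        metrics = cv_evaluate(frame, labels, all_genes, folds, delta, priors)
        rows.append(
            {
                "delta": float(delta),
                "n_genes": n_sel,
                "specificity": metrics.specificity,
                "sensitivity": metrics.sensitivity,
                "accuracy": metrics.accuracy,
            }
        )
    path = pd.DataFrame(rows)
    best = path.sort_values(["accuracy", "delta"], ascending=[False, False]).iloc[0]
    return path, float(best["delta"])
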