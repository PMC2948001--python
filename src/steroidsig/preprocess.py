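"""Gene-level normalization: background/log2, quantile normalization, batch scaling.

The probe-level steps of full RMA (background convolution, median polish) are
out of scope for gene-level matrices; background correction is a configurable
additive offset before the log2 transform. Quantile normalization and the
per-batch gene standardization follow the usual microarray conventions.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

#: Genes constant within a batch get SD replaced by this floor; their
#: standardized values become 0 rather than +/-inf.
SD_FLOOR = 1e-8


def background_correct_and_log(
    matrix: ExpressionMatrix, offset: float = 1.0
) -> ExpressionMatrix:
    """log2(value + offset) on a raw-scale matrix.

    ``offset`` is a simplified additive background stabilizer (default 1);
    it must be > 0 unless every value already is.
    """
    if matrix.scale != "raw":
        raise ValueError(f"expected raw-scale input, got {matrix.scale!r}")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    values = matrix.values
    if offset == 0 and (values <= 0).any():
        raise ValueError("non-positive values with offset 0")
    out = np.log2(values + offset)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        "log2",
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the mean empirical distribution.

    Each column's order statistics are replaced by the across-column mean of
    order statistics; ties within a column receive the average of the
    corresponding reference values (deterministic, permutation-invariant).
    Idempotent and rank-preserving within columns.
    """
    if matrix.scale not in ("log2", "log2_qnorm"):
        raise ValueError(f"expected log2-scale input, got {matrix.scale!r}")
    values = matrix.values
    n_genes, n_samples = values.shape
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if n_samples == 1:
        return ExpressionMatrix(matrix.data.copy(), "log2_qnorm")

    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        # average rank (1-based, ties averaged) mapped onto the reference
        # order statistics by linear interpolation between adjacent ones
        ranks = stats.rankdata(col, method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n_genes + 1), reference)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        "log2_qnorm",
    )


def standardize_within_batch(
    matrix: ExpressionMatrix,
    batch_of_sample: Mapping[str, int],
    center: bool = True,
    scale: bool = True,
    axis: str = "genes",
) -> ExpressionMatrix:
    """Gene-wise center/scale within each batch (R ``scale`` per batch).

    Removes additive per-gene batch offsets exactly: after standardization
    every gene has mean 0 (and SD 1) within each batch. ``axis="samples"``
    standardizes columns instead (exposed for completeness; it does not
    remove per-gene batch effects and is not used by the pipeline).
    """
    if axis not in ("genes", "samples"):
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    missing = [s for s in matrix.sample_ids if s not in batch_of_sample]
    if missing:
        raise ValueError(f"samples without batch assignment: {missing[:5]}")
    values = matrix.values.copy()
    batches = np.array([batch_of_sample[s] for s in matrix.sample_ids])
    for batch in np.unique(batches):
        cols = batches == batch
        if cols.sum() < 2:
            raise ValueError(f"batch {batch} has fewer than 2 samples")
        block = values[:, cols]
        if axis == "genes":
            if center:
                block = block - block.mean(axis=1, keepdims=True)
            if scale:
                sd = block.std(axis=1, ddof=1, keepdims=True)
                block = block / np.maximum(sd, SD_FLOOR)
                block[np.broadcast_to(sd < SD_FLOOR, block.shape)] = 0.0
        else:
            if center:
                block = block - block.mean(axis=0, keepdims=True)
            if scale:
                sd = block.std(axis=0, ddof=1, keepdims=True)
                block = block / np.maximum(sd, SD_FLOOR)
        values[:, cols] = block
    return ExpressionMatrix(
        pd.DataFrame(values, index=matrix.data.index, columns=matrix.data.columns),
        "standardized",
    )


def pool_batches(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate standardized per-batch matrices (gene order preserved)."""
    if not matrices:
        raise ValueError("no matrices to pool")
    first = matrices[0]
    for m in matrices[1:]:
        if list(m.data.index) != list(first.data.index):
            raise ValueError("gene ids differ between matrices; cannot pool")
        if m.scale != first.scale:
            raise ValueError("scale tags differ between matrices; cannot pool")
    pooled = pd.concat([m.data for m in matrices], axis=1)
    if pooled.columns.has_duplicates:
        raise ValueError("sample ids overlap between matrices")
    return ExpressionMatrix(pooled, first.scale)
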