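"""Shared fixtures: synthetic cohorts at the study scale and small variants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from steroidsig import (
    LPE,
    ExpressionMatrix,
    SyntheticSpec,
    background_correct_and_log,
    generate_cohort,
    pool_batches,
    quantile_normalize,
    standardize_within_batch,
)
from steroidsig.cohort import NON_RESPONDER, RESPONDER


def groups_of(records):
    grp_r = [r.sample_id for r in records if r.response_label == RESPONDER]
    grp_nr = [r.sample_id for r in records if r.response_label == NON_RESPONDER]
    return grp_r, grp_nr


def batch_qnorm(matrix, records, batch):
    batch_of = {r.sample_id: r.batch_id for r in records}
    sub = matrix.subset_samples([s for s in matrix.sample_ids if batch_of[s] == batch])
    return quantile_normalize(background_correct_and_log(sub))


def pooled_standardized(matrix, records):
    batch_of = {r.sample_id: r.batch_id for r in records}
    parts = [
        standardize_within_batch(batch_qnorm(matrix, records, b), batch_of)
        for b in sorted({r.batch_id for r in records})
    ]
    return pool_batches(parts)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study's design points (21,176 genes, 200 planted)."""
    return generate_cohort(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def default_pooled_results(default_cohort):
    """Pooled batch-standardized LPE fit of the default cohort."""
    matrix, records, truth = default_cohort
    pooled = pooled_standardized(matrix, records)
    grp_r, grp_nr = groups_of(records)
    return LPE(pooled, grp_r, grp_nr).fit(), pooled, records, truth


@pytest.fixture()
def small_cohort():
    """A fast cohort: 2,000 genes, 50 planted, strong-ish effects."""
    return generate_cohort(SyntheticSpec(n_genes=2000, n_de_genes=50, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
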