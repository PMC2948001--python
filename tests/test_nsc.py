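"""Shrunken-centroid classifier: fit arithmetic, prediction, CV machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from steroidsig.cohort import NON_RESPONDER, RESPONDER
from steroidsig.nsc import (
    ClassificationMetrics,
    NearestShrunkenCentroid,
    cv_evaluate,
    stratified_folds,
    subset_sweep,
    threshold_path,
)

R, N = RESPONDER, NON_RESPONDER


def toy_frame():
    """2 genes x 4 samples, hand-computable."""
    return pd.DataFrame(
        [[0.0, 2.0, 4.0, 6.0], [1.0, 1.0, 1.0, 3.0]],
        index=["g1", "g2"],
        columns=["a", "b", "c", "d"],
    )


TOY_LABELS = {"a": R, "b": R, "c": N, "d": N}


class TestFitArithmetic:
    def test_toy_fit_matches_hand_computation(self):
        # by hand: class means g1 (1, 5), g2 (1, 2); overall (3, 1.5)
        # pooled SS/(n-K): s1 = sqrt(2), s2 = 1; s0 = median = (sqrt(2)+1)/2
        # m_k = sqrt(1/2 - 1/4) = 0.5
        fit = NearestShrunkenCentroid(toy_frame(), TOY_LABELS).fit(delta=0.5)
        s1, s2 = math.sqrt(2.0), 1.0
        s0 = (s1 + s2) / 2.0
        assert np.allclose(fit.pooled_sd, [s1, s2])
        assert np.isclose(fit.s0, s0)
        d1 = (1.0 - 3.0) / (0.5 * (s1 + s0))
        d2 = (1.0 - 1.5) / (0.5 * (s2 + s0))
        assert np.allclose(fit.offsets[:, 0], [d1, d2])
        assert np.allclose(fit.offsets[:, 1], [-d1, -d2])
        # |d2| = 0.453 < 0.5 so gene 2 is shrunk away; gene 1 survives
        assert np.allclose(
            fit.shrunken_offsets[:, 0], [math.copysign(abs(d1) - 0.5, d1), 0.0]
        )
        assert fit.selected_genes == ["g1"]
        assert np.isclose(fit.shrunken_centroids[0, 0], 3.0 + 0.5 * (s1 + s0) * (d1 + 0.5))
        assert np.allclose(fit.shrunken_centroids[1], [1.5, 1.5])

    def test_zero_delta_keeps_empirical_centroids(self):
        fit = NearestShrunkenCentroid(toy_frame(), TOY_LABELS).fit(delta=0.0)
        assert np.allclose(fit.shrunken_centroids, fit.class_centroids)

    def test_large_delta_zeroes_everything(self):
        model = NearestShrunkenCentroid(toy_frame(), TOY_LABELS)
        fit = model.fit(delta=model.max_offset() + 1.0)
        assert fit.n_selected == 0
        assert np.allclose(fit.shrunken_centroids, fit.overall_centroid[:, None])

    def test_two_class_offsets_are_symmetric_with_equal_sizes(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 8)),
                             index=[f"g{i}" for i in range(30)],
                             columns=[f"s{j}" for j in range(8)])
        labels = {f"s{j}": R if j < 4 else N for j in range(8)}
        fit = NearestShrunkenCentroid(frame, labels).fit(0.0)
        assert np.allclose(fit.offsets[:, 0], -fit.offsets[:, 1])

    def test_class_with_one_sample_rejected(self):
        labels = {"a": R, "b": N, "c": N, "d": N}
        with pytest.raises(ValueError):
            NearestShrunkenCentroid(toy_frame(), labels)


class TestPrediction:
    def test_sample_at_centroid_is_classified_there(self):
        fit = NearestShrunkenCentroid(toy_frame(), TOY_LABELS).fit(0.0)
        probe = pd.DataFrame(
            fit.shrunken_centroids[:, [1]], index=["g1", "g2"], columns=["x"]
        )
        assert fit.predict(probe).iloc[0] == N

    def test_tie_goes_to_responder(self):
        frame = pd.DataFrame([[0.0, 0.0, 2.0, 2.0]], index=["g1"],
                             columns=["a", "b", "c", "d"])
        fit = NearestShrunkenCentroid(frame, TOY_LABELS).fit(0.0)
        midpoint = pd.DataFrame([[1.0]], index=["g1"], columns=["x"])
        assert fit.predict(midpoint).iloc[0] == R

    def test_matches_brute_force_discriminant_on_random_instances(self, rng):
        # independent oracle: recompute centroids, pooled SD, s0, shrinkage and
        # the penalized distance from first principles with plain loops
        for _ in range(100):
            n_genes = int(rng.integers(2, 6))
            n_r = int(rng.integers(2, 5))
            n_n = int(rng.integers(2, 5))
            X = rng.normal(size=(n_genes, n_r + n_n))
            cols = [f"s{j}" for j in range(n_r + n_n)]
            frame = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)], columns=cols)
            labels = {c: R if j < n_r else N for j, c in enumerate(cols)}
            delta = float(rng.uniform(0, 2))
            fit = NearestShrunkenCentroid(frame, labels).fit(delta)
            probe = rng.normal(size=n_genes)

            n = n_r + n_n
            scores = {}
            for k, idx, n_k in ((R, range(n_r), n_r), (N, range(n_r, n), n_n)):
                score = -2.0 * math.log(n_k / n)
                for i in range(n_genes):
                    xbar = X[i].mean()
                    mean_k = X[i, list(idx)].mean()
                    ss = 0.0
                    for kk, kidx in ((R, range(n_r)), (N, range(n_r, n))):
                        mk = X[i, list(kidx)].mean()
                        ss += sum((X[i, j] - mk) ** 2 for j in kidx)
                    s_i = math.sqrt(ss / (n - 2))
                    s0 = float(np.median(np.sqrt([
                        sum((X[g, j] - X[g, list(range(n_r))].mean()) ** 2
                            for j in range(n_r))
                        + sum((X[g, j] - X[g, list(range(n_r, n))].mean()) ** 2
                              for j in range(n_r, n))
                        for g in range(n_genes)
                    ]) / math.sqrt(n - 2)))
                    m_k = math.sqrt(1.0 / n_k - 1.0 / n)
                    d = (mean_k - xbar) / (m_k * (s_i + s0))
                    d_shr = math.copysign(max(abs(d) - delta, 0.0), d)
                    centroid = xbar + m_k * (s_i + s0) * d_shr
                    score += (probe[i] - centroid) ** 2 / (s_i + s0) ** 2
                scores[k] = score
            oracle = R if scores[R] <= scores[N] else N
            pred = fit.predict(
                pd.DataFrame(probe[:, None], index=frame.index, columns=["x"])
            ).iloc[0]
            assert pred == oracle

    def test_invariant_to_constant_gene_shift(self, rng):
        frame = pd.DataFrame(rng.normal(size=(10, 8)),
                             index=[f"g{i}" for i in range(10)],
                             columns=[f"s{j}" for j in range(8)])
        labels = {f"s{j}": R if j < 4 else N for j in range(8)}
        probe = pd.DataFrame(rng.normal(size=(10, 3)), index=frame.index,
                             columns=["x", "y", "z"])
        base = NearestShrunkenCentroid(frame, labels).fit(0.3).predict(probe)
        shifted_frame = frame.copy()
        shifted_frame.iloc[4] += 100.0
        shifted_probe = probe.copy()
        shifted_probe.iloc[4] += 100.0
        after = NearestShrunkenCentroid(shifted_frame, labels).fit(0.3).predict(shifted_probe)
        assert (base == after).all()

    def test_one_gene_zero_delta_is_scaled_nearest_mean(self, rng):
        values = rng.normal(size=(1, 8))
        frame = pd.DataFrame(values, index=["g1"], columns=[f"s{j}" for j in range(8)])
        labels = {f"s{j}": R if j < 4 else N for j in range(8)}
        fit = NearestShrunkenCentroid(frame, labels,
                                      priors={R: 0.5, N: 0.5}).fit(0.0)
        probes = rng.normal(size=(1, 20))
        pred = fit.predict(pd.DataFrame(probes, index=["g1"],
                                        columns=[f"p{j}" for j in range(20)]))
        mean_r, mean_n = values[0, :4].mean(), values[0, 4:].mean()
        expected = [R if abs(x - mean_r) <= abs(x - mean_n) else N for x in probes[0]]
        assert list(pred) == expected

    def test_gene_mismatch_rejected(self):
        fit = NearestShrunkenCentroid(toy_frame(), TOY_LABELS).fit(0.0)
        bad = pd.DataFrame([[1.0]], index=["unknown"], columns=["x"])
        with pytest.raises(ValueError):
            fit.predict(bad)


class TestFolds:
    def _labels40(self):
        labels, batches = {}, {}
        for j in range(40):
            sid = f"s{j}"
            labels[sid] = R if j % 2 == 0 else N
            batches[sid] = 1 if j < 20 else 2
        return labels, batches

    def test_forty_samples_ten_folds_of_four(self):
        labels, batches = self._labels40()
        fa = stratified_folds(labels, batches, k=10, seed=5)
        folds = fa.folds()
        assert len(folds) == 10
        for fold in folds:
            assert len(fold) == 4
            assert sum(labels[s] == R for s in fold) == 2

    def test_partition_and_determinism(self):
        labels, batches = self._labels40()
        fa1 = stratified_folds(labels, batches, k=10, seed=9)
        fa2 = stratified_folds(labels, batches, k=10, seed=9)
        assert fa1.fold_of_sample == fa2.fold_of_sample
        everyone = [s for fold in fa1.folds() for s in fold]
        assert sorted(everyone) == sorted(labels)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds({"a": R, "b": N}, None, k=3)


def separable_data(n_genes=20, per_class=10, gap=10.0, noise=0.05, seed=2):
    rng = np.random.default_rng(seed)
    cols = [f"s{j}" for j in range(2 * per_class)]
    labels = {c: R if j < per_class else N for j, c in enumerate(cols)}
    X = rng.normal(0, noise, size=(n_genes, 2 * per_class))
    X[:5, per_class:] += gap
    frame = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    return frame, labels


class TestCrossValidation:
    def test_separable_classes_are_perfect(self):
        frame, labels = separable_data()
        folds = stratified_folds(labels, None, k=10, seed=1)
        metrics = cv_evaluate(frame, labels, list(frame.index), folds)
        assert metrics.sensitivity == 100.0 and metrics.specificity == 100.0
        assert metrics.accuracy == 100.0

    def test_accuracy_formula_is_exact_on_pooled_counts(self):
        metrics = ClassificationMetrics(tp=16, tn=14, fp=6, fn=4)
        assert metrics.accuracy == 100.0 * (16 + 14) / 40
        assert metrics.sensitivity == 80.0 and metrics.specificity == 70.0

    def test_permuted_labels_score_near_chance(self):
        frame, labels = separable_data(noise=0.5)
        samples = list(frame.columns)
        accs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            perm = rng.permutation([labels[s] for s in samples])
            plabels = dict(zip(samples, perm))
            folds = stratified_folds(plabels, None, k=5, seed=seed)
            accs.append(cv_evaluate(frame, plabels, list(frame.index), folds).accuracy)
        assert abs(np.mean(accs) - 50.0) < 15.0

    def test_leave_one_out_matches_direct_loop(self):
        frame, labels = separable_data(n_genes=6, per_class=4, gap=1.0, noise=1.0)
        n = frame.shape[1]
        folds = stratified_folds(labels, None, k=n, seed=0)
        metrics = cv_evaluate(frame, labels, list(frame.index), folds)
        tp = tn = fp = fn = 0
        for held in frame.columns:
            train = [c for c in frame.columns if c != held]
            fit = NearestShrunkenCentroid(frame[train],
                                          {c: labels[c] for c in train}).fit(0.0)
            pred = fit.predict(frame[[held]]).iloc[0]
            truth = labels[held]
            tp += truth == N and pred == N
            tn += truth == R and pred == R
            fp += truth == R and pred == N
            fn += truth == N and pred == R
        assert (metrics.tp, metrics.tn, metrics.fp, metrics.fn) == (tp, tn, fp, fn)

    def test_training_split_without_both_classes_rejected(self):
        frame, labels = separable_data(per_class=2)
        folds = stratified_folds(labels, None, k=2, seed=0)
        bad = {s: (R if s in folds.folds()[0] else N) for s in frame.columns}
        with pytest.raises(ValueError):
            cv_evaluate(frame, bad, list(frame.index), folds)


class TestSweepAndPath:
    def test_sweep_rows_follow_requested_sizes(self):
        frame, labels = separable_data(n_genes=60)
        folds = stratified_folds(labels, None, k=5, seed=3)
        sizes = [41, 40, 35, 30, 25, 20, 15, 10, 5]
        table = subset_sweep(frame, labels, list(frame.index), sizes, folds)
        assert list(table["n_genes"]) == sizes
        assert set(table.columns) >= {"n_genes", "specificity", "sensitivity", "accuracy"}

    def test_separable_single_size_is_perfect(self):
        frame, labels = separable_data()
        folds = stratified_folds(labels, None, k=5, seed=3)
        table = subset_sweep(frame, labels, list(frame.index), [5], folds)
        assert table.loc[0, ["specificity", "sensitivity", "accuracy"]].tolist() == [
            100.0, 100.0, 100.0]

    def test_oversized_subset_rejected(self):
        frame, labels = separable_data(n_genes=10)
        folds = stratified_folds(labels, None, k=5, seed=3)
        with pytest.raises(ValueError):
            subset_sweep(frame, labels, list(frame.index), [11], folds)

    def test_noisier_data_degrades_mean_accuracy(self):
        folds_seed = 4
        means = []
        for noise in (0.5, 4.0):
            accs = []
            for seed in range(5):
                frame, labels = separable_data(n_genes=40, gap=1.0, noise=noise,
                                               seed=seed)
                folds = stratified_folds(labels, None, k=5, seed=folds_seed)
                table = subset_sweep(frame, labels, list(frame.index),
                                     [20, 10, 5], folds)
                accs.append(table["accuracy"].mean())
            means.append(np.mean(accs))
        assert means[0] > means[1]

    def test_path_endpoints(self):
        frame, labels = separable_data(n_genes=30)
        folds = stratified_folds(labels, None, k=5, seed=6)
        model = NearestShrunkenCentroid(frame, labels)
        top = model.max_offset() + 1.0
        path, best = threshold_path(frame, labels, [0.0, top], folds)
        assert path.loc[path.delta == 0.0, "n_genes"].iloc[0] == 30
        assert path.loc[path.delta == top, "n_genes"].iloc[0] == 0
        # with every offset shrunk away, CV predicts the majority class
        assert path.loc[path.delta == top, "accuracy"].iloc[0] == 50.0

    def test_ties_prefer_larger_delta(self):
        frame, labels = separable_data()
        folds = stratified_folds(labels, None, k=5, seed=6)
        path, best = threshold_path(frame, labels, [0.0, 0.5, 1.0], folds)
        perfect = path[path.accuracy == path.accuracy.max()]
        assert best == perfect["delta"].max()

    def test_best_delta_recovers_planted_genes(self):
        rng = np.random.default_rng(42)
        n_genes, per_class = 300, 20
        cols = [f"s{j}" for j in range(2 * per_class)]
        labels = {c: R if j < per_class else N for j, c in enumerate(cols)}
        X = rng.normal(size=(n_genes, 2 * per_class))
        planted = [f"g{i}" for i in range(50)]
        X[:50, per_class:] += 0.9
        frame = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)], columns=cols)
        folds = stratified_folds(labels, None, k=5, seed=7)
        model = NearestShrunkenCentroid(frame, labels)
        grid = np.linspace(0, model.max_offset(), 15)
        path, best = threshold_path(frame, labels, grid, folds)
        selected = set(model.fit(best).selected_genes)
        recall = len(selected & set(planted)) / 50
        assert recall >= 0.8
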