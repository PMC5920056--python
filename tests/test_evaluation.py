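"""Regression harness: recovery on constructed instances, metrics, leakage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from distinctcv import (
    Partition,
    PartitionCollection,
    RegressionSpec,
    TargetMatrix,
    compare_methods,
    distinctness_accuracy_correlation,
    evaluate_collection,
    fit_predict_partition,
    partition_accuracy,
    pooled_cv_accuracy,
    random_kfold,
)

from .conftest import make_conditions


def linear_instance(n_train=100, n_test=20, n_features=5, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_train + n_test, n_features))
    beta = np.zeros(n_features)
    beta[:3] = [1.5, -2.0, 0.7]
    y = X @ beta + noise * rng.normal(size=n_train + n_test)
    return X[:n_train], y[:n_train], X[n_train:], y[n_train:]


class TestFitPredict:
    def test_elastic_net_recovers_noiseless_linear_target(self):
        Xtr, ytr, Xte, yte = linear_instance()
        spec = RegressionSpec(
            method="elastic_net", seed=0, enet_tol=1e-14, enet_max_iter=100_000
        )
        pred = fit_predict_partition(Xtr, ytr, Xte, spec)
        rmsd = np.sqrt(np.mean((pred - yte) ** 2))
        assert rmsd < 1e-6

    @pytest.mark.parametrize("method", ["lars", "elastic_net", "svr_rbf"])
    def test_predictions_are_deterministic_given_seed(self, method):
        Xtr, ytr, Xte, _ = linear_instance(seed=1, noise=0.5)
        spec = RegressionSpec(method=method, seed=42)
        a = fit_predict_partition(Xtr, ytr, Xte, spec)
        b = fit_predict_partition(Xtr, ytr, Xte, spec)
        assert np.array_equal(a, b)

    def test_constant_features_give_training_mean(self):
        # all features zero-variance -> intercept-only model
        Xtr = np.ones((30, 4))
        ytr = np.linspace(0, 3, 30)
        Xte = np.ones((5, 4)) + 2.0
        spec = RegressionSpec(method="elastic_net", seed=0)
        with pytest.warns(UserWarning, match="zero-variance"):
            pred = fit_predict_partition(Xtr, ytr, Xte, spec)
        assert np.allclose(pred, ytr.mean())

    def test_zero_variance_target_rejected(self):
        Xtr, _, Xte, _ = linear_instance(seed=2)
        spec = RegressionSpec(method="lars", seed=0)
        with pytest.raises(ValueError, match="zero-variance target"):
            fit_predict_partition(Xtr, np.ones(len(Xtr)), Xte, spec)

    def test_lars_sparser_model_wins_ties(self):
        # with a single informative feature, inner CV should not pick more
        # active predictors than needed
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 10))
        y = 2.0 * X[:, 0]
        spec = RegressionSpec(method="lars", lars_active_sizes=(1, 2, 5), seed=0)
        pred = fit_predict_partition(X[:50], y[:50], X[50:], spec)
        assert np.sqrt(np.mean((pred - y[50:]) ** 2)) < 1e-8


def _toy_targets(values, gene_ids=("g0",)):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return TargetMatrix(
        values=values,
        condition_ids=tuple(f"c{i}" for i in range(values.shape[0])),
        gene_ids=gene_ids,
    )


class TestAccuracyMetrics:
    def test_pooled_pcc_perfect_and_antiperfect(self):
        y = np.arange(9, dtype=float)
        targets = _toy_targets(y)
        coll = random_kfold(9, 3, seed=0)
        perfect = {i: y[p.test_array][:, None] for i, p in enumerate(coll)}
        flipped = {i: -y[p.test_array][:, None] for i, p in enumerate(coll)}
        assert pooled_cv_accuracy(coll, targets, perfect)["g0"] == pytest.approx(1.0)
        assert pooled_cv_accuracy(coll, targets, flipped)["g0"] == pytest.approx(-1.0)

    def test_pooled_pcc_matches_hand_computation(self):
        y = np.array([1.0, 2.0, 4.0, 3.0, 5.0, 8.0, 6.0, 9.0, 7.0])
        pred = np.array([1.2, 1.8, 3.5, 3.1, 5.5, 7.0, 6.3, 8.1, 7.4])
        targets = _toy_targets(y)
        coll = random_kfold(9, 3, seed=1)
        preds = {i: pred[p.test_array][:, None] for i, p in enumerate(coll)}
        got = pooled_cv_accuracy(coll, targets, preds)["g0"]
        yc, pc = y - y.mean(), pred - pred.mean()
        expected = (yc * pc).sum() / np.sqrt((yc**2).sum() * (pc**2).sum())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_prediction_reported_missing_not_zero(self):
        y = np.arange(6, dtype=float)
        targets = _toy_targets(y)
        coll = random_kfold(6, 2, seed=0)
        preds = {i: np.full((3, 1), 2.5) for i in range(2)}
        with pytest.warns(UserWarning, match="undefined"):
            pcc = pooled_cv_accuracy(coll, targets, preds)
        assert np.isnan(pcc["g0"])

    def test_partition_metrics_offset_invariance(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        targets = _toy_targets(y)
        p = Partition(frozenset(range(5)), frozenset({5}))
        targets6 = _toy_targets(np.append(y, 0.0))
        acc = partition_accuracy(p, targets6, (y + 2.0)[:, None])
        assert acc.loc["g0", "rmsd"] == pytest.approx(2.0)
        assert acc.loc["g0", "pcc"] == pytest.approx(1.0)

    def test_partition_metrics_match_direct_formulas(self):
        y = np.array([2.0, -1.0, 0.5, 3.0, 1.0])
        pred = np.array([1.5, -0.5, 1.0, 2.0, 1.5])
        targets6 = _toy_targets(np.append(y, 0.0))
        p = Partition(frozenset(range(5)), frozenset({5}))
        acc = partition_accuracy(p, targets6, pred[:, None])
        assert acc.loc["g0", "rmsd"] == pytest.approx(
            np.sqrt(np.mean((pred - y) ** 2))
        )
        yc, pc = y - y.mean(), pred - pred.mean()
        assert acc.loc["g0", "pcc"] == pytest.approx(
            (yc * pc).sum() / np.sqrt((yc**2).sum() * (pc**2).sum())
        )

    def test_pcc_affine_invariant_rmsd_not(self):
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        targets6 = _toy_targets(np.append(y, 0.0))
        p = Partition(frozenset(range(5)), frozenset({5}))
        scaled = (2.0 * y + 1.0)[:, None]
        acc = partition_accuracy(p, targets6, scaled)
        assert acc.loc["g0", "pcc"] == pytest.approx(1.0)
        assert acc.loc["g0", "rmsd"] > 0

    def test_tiny_test_set_pcc_missing_rmsd_kept(self):
        targets = _toy_targets([1.0, 2.0, 3.0])
        p = Partition(frozenset({0, 1}), frozenset({2}))
        with pytest.warns(UserWarning, match="smaller than 3"):
            acc = partition_accuracy(p, targets, np.array([[1.5], [2.5]]))
        assert np.isnan(acc.loc["g0", "pcc"])
        assert acc.loc["g0", "rmsd"] == pytest.approx(0.5)


class TestSpearman:
    def test_perfectly_monotone_accuracies(self):
        eta = [0.1, 0.2, 0.3, 0.4]
        acc = pd.DataFrame({"up": [1, 2, 3, 4], "down": [4.0, 3.0, 2.0, 1.0]})
        rho = distinctness_accuracy_correlation(eta, acc)
        assert rho["up"] == pytest.approx(1.0)
        assert rho["down"] == pytest.approx(-1.0)

    def test_tied_accuracies_use_average_ranks(self):
        eta = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        acc = pd.DataFrame({"g": [2.0, 1.0, 3.0, 3.0, 5.0, 6.0]})
        # ranks of acc with the tie averaged: [2, 1, 3.5, 3.5, 5, 6];
        # Pearson of those ranks against [1..6] = 0.9276735...
        r = np.array([2.0, 1.0, 3.5, 3.5, 5.0, 6.0])
        e = np.arange(1.0, 7.0)
        rc, ec = r - r.mean(), e - e.mean()
        expected = (rc * ec).sum() / np.sqrt((rc**2).sum() * (ec**2).sum())
        got = distinctness_accuracy_correlation(eta, acc)["g"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_accuracy_reported_missing(self):
        eta = [0.1, 0.2, 0.3, 0.4]
        acc = pd.DataFrame({"g": [1.0, 1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="constant"):
            rho = distinctness_accuracy_correlation(eta, acc)
        assert np.isnan(rho["g"])


@pytest.fixture(scope="module")
def small_eval():
    cond = make_conditions(30, 6, 77)
    rng = np.random.default_rng(78)
    Y = cond.values[:, :2] @ np.array([[1.0, -0.5], [0.3, 1.2]]) + 0.1 * rng.normal(
        size=(30, 2)
    )
    targets = TargetMatrix(
        values=Y, condition_ids=cond.condition_ids, gene_ids=("g0", "g1")
    )
    coll = random_kfold(30, 3, seed=5)
    return cond, targets, coll


class TestCompareAndLeakage:
    def test_compare_identical_results_is_all_zero(self, small_eval):
        cond, targets, coll = small_eval
        spec = RegressionSpec(method="lars", seed=1)
        res = evaluate_collection(cond, targets, coll, spec)
        diff, summary = compare_methods(res, res)
        assert np.allclose(diff["rmsd_diff"], 0.0)
        assert np.allclose(summary[["q1", "median", "q3"]], 0.0)

    def test_compare_constant_offset(self, small_eval):
        cond, targets, coll = small_eval
        spec = RegressionSpec(method="lars", seed=1)
        a = evaluate_collection(cond, targets, coll, spec)
        import copy

        b = copy.deepcopy(a)
        b.per_partition = b.per_partition.assign(rmsd=b.per_partition["rmsd"] + 1.0)
        diff, _ = compare_methods(a, b)
        assert np.allclose(diff["rmsd_diff"], -1.0)

    def test_compare_mismatched_partitions_rejected(self, small_eval):
        cond, targets, coll = small_eval
        spec = RegressionSpec(method="lars", seed=1)
        a = evaluate_collection(cond, targets, coll, spec)
        other = random_kfold(30, 3, seed=6)
        b = evaluate_collection(cond, targets, other, spec)
        with pytest.raises(ValueError, match="different partitions"):
            compare_methods(a, b)

    def test_shuffling_test_targets_leaves_predictions_untouched(self, small_eval):
        # training never sees test-fold targets, in fitting or normalization
        cond, targets, coll = small_eval
        p = coll.partitions[0]
        spec = RegressionSpec(method="elastic_net", seed=3)
        X, Y = cond.values, targets.values
        train, test = p.train_array, p.test_array
        pred = fit_predict_partition(X[train], Y[train, 0], X[test], spec)
        Y_shuffled = Y.copy()
        Y_shuffled[test, 0] = np.random.default_rng(0).permutation(Y[test, 0])
        pred_after = fit_predict_partition(X[train], Y_shuffled[train, 0], X[test], spec)
        assert np.array_equal(pred, pred_after)


class TestEvaluateCollection:
    def test_pooled_predictions_cover_every_condition_once(self):
        cond = make_conditions(24, 5, 55)
        rng = np.random.default_rng(56)
        Y = cond.values[:, :1] * 2.0 + 0.2 * rng.normal(size=(24, 1))
        targets = TargetMatrix(
            values=Y, condition_ids=cond.condition_ids, gene_ids=("g0",)
        )
        coll = random_kfold(24, 4, seed=2)
        res = evaluate_collection(cond, targets, coll, RegressionSpec("lars", seed=0))
        assert res.pooled_pcc is not None
        assert sum(v.shape[0] for v in res.predictions.values()) == 24
        assert res.per_partition.shape[0] == 4  # one gene x four partitions
        assert res.pooled_pcc["g0"] > 0.9
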