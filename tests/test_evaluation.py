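"""Split plans, RFE selection, SVM scoring and the experiment loop."""

from __future__ import annotations

import numpy as np
import pytest

import pulsescale as ps
from pulsescale.evaluation import EvalResult, WorkloadClassifier


def _toy_table(n=100, n_features=30, n_informative=5, shift=1.5, seed=0):
    """Gaussian features; the first n_informative carry all class signal."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, n_features))
    X[:, :n_informative] += shift * y[:, None]
    return X, y


class TestMakeSplits:
    def test_250_pairs_and_partition(self):
        y = np.repeat([0, 1], 50)
        plan = ps.make_splits(y, folds=5, repeats=50, base_seed=1)
        assert len(plan) == 250
        # within each repeat the test folds partition the samples
        for rep in range(50):
            test_all = np.concatenate(
                [plan.splits[rep * 5 + f][1] for f in range(5)]
            )
            np.testing.assert_array_equal(np.sort(test_all), np.arange(100))

    def test_stratification_balance(self):
        y = np.repeat([0, 1], 50)
        plan = ps.make_splits(y, folds=5, repeats=2, base_seed=3)
        for _, test_idx in plan.splits:
            counts = np.bincount(y[test_idx], minlength=2)
            assert abs(counts[0] - counts[1]) <= 1

    def test_deterministic(self):
        y = np.repeat([0, 1], 20)
        a = ps.make_splits(y, repeats=3, base_seed=9)
        b = ps.make_splits(y, repeats=3, base_seed=9)
        for (tr1, te1), (tr2, te2) in zip(a.splits, b.splits):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            ps.make_splits(np.array([0, 0, 0, 1, 1]), folds=5)


class TestRFE:
    def test_returns_k_indices(self):
        X, y = _toy_table()
        sel = ps.select_features_rfe(X, y, k=20, seed=0)
        assert len(sel) == 20
        assert len(np.unique(sel)) == 20

    def test_recovers_planted_signal(self):
        X, y = _toy_table(n_features=40, n_informative=5, shift=2.0, seed=1)
        sel = ps.select_features_rfe(X, y, k=10, seed=2)
        assert set(range(5)) <= set(sel)

    def test_deterministic_given_seed(self):
        X, y = _toy_table(seed=4)
        a = ps.select_features_rfe(X, y, k=10, seed=5)
        b = ps.select_features_rfe(X, y, k=10, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_k_too_large_rejected(self):
        X, y = _toy_table(n_features=10)
        with pytest.raises(ValueError, match="exceeds"):
            ps.select_features_rfe(X, y, k=20)


class TestSVM:
    def test_separable_classes_perfect(self):
        X, y = _toy_table(shift=8.0, seed=6)
        acc, f1 = ps.train_eval_svm(X, y, X, y)
        assert acc == 1.0 and f1 == 1.0

    def test_single_class_train_rejected(self):
        X, y = _toy_table()
        with pytest.raises(ValueError, match="single class"):
            ps.train_eval_svm(X, np.zeros(len(X)), X, y)

    def test_degenerate_prediction_scores(self):
        """All-one-class prediction on a balanced fold: accuracy 0.5 and F1
        by the positive-class convention."""
        rng = np.random.default_rng(0)
        Xtr = np.vstack([np.zeros((20, 3)), np.ones((20, 3)) * 0.01])
        ytr = np.repeat([0, 1], 20)
        Xte = rng.normal(size=(20, 3)) * 100 - 200  # far from both classes
        yte = np.repeat([0, 1], 10)
        acc, f1 = ps.train_eval_svm(Xtr, ytr, Xte, yte)
        assert acc == 0.5
        # all-0 predictions give F1 = 0; all-1 give 2·0.5·1/(0.5+1) = 2/3
        assert f1 == pytest.approx(0.0) or f1 == pytest.approx(2 / 3)


class TestWorkloadClassifier:
    def test_fit_predict_and_attributes(self):
        X, y = _toy_table(shift=3.0, seed=7)
        clf = WorkloadClassifier(n_features=10, random_state=0).fit(X, y)
        assert clf.selected_.shape == (10,)
        assert clf.predict(X).shape == (len(y),)
        assert clf.score(X, y) > 0.9

    def test_sklearn_cross_val_integration(self):
        from sklearn.model_selection import cross_val_score

        X, y = _toy_table(shift=3.0, seed=8)
        scores = cross_val_score(
            WorkloadClassifier(n_features=5, random_state=0), X, y, cv=3
        )
        assert scores.mean() > 0.8

    def test_get_set_params(self):
        clf = WorkloadClassifier(C=2.0)
        assert clf.get_params()["C"] == 2.0
        clf.set_params(n_features=7)
        assert clf.n_features == 7


@pytest.fixture(scope="module")
def small_run():
    X, y = _toy_table(n=60, shift=2.0, seed=10)
    plan = ps.make_splits(y, folds=5, repeats=2, base_seed=11)
    return ps.run_experiment(X, y, plan, k=10, base_seed=11), plan


class TestExperimentLoop:
    def test_record_count_and_aggregates(self, small_run):
        result, plan = small_run
        assert len(result.accuracies) == len(plan) == 10
        assert all(len(sel) == 10 for sel in result.selected)
        assert result.mean_accuracy == pytest.approx(np.mean(result.accuracies))

    def test_deterministic(self, small_run):
        result, plan = small_run
        X, y = _toy_table(n=60, shift=2.0, seed=10)
        again = ps.run_experiment(X, y, plan, k=10, base_seed=11)
        np.testing.assert_array_equal(result.accuracies, again.accuracies)

    def test_no_test_fold_leakage(self, small_run):
        """Shuffling test labels cannot change training artifacts."""
        _, plan = small_run
        X, y = _toy_table(n=60, shift=2.0, seed=10)
        y_shuffled = y.copy()
        rng = np.random.default_rng(0)
        # scramble labels only on the first split's test fold
        test_idx = plan.splits[0][1]
        y_shuffled[test_idx] = rng.permutation(y_shuffled[test_idx])
        a = ps.run_experiment(X, y, plan, k=10, base_seed=11)
        b = ps.run_experiment(X, y_shuffled, plan, k=10, base_seed=11)
        np.testing.assert_array_equal(a.selected[0], b.selected[0])

    def test_mismatched_plan_rejected(self, small_run):
        _, plan = small_run
        X, y = _toy_table(n=40)
        with pytest.raises(ValueError, match="different number"):
            ps.run_experiment(X, y, plan)


class TestFeatureFrequency:
    def _result(self, selections, n_features=5):
        n = len(selections)
        return EvalResult(
            accuracies=np.full(n, 0.8),
            f1_scores=np.full(n, 0.8),
            selected=[np.asarray(s) for s in selections],
            feature_names=[f"f{i}" for i in range(n_features)],
        )

    def test_always_selected_is_100(self):
        res = self._result([[0, 1]] * 250)
        table = ps.feature_frequency(res)
        assert table.loc[table.feature == "f0", "freq"].item() == 100.0

    def test_176_of_250_is_retained_at_70(self):
        sels = [[0]] * 176 + [[1]] * 74
        table = ps.feature_frequency(self._result(sels), threshold=70.0)
        assert table.freq.tolist() == [pytest.approx(70.4)]
        assert table.feature.tolist() == ["f0"]

    def test_strict_threshold_and_empty(self):
        sels = [[0]] * 175 + [[1]] * 75  # exactly 70% is excluded
        table = ps.feature_frequency(self._result(sels), threshold=70.0)
        assert table.empty

    def test_ranking_descending(self):
        sels = [[0, 1]] * 200 + [[0, 2]] * 50
        table = ps.feature_frequency(self._result(sels), threshold=10.0)
        assert table.freq.is_monotonic_decreasing


class TestCompareRuns:
    def _res(self, accs):
        return EvalResult(
            accuracies=np.asarray(accs), f1_scores=np.asarray(accs), selected=[]
        )

    def test_identical_runs_p_one(self):
        a = self._res(np.full(250, 0.8))
        assert ps.compare_runs(a, a) == 1.0

    def test_planted_effect_tiny_p(self):
        rng = np.random.default_rng(0)
        base = 0.7 + rng.normal(0, 0.02, 250)
        assert ps.compare_runs(self._res(base + 0.1), self._res(base)) < 1e-6

    def test_null_p_values_roughly_uniform(self):
        """Independent null runs give approximately uniform p-values."""
        from scipy.stats import kstest

        rng = np.random.default_rng(1)
        pvals = [
            ps.compare_runs(
                self._res(0.7 + rng.normal(0, 0.02, 60)),
                self._res(0.7 + rng.normal(0, 0.02, 60)),
            )
            for _ in range(200)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_chance_level_helper(self):
        above = self._res(np.clip(0.8 + np.random.default_rng(2).normal(0, 0.02, 100), 0, 1))
        assert ps.chance_level_pvalue(above) < 1e-6
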