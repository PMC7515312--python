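"""Repeated cross-validated RFE + RBF-SVM evaluation harness.

The study design: stratified 5-fold cross-validation repeated 50 times
with different shuffles (250 train/test splits). In each split,
features are z-scored with training-fold statistics, recursive feature
elimination under an extra-trees importance estimator keeps the top 20
features, and an RBF-kernel SVM is scored on the held-out fold
(accuracy and F1 with high workload as the positive class). Feature
importance is summarized as the percentage of splits in which each
feature enters the selected set; features above 70% make the ranking
table. No test-fold information reaches standardization, selection or
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.feature_selection import RFE
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "SplitPlan",
    "EvalResult",
    "WorkloadClassifier",
    "make_splits",
    "select_features_rfe",
    "train_eval_svm",
    "run_experiment",
    "feature_frequency",
    "compare_runs",
    "chance_level_pvalue",
]


@dataclass(frozen=True)
class SplitPlan:
    """Fold assignments for repeated stratified cross-validation."""

    splits: list  # (train_idx, test_idx) pairs, repeats * folds entries
    folds: int
    repeats: int
    repeat_seeds: np.ndarray
    n_samples: int

    def __len__(self) -> int:
        return len(self.splits)


@dataclass
class EvalResult:
    """Per-split scores and selections of one experiment."""

    accuracies: np.ndarray
    f1_scores: np.ndarray
    selected: list = field(default_factory=list)  # per-split index arrays
    feature_names: list = field(default_factory=list)
    plan: SplitPlan | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracies))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1_scores))

    @property
    def std_f1(self) -> float:
        return float(np.std(self.f1_scores))

    def summary(self) -> dict:
        return {
            "accuracy": self.mean_accuracy,
            "accuracy_std": self.std_accuracy,
            "f1": self.mean_f1,
            "f1_std": self.std_f1,
            "n_splits": len(self.accuracies),
        }


class WorkloadClassifier(ClassifierMixin, BaseEstimator):
    """z-score -> RFE(extra trees) -> RBF-SVM, as one sklearn estimator.

    Parameters
    ----------
    n_features : number of features RFE retains (default 20).
    rfe_step : features removed per RFE iteration; a float in (0, 1)
        removes that fraction of the remaining features (default 0.1).
    n_estimators : trees in the importance estimator (default 100).
    C, gamma : SVM hyperparameters (defaults 1.0, 'scale').
    random_state : seed of the importance estimator.

    Attributes
    ----------
    pipeline_ : the fitted sklearn pipeline.
    selected_ : ndarray of selected feature indices (sorted).
    classes_ : class labels.
    """

    def __init__(
        self,
        n_features: int = 20,
        rfe_step: float = 0.1,
        n_estimators: int = 100,
        C: float = 1.0,
        gamma: str | float = "scale",
        random_state: int | None = None,
    ):
        self.n_features = n_features
        self.rfe_step = rfe_step
        self.n_estimators = n_estimators
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training fold contains a single class")
        n_feat = min(self.n_features, X.shape[1])
        self.pipeline_ = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "select",
                    RFE(
                        ExtraTreesClassifier(
                            n_estimators=self.n_estimators,
                            random_state=self.random_state,
                            n_jobs=1,
                        ),
                        n_features_to_select=n_feat,
                        step=self.rfe_step,
                    ),
                ),
                ("svm", SVC(kernel="rbf", C=self.C, gamma=self.gamma)),
            ]
        )
        self.pipeline_.fit(X, y)
        self.selected_ = np.nonzero(self.pipeline_.named_steps["select"].support_)[0]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.pipeline_.predict(X)


def make_splits(
    labels, folds: int = 5, repeats: int = 50, base_seed: int = 0
) -> SplitPlan:
    """Build the repeated stratified k-fold split plan.

    Each repeat shuffles with its own seed derived from ``base_seed``;
    within a repeat the test folds partition the data and preserve the
    class balance to within one sample per fold.
    """
    y = np.asarray(labels)
    counts = np.bincount(pd.factorize(y)[0])
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds"
        )
    repeat_seeds = np.random.SeedSequence(base_seed).generate_state(repeats) % (2**31)
    splits = []
    for rep_seed in repeat_seeds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rep_seed))
        splits.extend(skf.split(np.zeros(len(y)), y))
    return SplitPlan(
        splits=splits,
        folds=folds,
        repeats=repeats,
        repeat_seeds=repeat_seeds,
        n_samples=len(y),
    )


def select_features_rfe(
    train_features,
    train_labels,
    k: int = 20,
    n_estimators: int = 100,
    step: float = 0.1,
    seed: int | None = None,
) -> np.ndarray:
    """Indices of the top-k features under extra-trees RFE."""
    X = np.asarray(train_features, dtype=float)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {X.shape[1]}")
    rfe = RFE(
        ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1),
        n_features_to_select=k,
        step=step,
    )
    rfe.fit(X, np.asarray(train_labels))
    return np.nonzero(rfe.support_)[0]


def train_eval_svm(
    train_features,
    train_labels,
    test_features,
    test_labels,
    C: float = 1.0,
    gamma: str | float = "scale",
    positive_label=1,
) -> tuple[float, float]:
    """Fit the z-score + RBF-SVM stage and score a held-out fold.

    Standardization statistics come from the training fold only. F1 is
    computed for the high-workload (positive) class.
    """
    Xtr = np.asarray(train_features, dtype=float)
    Xte = np.asarray(test_features, dtype=float)
    ytr, yte = np.asarray(train_labels), np.asarray(test_labels)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training fold contains a single class")
    scaler = StandardScaler().fit(Xtr)
    svm = SVC(kernel="rbf", C=C, gamma=gamma).fit(scaler.transform(Xtr), ytr)
    pred = svm.predict(scaler.transform(Xte))
    acc = accuracy_score(yte, pred)
    f1 = f1_score(yte, pred, pos_label=positive_label, zero_division=0)
    return float(acc), float(f1)


def run_experiment(
    feature_table,
    labels,
    plan: SplitPlan,
    k: int = 20,
    n_estimators: int = 100,
    rfe_step: float = 0.1,
    base_seed: int = 0,
) -> EvalResult:
    """Run the full RFE + SVM loop over every split of the plan.

    Per split: z-score with training statistics, RFE to k features,
    RBF-SVM fit, held-out scoring. Deterministic given the inputs and
    ``base_seed`` (each split's importance estimator gets its own
    derived seed).
    """
    if isinstance(feature_table, pd.DataFrame):
        names = list(feature_table.columns)
        X = feature_table.to_numpy(dtype=float)
    else:
        X = np.asarray(feature_table, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if X.shape[0] != plan.n_samples:
        raise ValueError("plan was built for a different number of samples")

    split_seeds = np.random.SeedSequence(base_seed).generate_state(len(plan)) % (2**31)
    accs, f1s, selections = [], [], []
    for (train_idx, test_idx), s in zip(plan.splits, split_seeds):
        scaler = StandardScaler().fit(X[train_idx])
        Xtr = scaler.transform(X[train_idx])
        Xte = scaler.transform(X[test_idx])
        sel = select_features_rfe(
            Xtr, y[train_idx], k=k, n_estimators=n_estimators,
            step=rfe_step, seed=int(s),
        )
        acc, f1 = train_eval_svm(Xtr[:, sel], y[train_idx], Xte[:, sel], y[test_idx])
        accs.append(acc)
        f1s.append(f1)
        selections.append(sel)
    return EvalResult(
        accuracies=np.asarray(accs),
        f1_scores=np.asarray(f1s),
        selected=selections,
        feature_names=names,
        plan=plan,
    )


def feature_frequency(results: EvalResult, threshold: float = 70.0) -> pd.DataFrame:
    """Selection-frequency ranking over the splits.

    Frequency is 100 x (splits selecting the feature) / n_splits;
    features strictly above the threshold are returned ranked
    descending, as a (feature, freq) table.
    """
    n_splits = len(results.selected)
    counts = np.zeros(len(results.feature_names))
    for sel in results.selected:
        counts[sel] += 1
    freq = 100.0 * counts / n_splits
    table = pd.DataFrame({"feature": results.feature_names, "freq": freq})
    table = table[table["freq"] > threshold]
    return table.sort_values("freq", ascending=False, kind="stable").reset_index(
        drop=True
    )


def compare_runs(result_a: EvalResult, result_b: EvalResult) -> float:
    """Paired two-sided Wilcoxon signed-rank p-value over split accuracies.

    Both runs must use the same split plan. Identical scores on every
    split return p = 1 (no evidence of a difference). Splits of a
    repeated CV are not independent, so the p-value is heuristic.
    """
    if result_a.plan is not None and result_b.plan is not None:
        if len(result_a.plan) != len(result_b.plan) or (
            result_a.plan.n_samples != result_b.plan.n_samples
        ):
            raise ValueError("results come from different split plans")
    diffs = result_a.accuracies - result_b.accuracies
    if np.allclose(diffs, 0):
        return 1.0
    return float(stats.wilcoxon(diffs).pvalue)


def chance_level_pvalue(
    result: EvalResult, chance: float = 0.5, alternative: str = "greater"
) -> float:
    """One-sample Wilcoxon p-value of split accuracies against chance."""
    diffs = result.accuracies - chance
    if np.allclose(diffs, 0):
        return 1.0
    return float(stats.wilcoxon(diffs, alternative=alternative).pvalue)
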