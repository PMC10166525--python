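"""Repeated stratified-holdout SVM evaluation of dataset partitions.

Each iteration draws a fresh stratified 65/35 train/test split, reports the
cross-validated training accuracy, held-out test accuracy and F-score (DB
positive), and the harness averages across iterations.  Five other
classifier families can be run on identical split plans for model
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .engineer import DatasetPartition
from .simulate import CLASS_DB

MODEL_FAMILIES = (
    "tree",
    "discriminant",
    "naive-bayes",
    "k-nearest-neighbor",
    "svm",
    "ensemble",
)


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierSpec:
    """Maximum-margin classifier settings (linear kernel, unit C by default)."""

    kernel: str = "linear"
    C: float = 1.0
    gamma: str | float = "scale"

    def build(self):
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)

    def describe(self) -> str:
        return f"svm(kernel={self.kernel}, C={self.C})"


@dataclass
class SplitPlan:
    """One stratified train/test split (row indices into the partition)."""

    iteration: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def stratified_split(labels, train_frac: float = 0.65, seed: int = 0, iteration: int = 0) -> SplitPlan:
    """Stratified holdout split with per-class floor rounding.

    Each class contributes ``floor(train_frac * n_class)`` training rows,
    sampled uniformly without replacement; the remainder goes to test.
    With 14 WT + 13 DB at 0.65 this yields 9 + 8 training animals.
    """
    if not 0.0 < train_frac < 1.0:
        raise ClassifyError("train_frac must be in (0, 1)")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        n_train = floor(train_frac * rows.size)
        if n_train == 0 or n_train == rows.size:
            raise ClassifyError(
                f"class {c!r} would get an empty train or test half (n={rows.size})"
            )
        chosen = rng.choice(rows, size=n_train, replace=False)
        train.append(np.sort(chosen))
        test.append(np.sort(np.setdiff1d(rows, chosen)))
    return SplitPlan(
        iteration=iteration,
        train_idx=np.sort(np.concatenate(train)),
        test_idx=np.sort(np.concatenate(test)),
        seed=seed,
    )


@dataclass
class EvaluationResult:
    """Per-iteration and averaged performance of one dataset partition.

    Accuracies are percentages; the F-score (in [0, 1]) treats the DB class
    as positive.  SDs use the sample convention (ddof=1) and are defined as
    0 for a single iteration.
    """

    dataset: str
    train_accuracies: list[float]
    test_accuracies: list[float]
    f_scores: list[float]
    n_iterations: int
    cv_folds: int
    classifier: str
    seed: int
    train_frac: float = 0.65

    @staticmethod
    def _sd(xs) -> float:
        return float(np.std(xs, ddof=1)) if len(xs) > 1 else 0.0

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean(self.train_accuracies))

    @property
    def sd_train_accuracy(self) -> float:
        return self._sd(self.train_accuracies)

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean(self.test_accuracies))

    @property
    def sd_test_accuracy(self) -> float:
        return self._sd(self.test_accuracies)

    @property
    def mean_f_score(self) -> float:
        return float(np.mean(self.f_scores))

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "classifier": self.classifier,
            "n_iterations": self.n_iterations,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "train_frac": self.train_frac,
            "train_accuracies": self.train_accuracies,
            "test_accuracies": self.test_accuracies,
            "f_scores": self.f_scores,
            "mean_train_accuracy": self.mean_train_accuracy,
            "sd_train_accuracy": self.sd_train_accuracy,
            "mean_test_accuracy": self.mean_test_accuracy,
            "sd_test_accuracy": self.sd_test_accuracy,
            "mean_f_score": self.mean_f_score,
        }


def _iteration_seed(seed: int, iteration: int) -> int:
    # independent, reproducible per-iteration streams, kept below 2**31
    return int(np.random.SeedSequence([int(seed), int(iteration)]).generate_state(1)[0] % (2**31))


def _evaluate_matrix(
    X: np.ndarray,
    y: np.ndarray,
    dataset: str,
    estimator,
    describe: str,
    n_iterations: int,
    cv_folds: int,
    train_frac: float,
    seed: int,
) -> EvaluationResult:
    train_accs, test_accs, fscores = [], [], []
    for it in range(n_iterations):
        it_seed = _iteration_seed(seed, it)
        plan = stratified_split(y, train_frac=train_frac, seed=it_seed, iteration=it)
        X_tr, y_tr = X[plan.train_idx], y[plan.train_idx]
        X_te, y_te = X[plan.test_idx], y[plan.test_idx]
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=it_seed % (2**31))
        cv_scores = cross_val_score(clone(estimator), X_tr, y_tr.astype(str), cv=cv)
        model = clone(estimator).fit(X_tr, y_tr.astype(str))
        pred = model.predict(X_te)
        train_accs.append(float(cv_scores.mean() * 100.0))
        test_accs.append(float((pred == y_te.astype(str)).mean() * 100.0))
        fscores.append(float(f1_score(y_te.astype(str), pred, pos_label=CLASS_DB, zero_division=0)))
    return EvaluationResult(
        dataset=dataset,
        train_accuracies=train_accs,
        test_accuracies=test_accs,
        f_scores=fscores,
        n_iterations=n_iterations,
        cv_folds=cv_folds,
        classifier=describe,
        seed=seed,
        train_frac=train_frac,
    )


def evaluate_partition(
    partition: DatasetPartition,
    n_iterations: int = 5,
    cv_folds: int = 5,
    classifier: ClassifierSpec | None = None,
    seed: int = 0,
    train_frac: float = 0.65,
) -> EvaluationResult:
    """Score one dataset partition with the repeated-holdout SVM harness.

    The partition table must already be imputed and scaled.  Cross-validation
    folds are stratified and shuffled per iteration seed.
    """
    if n_iterations < 1:
        raise ClassifyError("n_iterations must be >= 1")
    if partition.table.missing_mask.any():
        raise ClassifyError("partition table must be imputed before evaluation")
    spec = classifier or ClassifierSpec()
    return _evaluate_matrix(
        partition.table.values,
        partition.table.class_labels,
        partition.name,
        spec.build(),
        spec.describe(),
        n_iterations,
        cv_folds,
        train_frac,
        seed,
    )


def _family_estimator(family: str, seed: int):
    if family == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "discriminant":
        return LinearDiscriminantAnalysis()
    if family == "naive-bayes":
        return GaussianNB()
    if family == "k-nearest-neighbor":
        return KNeighborsClassifier()
    if family == "svm":
        return ClassifierSpec().build()
    if family == "ensemble":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ClassifyError(f"unknown model family {family!r}")


def compare_models(
    partition: DatasetPartition,
    families=MODEL_FAMILIES,
    n_iterations: int = 5,
    cv_folds: int = 5,
    seed: int = 0,
    train_frac: float = 0.65,
) -> dict[str, EvaluationResult]:
    """Run several classifier families on identical split plans.

    Split plans depend only on the seed and labels, so families sharing a
    seed see the same train/test rows and results are directly comparable.
    """
    for fam in families:
        if fam not in MODEL_FAMILIES:
            raise ClassifyError(f"unknown model family {fam!r}")
    out = {}
    for fam in families:
        est = _family_estimator(fam, seed)
        out[fam] = _evaluate_matrix(
            partition.table.values,
            partition.table.class_labels,
            partition.name,
            est,
            fam,
            n_iterations,
            cv_folds,
            train_frac,
            seed,
        )
    return out
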