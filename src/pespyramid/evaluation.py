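"""Cubic-kernel SVM evaluation under stratified 10-fold cross-validation.

The pinned classifier is a support vector machine with a degree-3 polynomial
kernel (1 + x.y / s^2)^3, box constraint C = 1 and per-fold standardization,
evaluated by pooling held-out predictions over stratified folds into a
single confusion matrix.  The kernel scale s is resolved "auto" per training
fold as the median pairwise Euclidean distance among up to 1000 standardized
training points — deterministic and scale-adaptive.

The positive class follows the radiological convention used here: TP counts
correctly classified *normal* images and TN correctly classified pes planus
images.  Accuracy is (TP+TN)/total, precision TP/(TP+FP), recall TP/(TP+FN)
and F1 the harmonic mean of precision and recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

__all__ = [
    "SVMConfig",
    "ConfusionCounts",
    "EvalReport",
    "stratified_folds",
    "resolve_kernel_scale",
    "cv_svm_loss",
    "evaluate",
    "metrics_from_confusion",
    "grid_benchmark",
    "make_svm_evaluator",
    "default_classifier_registry",
]


@dataclass
class SVMConfig:
    """Cubic-SVM hyperparameters: polynomial kernel, order 3, C=1,
    kernel scale "auto", standardize=True."""

    kernel: str = "poly"
    degree: int = 3
    C: float = 1.0
    kernel_scale: float | str = "auto"
    standardize: bool = True
    scale_subsample: int = 1000
    scale_seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"box constraint C must be positive, got {self.C}")
        if isinstance(self.kernel_scale, (int, float)) and self.kernel_scale <= 0:
            raise ValueError(f"kernel_scale must be positive, got {self.kernel_scale}")


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvalReport:
    """Pooled cross-validation confusion counts plus the metric suite."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    fold_assignments: np.ndarray
    seed: int
    positive_class: str = ""
    n_folds: int = 10

    def to_dict(self) -> dict:
        return {
            "counts": {"TP": self.counts.TP, "TN": self.counts.TN,
                       "FP": self.counts.FP, "FN": self.counts.FN},
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "seed": self.seed,
            "positive_class": self.positive_class,
            "n_folds": self.n_folds,
            "fold_assignments": self.fold_assignments.tolist(),
        }


def stratified_folds(labels, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each case a fold index with per-class balance.

    Within each class (in sorted label order) the indices are shuffled with
    the seeded generator and dealt round-robin, so per-class fold sizes
    differ by at most one and the assignment is deterministic given the seed.
    """
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    rng = np.random.default_rng(seed)
    folds = np.empty(labels.shape[0], dtype=np.int64)
    for cls in sorted(np.unique(labels).tolist()):
        members = np.flatnonzero(labels == cls)
        if members.size < n_folds:
            raise ValueError(
                f"class {cls!r} has {members.size} members, fewer than {n_folds} folds"
            )
        shuffled = rng.permutation(members)
        folds[shuffled] = np.arange(shuffled.size) % n_folds
    return folds


def resolve_kernel_scale(X_std: np.ndarray, config: SVMConfig) -> float:
    """Resolve the "auto" kernel scale on standardized training data.

    Median pairwise Euclidean distance among up to ``scale_subsample``
    seeded-subsampled rows; falls back to 1 when the median is zero
    (degenerate duplicated data).
    """
    if not isinstance(config.kernel_scale, str):
        return float(config.kernel_scale)
    if config.kernel_scale != "auto":
        raise ValueError(f"unknown kernel_scale {config.kernel_scale!r}")
    n = X_std.shape[0]
    if n > config.scale_subsample:
        rng = np.random.default_rng(config.scale_seed)
        rows = rng.choice(n, size=config.scale_subsample, replace=False)
        X_std = X_std[rows]
    if X_std.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(X_std)))
    return med if med > 0 else 1.0


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _fit_predict_svm(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, config: SVMConfig
) -> np.ndarray:
    if np.unique(y_train).size < 2:
        raise ValueError("degenerate training fold with a single class")
    if config.standardize:
        X_train, X_test = _standardize(X_train, X_test)
    scale = resolve_kernel_scale(X_train, config)
    clf = SVC(
        kernel="poly",
        degree=config.degree,
        C=config.C,
        gamma=1.0 / scale**2,
        coef0=1.0,
        cache_size=200,
    )
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


def _pooled_predictions(X, y, config: SVMConfig, folds: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    predictions = np.empty(y.shape[0], dtype=object)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        predictions[test] = _fit_predict_svm(X[train], y[train], X[test], config)
    return predictions


def cv_svm_loss(X, y, config: SVMConfig | None = None, folds: np.ndarray | None = None) -> float:
    """Pooled misclassification fraction of the cubic SVM over the folds.

    Standardization statistics and the auto kernel scale are resolved on each
    training fold only; every case is predicted exactly once while held out.
    """
    config = config or SVMConfig()
    y = np.asarray(y)
    if folds is None:
        folds = stratified_folds(y, n_folds=10, seed=0)
    predictions = _pooled_predictions(X, y, config, folds)
    return float(np.mean(predictions != y))


def metrics_from_confusion(counts: ConfusionCounts) -> tuple:
    """(accuracy, precision, recall, f1) from pooled confusion counts.

    Zero-denominator precision/recall are defined as 0 with a warning;
    all-zero counts are an error.
    """
    total = counts.total
    if total == 0:
        raise ValueError("confusion counts are all zero")
    accuracy = (counts.TP + counts.TN) / total
    if counts.TP + counts.FP == 0:
        warnings.warn("no positive predictions; precision defined as 0")
        precision = 0.0
    else:
        precision = counts.TP / (counts.TP + counts.FP)
    if counts.TP + counts.FN == 0:
        warnings.warn("no positive cases; recall defined as 0")
        recall = 0.0
    else:
        recall = counts.TP / (counts.TP + counts.FN)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1


def evaluate(
    X,
    y,
    config: SVMConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
    positive_class: str | None = None,
) -> EvalReport:
    """Run stratified CV and report the pooled confusion matrix and metrics.

    ``positive_class`` defaults to ``"normal"`` when that label is present
    (so TP counts correctly classified normal images), else the
    lexicographically first label.
    """
    config = config or SVMConfig()
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if positive_class is None:
        positive_class = "normal" if "normal" in classes else classes[0]
    elif positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not among labels {classes}")
    folds = stratified_folds(y, n_folds=n_folds, seed=seed)
    predictions = _pooled_predictions(X, y, config, folds)
    is_pos = y == positive_class
    pred_pos = predictions == positive_class
    counts = ConfusionCounts(
        TP=int(np.sum(is_pos & pred_pos)),
        TN=int(np.sum(~is_pos & ~pred_pos)),
        FP=int(np.sum(~is_pos & pred_pos)),
        FN=int(np.sum(is_pos & ~pred_pos)),
    )
    accuracy, precision, recall, f1 = metrics_from_confusion(counts)
    return EvalReport(
        counts=counts,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        fold_assignments=folds,
        seed=seed,
        positive_class=positive_class,
        n_folds=n_folds,
    )


def make_svm_evaluator(
    config: SVMConfig | None = None, n_folds: int = 10, seed: int = 0
) -> Callable[[np.ndarray, np.ndarray], float]:
    """Bind cv_svm_loss to a config/fold seed for use as a selection loss."""
    config = config or SVMConfig()

    def loss(X: np.ndarray, y: np.ndarray) -> float:
        folds = stratified_folds(y, n_folds=n_folds, seed=seed)
        return cv_svm_loss(X, y, config, folds)

    return loss


def _make_sklearn_cv_accuracy(factory) -> Callable:
    def run(X, y, folds) -> float:
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        predictions = np.empty(y.shape[0], dtype=object)
        for f in np.unique(folds):
            test = folds == f
            train = ~test
            X_tr, X_te = _standardize(X[train], X[test])
            clf = factory()
            clf.fit(X_tr, y[train])
            predictions[test] = clf.predict(X_te)
        return float(np.mean(predictions == y))

    return run


def default_classifier_registry(config: SVMConfig | None = None) -> dict:
    """Pluggable classifier registry for the grid runner.

    Each entry maps (X, y, folds) to pooled CV accuracy.  Only the cubic SVM
    is a pinned contract; the others are off-the-shelf conveniences.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.neighbors import KNeighborsClassifier

    svm_config = config or SVMConfig()

    def cubic_svm(X, y, folds) -> float:
        return 1.0 - cv_svm_loss(X, y, svm_config, folds)

    return {
        "cubic_svm": cubic_svm,
        "linear_discriminant": _make_sklearn_cv_accuracy(
            lambda: LinearDiscriminantAnalysis()
        ),
        "fine_knn": _make_sklearn_cv_accuracy(
            lambda: KNeighborsClassifier(n_neighbors=1)
        ),
    }


def grid_benchmark(
    feature_sets: dict,
    classifiers: dict,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy table: one row per named feature set, one column per classifier.

    ``feature_sets`` maps name -> (X, y); ``classifiers`` maps name ->
    callable(X, y, folds) -> accuracy.  A failing cell is recorded as NaN
    with a warning and the run continues.
    """
    if not feature_sets or not classifiers:
        raise ValueError("feature_sets and classifiers must be non-empty")
    table = pd.DataFrame(
        index=list(feature_sets), columns=list(classifiers), dtype=float
    )
    for fs_name, (X, y) in feature_sets.items():
        folds = stratified_folds(np.asarray(y), n_folds=n_folds, seed=seed)
        for clf_name, runner in classifiers.items():
            try:
                table.loc[fs_name, clf_name] = float(runner(X, y, folds))
            except Exception as exc:
                warnings.warn(f"cell ({fs_name}, {clf_name}) failed: {exc}")
                table.loc[fs_name, clf_name] = np.nan
    return table
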