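"""Classifiers, stratified 10-fold cross-validation and the metric suite.

Five classifiers are supported: cubic- and quadratic-kernel SVMs, a
"medium" Gaussian-kernel SVM (kernel scale sqrt(P), the preset the name
comes from), 3-nearest-neighbour with Euclidean distance, and a small
feed-forward network (two hidden layers of 10 rectified-linear units).
All SVMs use box constraint C = 1.

Each fold standardises features on its training part, optionally runs a
feature-selection hook fitted on the training part only, then trains and
predicts; test predictions are pooled into a single confusion matrix from
which accuracy, sensitivity, specificity, precision, F1 and the Matthews
correlation coefficient are computed, alongside a pooled ROC curve/AUC.
The positive class is ADHD (label 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_KINDS", "ClassifierSpec", "ConfusionMatrix",
    "EvaluationReport", "stratified_kfold", "fit_predict",
    "crossval_evaluate", "compute_metrics", "roc_auc",
]

CLASSIFIER_KINDS = (
    "svm_cubic", "svm_quadratic", "svm_rbf_medium", "knn", "ann",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier kind plus its (fixed) hyperparameters."""

    kind: str
    C: float = 1.0                      # SVM box constraint
    knn_k: int = 3
    hidden: tuple[int, int] = (10, 10)  # ANN layout
    max_iter: int = 1000                # ANN iteration cap
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; "
                             f"choose from {CLASSIFIER_KINDS}")

    def build(self, n_features: int):
        if self.kind == "svm_cubic":
            return SVC(kernel="poly", degree=3, coef0=1, gamma="scale",
                       C=self.C)
        if self.kind == "svm_quadratic":
            return SVC(kernel="poly", degree=2, coef0=1, gamma="scale",
                       C=self.C)
        if self.kind == "svm_rbf_medium":
            # kernel scale sqrt(P)  <=>  gamma = 1/P
            return SVC(kernel="rbf", gamma=1.0 / n_features, C=self.C)
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k,
                                        metric="euclidean")
        return MLPClassifier(hidden_layer_sizes=self.hidden,
                             activation="relu", solver="adam",
                             max_iter=self.max_iter,
                             random_state=self.seed)


@dataclass
class ConfusionMatrix:
    """Binary confusion counts; the positive class is ADHD."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision, F1 and MCC.

    Zero denominators yield 0 for the affected metric (with a warning)
    rather than NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.warning("metric %s has zero denominator; reporting 0", name)
            return 0.0
        return num / den

    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    acc = (tp + tn) / cm.total
    sens = safe(tp, tp + fn, "sensitivity")
    spec = safe(tn, tn + fp, "specificity")
    prec = safe(tp, tp + fp, "precision")
    f1 = safe(2 * prec * sens, prec + sens, "F1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = safe(tp * tn - fp * fn, mcc_den, "MCC")
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "precision": prec, "f1": f1, "mcc": mcc}


def roc_auc(scores: np.ndarray, y: np.ndarray):
    """ROC points (threshold sweep) and trapezoidal AUC.

    The AUC equals the Mann-Whitney concordance probability of the scores.
    """
    from sklearn.metrics import roc_curve, auc as sk_auc

    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(y, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr]), float(sk_auc(fpr, tpr))


def stratified_kfold(y: np.ndarray, k: int = 10, seed: int = 0,
                     groups: np.ndarray | None = None) -> np.ndarray:
    """Fold index (0..k-1) per sample, stratified and seed-deterministic.

    With ``groups`` (e.g. subject identifiers) all segments of a group
    land in the same test fold — the subject-level protocol that avoids
    within-subject leakage; the default is segment-level splitting.
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot make {k} "
            "stratified folds"
        )
    if groups is not None:
        from sklearn.model_selection import StratifiedGroupKFold

        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        split = splitter.split(np.zeros((len(y), 1)), y, np.asarray(groups))
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = skf.split(np.zeros((len(y), 1)), y)
    folds = np.empty(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(split):
        folds[test_idx] = i
    return folds


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Train one classifier and return (hard labels, real-valued scores).

    Scores are signed margins for SVMs, positive-class probabilities for
    kNN/ANN; either is usable for ROC analysis. Inputs are assumed already
    standardised.
    """
    if np.unique(y_train).size < 2:
        raise ValueError("training fold contains a single class")
    clf = spec.build(X_train.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ANN convergence cap is intentional
        clf.fit(X_train, y_train)
    labels = clf.predict(X_test)
    if hasattr(clf, "decision_function"):
        scores = clf.decision_function(X_test)
    else:
        scores = clf.predict_proba(X_test)[:, 1]
    return labels, scores


@dataclass
class EvaluationReport:
    """Cross-validation outcome: pooled counts, metrics, ROC and AUC."""

    fold_matrices: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    metrics: dict[str, float]
    roc_points: np.ndarray
    auc: float
    seed: int
    spec: ClassifierSpec
    n_selected: int | None = None


SelectionHook = Callable[[np.ndarray, np.ndarray], np.ndarray]


def crossval_evaluate(
    data: FeatureMatrix | tuple[np.ndarray, np.ndarray],
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    selection_hook: SelectionHook | None = None,
    selected_columns: Sequence[int] | None = None,
    groups: np.ndarray | None = None,
) -> EvaluationReport:
    """Stratified k-fold evaluation with fold-honest scaling and selection.

    Standardisation is fitted on each training fold; ``selection_hook``
    (X_train, y_train) -> column indices is likewise fitted per training
    fold. ``selected_columns`` instead applies one fixed, precomputed
    selection to every fold — the protocol-mimicking variant where feature
    ranks come from all data. Predictions are pooled into one confusion
    matrix; metrics are computed from the pooled counts.
    """
    if isinstance(data, FeatureMatrix):
        X, y = data.X, data.y
    else:
        X, y = data
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if selection_hook is not None and selected_columns is not None:
        raise ValueError("pass either selection_hook or selected_columns")
    if selected_columns is not None:
        X = X[:, np.asarray(selected_columns)]

    folds = stratified_kfold(y, k=k, seed=seed, groups=groups)
    fold_cms: list[ConfusionMatrix] = []
    pooled_scores = np.empty(len(y))
    pooled_pred = np.empty(len(y), dtype=y.dtype)
    n_selected = None
    for i in range(k):
        test = folds == i
        train = ~test
        scaler = StandardScaler().fit(X[train])
        X_tr, X_te = scaler.transform(X[train]), scaler.transform(X[test])
        if selection_hook is not None:
            cols = np.asarray(selection_hook(X_tr, y[train]))
            n_selected = len(cols)
            X_tr, X_te = X_tr[:, cols], X_te[:, cols]
        labels, scores = fit_predict(spec, X_tr, y[train], X_te)
        pooled_pred[test] = labels
        pooled_scores[test] = scores
        fold_cms.append(ConfusionMatrix.from_predictions(y[test], labels))

    pooled = sum(fold_cms, ConfusionMatrix())
    roc_points, auc_value = roc_auc(pooled_scores, y)
    return EvaluationReport(
        fold_matrices=fold_cms,
        pooled=pooled,
        metrics=compute_metrics(pooled),
        roc_points=roc_points,
        auc=auc_value,
        seed=seed,
        spec=spec,
        n_selected=n_selected if selection_hook is not None
        else (len(selected_columns) if selected_columns is not None else None),
    )
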