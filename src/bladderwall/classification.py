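"""Classification of bladder-wall feature vectors.

Severe (pathological, +1) versus non-severe (-1) discrimination with
SVM (RBF / linear / polynomial kernels) and Random Forest, evaluated by
stratified 5-fold cross-validation and on a held-out split.  The RBF
kernel uses the gamma-as-width convention

    K(xi, xj) = exp(-||xi - xj||^2 / (2 gamma^2)),

mapped onto scikit-learn's ``exp(-g ||.||^2)`` via ``g = 1/(2 gamma^2)``.
Feature ranges are min-max normalized to [-1, 1] with the scaling always
learned on training data only.  The GWO coupling searches (C, gamma) in
log10 space, maximizing mean CV accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .gwo import GWOConfig, GWOResult, optimize

__all__ = [
    "Dataset",
    "NormalizationModel",
    "ClassifierConfig",
    "ClassificationMetrics",
    "normalize_fit",
    "normalize_apply",
    "normalize_fit_apply",
    "rbf_kernel",
    "train_classifier",
    "predict",
    "confusion_metrics",
    "cross_validate",
    "cv_accuracy_objective",
    "GWOSVMResult",
    "gwo_svm",
    "train_test_protocol",
]


@dataclass(frozen=True)
class Dataset:
    """Feature matrix with labels in {-1, +1} (+1 = pathological)."""

    X: np.ndarray
    y: np.ndarray
    ids: tuple = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        y = np.asarray(self.y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        uniq = set(np.unique(y).tolist())
        if not uniq <= {-1, 1}:
            raise ValueError(f"labels must be in {{-1, +1}}, got {sorted(uniq)}")
        if len(uniq) < 2:
            raise ValueError("both classes must be present")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y.astype(int))

    def subset_features(self, indices) -> "Dataset":
        return Dataset(self.X[:, list(indices)], self.y, self.ids)


@dataclass(frozen=True)
class NormalizationModel:
    mins: np.ndarray
    maxs: np.ndarray


def normalize_fit(train_X: np.ndarray) -> NormalizationModel:
    X = np.asarray(train_X, dtype=np.float64)
    return NormalizationModel(mins=X.min(axis=0), maxs=X.max(axis=0))


def normalize_apply(model: NormalizationModel, X: np.ndarray) -> np.ndarray:
    """x' = 2 (x - min) / (max - min) - 1; constant train features map to 0.

    Test values outside the train range are not clipped.
    """
    X = np.asarray(X, dtype=np.float64)
    span = model.maxs - model.mins
    const = span == 0
    safe = np.where(const, 1.0, span)
    out = 2.0 * (X - model.mins) / safe - 1.0
    out[:, const] = 0.0
    return out


def normalize_fit_apply(train_X, test_X):
    model = normalize_fit(train_X)
    return model, normalize_apply(model, train_X), normalize_apply(model, test_X)


def rbf_kernel(xi, xj, gamma: float) -> float:
    """Gaussian kernel exp(-||xi - xj||^2 / (2 gamma^2))."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    if xi.shape != xj.shape:
        raise ValueError("vectors must have equal dimension")
    return float(np.exp(-np.sum((xi - xj) ** 2) / (2.0 * gamma**2)))


@dataclass(frozen=True)
class ClassifierConfig:
    kind: str = "svm"              # "svm" or "rf"
    kernel: str = "rbf"            # rbf | linear | poly
    C: float = 1.0
    gamma: float = 1.0             # RBF width (the 2*gamma^2 convention)
    degree: int = 3
    n_trees: int = 100
    seed: int = 0

    def make(self):
        if self.kind == "svm":
            if self.kernel == "rbf":
                return SVC(kernel="rbf", C=self.C, gamma=1.0 / (2.0 * self.gamma**2))
            if self.kernel == "linear":
                return SVC(kernel="linear", C=self.C)
            if self.kernel == "poly":
                return SVC(kernel="poly", C=self.C, degree=self.degree, gamma="scale")
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kind == "rf":
            return RandomForestClassifier(n_estimators=self.n_trees, random_state=self.seed)
        raise ValueError(f"unknown classifier kind {self.kind!r}")


def train_classifier(train: Dataset, config: ClassifierConfig):
    """Fit the configured classifier on (already normalized) features."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set contains a single class")
    model = config.make()
    model.fit(train.X, train.y)
    return model


def predict(model, X) -> np.ndarray:
    return model.predict(np.asarray(X, dtype=np.float64))


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def confusion_metrics(y_true, y_pred) -> ClassificationMetrics:
    """Accuracy, sensitivity (recall of +1), specificity, precision.

    Metrics with an empty denominator are reported as NaN, not 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == -1) & (y_pred == -1)).sum())
    fp = int(((y_true == -1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == -1)).sum())
    n = tp + tn + fp + fn

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    return ClassificationMetrics(
        accuracy=ratio(tp + tn, n),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
    )


def cross_validate(data: Dataset, config: ClassifierConfig, k: int = 5,
                   seed: int = 0) -> ClassificationMetrics:
    """Mean metrics over stratified k-fold CV.

    Normalization is re-fit inside each training fold; NaN fold metrics
    (empty denominators) are skipped in the average.
    """
    counts = np.bincount((data.y == 1).astype(int))
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} members for {k}-fold stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for train_idx, test_idx in skf.split(data.X, data.y):
        _, Xtr, Xte = normalize_fit_apply(data.X[train_idx], data.X[test_idx])
        model = train_classifier(Dataset(Xtr, data.y[train_idx]), config)
        y_pred = predict(model, Xte)
        per_fold.append(confusion_metrics(data.y[test_idx], y_pred))
    return ClassificationMetrics(*[
        float(np.nanmean([getattr(m, f) for m in per_fold]))
        for f in ("accuracy", "sensitivity", "specificity", "precision")
    ])


def cv_accuracy_objective(data: Dataset, config: ClassifierConfig, k: int = 5,
                          seed: int = 0):
    """Subset -> mean CV accuracy, for the feature-selection search.

    The fold seed is fixed so every subset is scored on identical folds.
    """

    def objective(subset) -> float:
        idx = sorted(subset)
        if not idx:
            return 0.0
        return cross_validate(data.subset_features(idx), config, k=k, seed=seed).accuracy

    return objective


@dataclass
class GWOSVMResult:
    C: float
    gamma: float
    cv_metrics: ClassificationMetrics
    trace: np.ndarray = field(repr=False, default=None)
    gwo: GWOResult = field(repr=False, default=None)


def gwo_svm(data: Dataset, gwo_config: GWOConfig | None = None, k: int = 5,
            cv_seed: int = 0, log_scale: bool = True) -> GWOSVMResult:
    """Tune (C, gamma) of the RBF SVM by maximizing mean k-fold CV accuracy.

    The default search box is log10 C in [-2, 2], log10 gamma in [-4, 1].
    """
    cfg = gwo_config or GWOConfig()

    def fitness(pos: np.ndarray) -> float:
        c, g = (10.0 ** pos[0], 10.0 ** pos[1]) if log_scale else (pos[0], pos[1])
        clf = ClassifierConfig(kind="svm", kernel="rbf", C=c, gamma=g)
        return cross_validate(data, clf, k=k, seed=cv_seed).accuracy

    result = optimize(fitness, cfg)
    if log_scale:
        best_c, best_g = 10.0 ** result.best_position[0], 10.0 ** result.best_position[1]
    else:
        best_c, best_g = float(result.best_position[0]), float(result.best_position[1])
    metrics = cross_validate(
        data, ClassifierConfig(kind="svm", kernel="rbf", C=best_c, gamma=best_g),
        k=k, seed=cv_seed,
    )
    return GWOSVMResult(C=best_c, gamma=best_g, cv_metrics=metrics,
                        trace=result.trace, gwo=result)


def train_test_protocol(data: Dataset, config: ClassifierConfig, test_frac: float = 0.2,
                        seed: int = 0) -> tuple[ClassificationMetrics, ClassificationMetrics]:
    """Stratified train/test split evaluation.

    Returns (held-out metrics, 5-fold CV metrics on the training portion);
    normalization is learned on the training data only.
    """
    idx = np.arange(len(data.y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, random_state=seed, stratify=data.y
    )
    cv_metrics = cross_validate(Dataset(data.X[train_idx], data.y[train_idx]),
                                config, k=5, seed=seed)
    _, Xtr, Xte = normalize_fit_apply(data.X[train_idx], data.X[test_idx])
    model = train_classifier(Dataset(Xtr, data.y[train_idx]), config)
    held_out = confusion_metrics(data.y[test_idx], predict(model, Xte))
    return held_out, cv_metrics
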