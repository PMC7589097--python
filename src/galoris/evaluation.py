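"""Downstream classifier evaluation and filter/projection baselines.

The structured dataset produced by the selector is scored with four
classifiers — SVM with RBF and linear kernels, k-nearest neighbours, and
a linear-regression classifier thresholded at 0.5 — under stratified
10-fold cross-validation (each fold is a 90/10 train/test split).
Hyperparameters are chosen by grid search inside the training folds only,
over C in [1e-4, 1e3], gamma in [1e-5, 10] and k in [1, 10].

Metrics follow the workload-confusion convention: sensitivity is the
percentage of low-workload samples predicted correctly,
CLCW / (CLCW + IHCW) * 100, and accuracy is the percentage of all samples
predicted correctly.

Two baseline selectors are provided for matched comparisons: mutual-
information ranking (histogram plug-in estimator with equal-frequency
bins) and projection onto principal components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .ga import StructuredDataset

__all__ = [
    "ConfusionCounts",
    "sensitivity",
    "accuracy",
    "confusion_from_predictions",
    "make_classifier",
    "kfold_evaluate",
    "evaluate_all_classifiers",
    "baseline_select",
    "mutual_information",
    "CLASSIFIER_NAMES",
]

#: Hyperparameter search ranges.
C_RANGE = (1e-4, 1e3)
GAMMA_RANGE = (1e-5, 10.0)
K_RANGE = (1, 10)

CLASSIFIER_NAMES = ("svm_rbf", "svm_linear", "knn", "linear_regression")


@dataclass(frozen=True)
class ConfusionCounts:
    """Workload confusion tallies: correct/incorrect low (CLCW/ILCW) and
    high (CHCW/IHCW) predictions."""

    clcw: int
    chcw: int
    ilcw: int
    ihcw: int

    def __post_init__(self) -> None:
        if min(self.clcw, self.chcw, self.ilcw, self.ihcw) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.clcw + self.chcw + self.ilcw + self.ihcw


def sensitivity(counts: ConfusionCounts) -> float:
    """CLCW / (CLCW + IHCW) * 100; NaN when no low-workload sample exists."""
    denom = counts.clcw + counts.ihcw
    if denom == 0:
        return float("nan")
    return 100.0 * counts.clcw / denom


def accuracy(counts: ConfusionCounts) -> float:
    """(CLCW + CHCW) / total * 100."""
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    return 100.0 * (counts.clcw + counts.chcw) / counts.total


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Tally predictions against truth (0 = low workload, 1 = high)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    return ConfusionCounts(
        clcw=int(np.sum((y_true == 0) & (y_pred == 0))),
        chcw=int(np.sum((y_true == 1) & (y_pred == 1))),
        ilcw=int(np.sum((y_true == 1) & (y_pred == 0))),
        ihcw=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


class ThresholdedLinearRegression(BaseEstimator, RegressorMixin):
    """Ordinary least squares on 0/1 labels, classified at fitted value 0.5."""

    def fit(self, X, y):
        self.ols_ = LinearRegression().fit(X, y)
        return self

    def predict(self, X):
        return (self.ols_.predict(X) >= 0.5).astype(int)


def _log_grid(low: float, high: float, n_points: int) -> np.ndarray:
    return np.logspace(np.log10(low), np.log10(high), n_points)


def make_classifier(name: str, grid_points: int = 8):
    """A (estimator, parameter-grid) pair for one of the four classifiers.

    ``grid_points`` controls the log-grid resolution over C and gamma
    inside their search ranges; k is searched exhaustively over 1..10.
    """
    if name == "svm_rbf":
        return SVC(kernel="rbf"), {
            "C": _log_grid(*C_RANGE, grid_points),
            "gamma": _log_grid(*GAMMA_RANGE, grid_points),
        }
    if name == "svm_linear":
        return SVC(kernel="linear"), {"C": _log_grid(*C_RANGE, grid_points)}
    if name == "knn":
        return KNeighborsClassifier(), {
            "n_neighbors": list(range(K_RANGE[0], K_RANGE[1] + 1))
        }
    if name == "linear_regression":
        return ThresholdedLinearRegression(), {}
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def kfold_evaluate(
    dataset: StructuredDataset | tuple[pd.DataFrame, np.ndarray],
    classifier: str = "svm_rbf",
    k: int = 10,
    seed: int = 0,
    grid_points: int = 8,
    tune: bool = True,
    inner_folds: int = 3,
) -> dict[str, float]:
    """Stratified k-fold evaluation of one classifier.

    Every sample lands in exactly one test fold; each fold trains on the
    remaining (k-1)/k of the samples (90% for k=10) and tests on the held
    fold.  When ``tune`` is on, hyperparameters are grid-searched with an
    inner CV restricted to the training fold.  Returns mean train/test
    accuracy and sensitivity (percent) with the test-fold SD.
    """
    if isinstance(dataset, StructuredDataset):
        X, y = dataset.features.to_numpy(dtype=float), dataset.labels
    else:
        X, y = np.asarray(dataset[0], dtype=float), np.asarray(dataset[1], dtype=int)
    estimator, grid = make_classifier(classifier, grid_points)

    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    train_accs, test_accs, sens = [], [], []
    for train_idx, test_idx in folds.split(X, y):
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("a training fold lost one of the classes")
        if tune and grid:
            search = GridSearchCV(clone(estimator), grid, cv=inner_folds, n_jobs=1)
            search.fit(X[train_idx], y[train_idx])
            fitted = search.best_estimator_
        else:
            fitted = clone(estimator).fit(X[train_idx], y[train_idx])
        train_counts = confusion_from_predictions(y[train_idx], fitted.predict(X[train_idx]))
        test_counts = confusion_from_predictions(y[test_idx], fitted.predict(X[test_idx]))
        train_accs.append(accuracy(train_counts))
        test_accs.append(accuracy(test_counts))
        sens.append(sensitivity(test_counts))
    return {
        "classifier": classifier,
        "train_accuracy": float(np.mean(train_accs)),
        "test_accuracy": float(np.mean(test_accs)),
        "sensitivity": float(np.nanmean(sens)),
        "test_accuracy_sd": float(np.std(test_accs, ddof=1)),
    }


def evaluate_all_classifiers(
    dataset: StructuredDataset | tuple[pd.DataFrame, np.ndarray],
    k: int = 10,
    seed: int = 0,
    grid_points: int = 8,
    tune: bool = True,
) -> pd.DataFrame:
    """One report row per classifier (train/test accuracy, sensitivity, SD)."""
    rows = [
        kfold_evaluate(dataset, name, k=k, seed=seed, grid_points=grid_points, tune=tune)
        for name in CLASSIFIER_NAMES
    ]
    return pd.DataFrame(rows).set_index("classifier")


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 8) -> float:
    """Plug-in mutual information (nats) between a real feature and a
    discrete label, with equal-frequency binning of the feature."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    uniq = np.unique(x)
    if uniq.size <= 1:
        return 0.0
    if uniq.size <= n_bins:  # already discrete: one bin per value
        xb = np.searchsorted(uniq, x)
    else:
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
        xb = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)
    joint = pd.crosstab(xb, y).to_numpy(dtype=float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px @ py))
    return float(np.nansum(terms))


def baseline_select(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    method: str,
    n_features: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Matched-size baseline reducers for comparison with the GA selector.

    ``method='mutual_information'`` keeps the ``n_features`` columns with
    the highest plug-in MI against the label; ``method='pca'`` projects
    onto the leading ``n_features`` principal components (columns named
    ``PC1..``).
    """
    matrix = pd.DataFrame(matrix)
    if not 0 < n_features <= matrix.shape[1]:
        raise ValueError(
            f"n_features must lie in [1, {matrix.shape[1]}], got {n_features}"
        )
    y = np.asarray(labels)
    if method == "mutual_information":
        scores = {c: mutual_information(matrix[c].to_numpy(), y) for c in matrix.columns}
        top = sorted(matrix.columns, key=lambda c: (-scores[c], str(c)))[:n_features]
        return matrix[[c for c in matrix.columns if c in set(top)]].copy()
    if method == "pca":
        proj = PCA(n_components=n_features, random_state=seed).fit_transform(
            matrix.to_numpy(dtype=float)
        )
        return pd.DataFrame(proj, columns=[f"PC{i + 1}" for i in range(n_features)])
    raise ValueError("method must be 'mutual_information' or 'pca'")
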