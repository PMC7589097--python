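"""Interval-threshold labeling of unlabeled feature data.

Real recordings carry no workload labels.  The labeling rule averages each
sample across all feature columns, splits the range of that average vector
into ``n_states`` equal intervals, and assigns each sample the index of its
interval.  For two states the boundary is the midpoint of the range:
samples with a below-boundary average are labeled 0 (low workload), the
rest 1 (high workload) — high average band power marks the high-demand
peaks of the session.  Ties at the boundary go to the high state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import BandFeatureMatrix

__all__ = ["LabelVector", "sample_average_vector", "compute_threshold", "label_samples"]


@dataclass
class LabelVector:
    """Binary labels plus the threshold interval that produced them."""

    labels: np.ndarray
    boundary: float
    interval_size: float
    min_value: float
    max_value: float
    n_states: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if not self.min_value <= self.boundary <= self.max_value:
            raise ValueError("boundary must lie within [min_value, max_value]")

    @property
    def counts(self) -> tuple[int, int]:
        """(n_low, n_high) label counts."""
        n_high = int(self.labels.sum())
        return len(self.labels) - n_high, n_high

    @property
    def intervals(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """The low-state [min, boundary) and high-state [boundary, max] intervals."""
        return (self.min_value, self.boundary), (self.boundary, self.max_value)


def sample_average_vector(matrix: BandFeatureMatrix) -> np.ndarray:
    """Per-sample arithmetic mean across all feature columns."""
    if len(matrix.column_names) == 0:
        raise ValueError("feature matrix has no columns")
    return matrix.values.to_numpy(dtype=float).mean(axis=1)


def compute_threshold(avg: np.ndarray, n_states: int = 2) -> dict[str, float]:
    """Equal division of the average vector's range into ``n_states``.

    interval_size = (max - min) / n_states; for two states the decision
    boundary is min + interval_size, the midpoint of the range.
    """
    avg = np.asarray(avg, dtype=float)
    if n_states < 2:
        raise ValueError("need at least 2 cognitive states")
    vmin, vmax = float(avg.min()), float(avg.max())
    if vmax <= vmin:
        raise ValueError(
            "sample averages are constant (max == min); interval labeling "
            "cannot separate states"
        )
    interval = (vmax - vmin) / n_states
    return {
        "min_value": vmin,
        "max_value": vmax,
        "interval_size": interval,
        "boundary": vmin + interval,
        "n_states": n_states,
    }


def label_samples(avg: np.ndarray, boundary: float) -> np.ndarray:
    """0 below the boundary, 1 at or above it."""
    avg = np.asarray(avg, dtype=float)
    return (avg >= boundary).astype(int)


def label_matrix(matrix: BandFeatureMatrix, n_states: int = 2) -> LabelVector:
    """Full labeling pass: average, threshold, assign."""
    avg = sample_average_vector(matrix)
    thr = compute_threshold(avg, n_states=n_states)
    labels = label_samples(avg, thr["boundary"])
    return LabelVector(labels=labels, **thr)
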