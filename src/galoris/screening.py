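"""Statistical screening and study-level summary statistics.

The search space handed to the genetic algorithm is defined by a per-column
two-task t-test: a (band, channel) power feature is retained only when its
low- vs high-workload difference is significant at level alpha.  Retained
columns are ordered band-major (canonical band order, surviving bands keep
their relative order) then by the fixed channel order.

Also provides the study's validation statistics: Pearson correlation
matrices between workload measures, the driving error rate ae/at, and
per-task mean +/- SD summaries of subjective scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bands import sort_columns
from .features import BandFeatureMatrix

__all__ = [
    "SearchSpace",
    "SubjectScores",
    "two_task_t_test",
    "build_search_space",
    "pearson_matrix",
    "error_rate",
    "task_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class SearchSpace:
    """Ordered feature columns surviving the p <= alpha screen."""

    columns: list[str]
    alpha: float = 0.05
    p_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("search-space columns must be unique")

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class SubjectScores:
    """One subject's per-task workload scores and driving-activity counts.

    ``isa`` and ``nasa_tlx`` are the weighted 1-100 questionnaire scores;
    ``activities_erroneous``/``activities_total`` count lane-change
    activities performed incorrectly out of those presented.
    """

    subject: str
    task: str
    isa: float | None = None
    nasa_tlx: float | None = None
    activities_erroneous: int | None = None
    activities_total: int | None = None

    def __post_init__(self) -> None:
        if self.activities_erroneous is not None and self.activities_total is not None:
            if not 0 <= self.activities_erroneous <= self.activities_total:
                raise ValueError(
                    f"need 0 <= erroneous <= total, got "
                    f"{self.activities_erroneous}/{self.activities_total}"
                )


def two_task_t_test(
    values_task1: np.ndarray,
    values_task2: np.ndarray,
    paired: bool = False,
    equal_var: bool = True,
) -> dict[str, float]:
    """Two-sided t-test between the two task conditions.

    Returns the statistic, p-value and per-task means/SDs.  The unpaired
    two-sample test is the default; ``paired=True`` runs the paired test
    (equal lengths required).  Identical paired vectors — zero-variance
    differences — are reported as t=0, p=1 rather than NaN.
    """
    x1 = np.asarray(values_task1, dtype=float)
    x2 = np.asarray(values_task2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need at least 2 observations per task")
    if paired:
        if x1.size != x2.size:
            raise ValueError("paired test requires equal-length vectors")
        diffs = x1 - x2
        if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0.0):
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat, p_value = stats.ttest_rel(x1, x2)
    else:
        t_stat, p_value = stats.ttest_ind(x1, x2, equal_var=equal_var)
    return {
        "t": float(t_stat),
        "p": float(p_value),
        "mean_task1": float(x1.mean()),
        "mean_task2": float(x2.mean()),
        "sd_task1": float(x1.std(ddof=1)),
        "sd_task2": float(x2.std(ddof=1)),
    }


def build_search_space(
    matrix: BandFeatureMatrix,
    task_labels: np.ndarray,
    alpha: float = 0.05,
    paired: bool = False,
    bonferroni: bool = False,
) -> SearchSpace:
    """Screen every column with the two-task t-test at level alpha.

    Exactly the columns with p <= alpha are retained, in band-major /
    canonical channel order.  Columns with zero variance in both tasks are
    excluded with a logged warning.  ``bonferroni`` divides alpha by the
    number of tested columns (off by default: the screen is a plain
    per-column criterion).
    """
    labels = np.asarray(task_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"need exactly two task groups, got {groups.size}")
    g1, g2 = (labels == groups[0]), (labels == groups[1])

    level = alpha / len(matrix.column_names) if bonferroni else alpha
    p_values: dict[str, float] = {}
    retained: list[str] = []
    for col in matrix.column_names:
        x = matrix.values[col].to_numpy(dtype=float)
        x1, x2 = x[g1], x[g2]
        if np.ptp(x1) == 0 and np.ptp(x2) == 0:
            logger.warning("column %s has zero variance in both tasks; excluded", col)
            continue
        res = two_task_t_test(x1, x2, paired=paired)
        p_values[col] = res["p"]
        if res["p"] <= level:
            retained.append(col)

    return SearchSpace(columns=sort_columns(retained), alpha=alpha, p_values=p_values)


def pearson_matrix(measure_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between named measure vectors.

    Unit diagonal, symmetric, entries in [-1, 1].  A zero-variance measure
    yields NaN against every other measure (undefined, not zero).
    """
    df = pd.DataFrame(measure_table)
    if len(df) < 3:
        raise ValueError("need at least 3 joint observations for correlations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    corr = pd.DataFrame(corr, index=df.columns, columns=df.columns)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def error_rate(scores: SubjectScores) -> float:
    """Driving error rate ae/at: erroneous lane-change activities out of
    those presented, in [0, 1]."""
    ae, at = scores.activities_erroneous, scores.activities_total
    if ae is None or at is None:
        raise ValueError("activity counts are missing")
    if at <= 0:
        raise ValueError("total activities must be positive")
    return ae / at


def task_summary(per_subject_scores: list[SubjectScores]) -> pd.DataFrame:
    """Mean and SD of each measure, per task, across subjects.

    A single observation reports SD = 0 with a warning (there is no
    dispersion to estimate from one subject).
    """
    if not per_subject_scores:
        raise ValueError("no subject scores given")
    records = []
    for s in per_subject_scores:
        rec = {"task": s.task, "ISA": s.isa, "NASA_TLX": s.nasa_tlx}
        if s.activities_erroneous is not None:
            rec["ER_count"] = s.activities_erroneous
        records.append(rec)
    df = pd.DataFrame(records)

    rows = []
    for task, grp in df.groupby("task", sort=True):
        for measure in [c for c in grp.columns if c != "task"]:
            vals = grp[measure].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            if vals.size == 1:
                warnings.warn(
                    f"single observation for {measure}/{task}; SD reported as 0",
                    stacklevel=2,
                )
                sd = 0.0
            else:
                sd = float(vals.std(ddof=1))
            rows.append(
                {"task": task, "measure": measure, "mean": float(vals.mean()), "sd": sd}
            )
    return pd.DataFrame(rows)
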