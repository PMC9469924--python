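"""Selective classification by softmax thresholding.

For each task independently, the smallest threshold on the maximum
softmax entry is found (over the grid 0.001, 0.002, ..., 0.999) such
that validation accuracy over the retained documents (confidence >=
threshold) reaches the target (0.97 by default, the accuracy registries
require before deployment).  At test time predictions below the
threshold are abstained; performance is reported as the retention
proportion RP = retained/total (in percent, RP = 100 - abstention rate)
together with the accuracy of the retained set.

The module also carries the overconfidence diagnostics: histograms of
wrong-prediction confidence, counts of wrong predictions above a
confidence cutoff, the ensemble-size curve of that count, and percentile
confidence intervals over a model pool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ensemble import EnsemblePool, aggregate
from .model import PredictionSet

#: Sentinel threshold meaning "abstain on everything" (no grid value met
#: the target accuracy on validation).
ABSTAIN_ALL = 1.001


class CalibrationWarning(UserWarning):
    pass


def threshold_grid() -> np.ndarray:
    """The 999 candidate thresholds 0.001, 0.002, ..., 0.999."""
    return np.arange(1, 1000, dtype=np.int64) / 1000.0


def calibrate_threshold(
    confidences: np.ndarray,
    correct: np.ndarray,
    target: float = 0.97,
) -> float:
    """Smallest grid threshold whose retained set (confidence >= threshold)
    is non-empty and at least ``target`` accurate.

    Returns :data:`ABSTAIN_ALL` (with a warning) when no grid value
    qualifies.
    """
    confidences = np.asarray(confidences, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if confidences.size == 0:
        raise ValueError("empty calibration set")
    if confidences.min() < 0 or confidences.max() > 1:
        raise ValueError("confidences must lie in [0, 1]")
    order = np.argsort(confidences)
    conf_sorted = confidences[order]
    # suffix sums: retained correct/total for each cut position
    corr_sorted = correct[order].astype(np.int64)
    suffix_correct = np.concatenate([np.cumsum(corr_sorted[::-1])[::-1], [0]])
    n = confidences.size
    for tau in threshold_grid():
        i = np.searchsorted(conf_sorted, tau, side="left")  # first retained
        retained = n - i
        if retained == 0:
            break
        if suffix_correct[i] / retained >= target:
            return float(tau)
    warnings.warn(
        f"no threshold on the grid reaches target accuracy {target}; abstaining on all",
        CalibrationWarning,
        stacklevel=2,
    )
    return ABSTAIN_ALL


@dataclass
class ThresholdTable:
    """Per-task calibrated thresholds for one model."""

    thresholds: dict[str, float]
    target: float = 0.97
    calibration_split: str = "validation"

    def __getitem__(self, task: str) -> float:
        return self.thresholds[task]


def calibrate_thresholds(
    predictions: PredictionSet,
    labels: Mapping[str, np.ndarray],
    target: float = 0.97,
    calibration_split: str = "validation",
) -> ThresholdTable:
    """Calibrate each task's threshold independently on validation data."""
    th = {}
    for task in predictions.probs:
        conf = predictions.confidence(task)
        correct = predictions.argmax(task) == np.asarray(labels[task])
        th[task] = calibrate_threshold(conf, correct, target)
    return ThresholdTable(thresholds=th, target=target, calibration_split=calibration_split)


@dataclass
class TaskRetention:
    """Abstention outcome for one task."""

    threshold: float
    total: int
    retained: int
    accuracy: float | None  # None when nothing is retained
    ci: tuple[float, float] | None = None

    @property
    def rp(self) -> float:
        """Retention proportion in percent."""
        return 100.0 * self.retained / self.total if self.total else 0.0

    @property
    def abstained(self) -> int:
        return self.total - self.retained

    @property
    def abstention_rate(self) -> float:
        return 100.0 - self.rp


@dataclass
class RetentionReport:
    """Per-task retention proportions and retained-set accuracy."""

    tasks: dict[str, TaskRetention] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for task, r in self.tasks.items():
            rows.append(
                {
                    "task": task,
                    "threshold": r.threshold,
                    "total": r.total,
                    "retained": r.retained,
                    "rp_percent": r.rp,
                    "accuracy": r.accuracy,
                }
            )
        return rows


def apply_abstention(
    predictions: PredictionSet,
    labels: Mapping[str, np.ndarray],
    thresholds: ThresholdTable,
) -> RetentionReport:
    """Apply calibrated thresholds to test predictions: retain documents
    with confidence >= threshold, report RP and retained accuracy (None
    when everything is abstained)."""
    report = RetentionReport()
    for task in predictions.probs:
        conf = predictions.confidence(task)
        correct = predictions.argmax(task) == np.asarray(labels[task])
        tau = thresholds[task]
        keep = conf >= tau
        retained = int(keep.sum())
        acc = float(correct[keep].mean()) if retained else None
        report.tasks[task] = TaskRetention(
            threshold=tau, total=conf.size, retained=retained, accuracy=acc
        )
    return report


def retained_count(rp_percent: float, N: int) -> int:
    """Documents retained at a retention proportion: floor(rp/100 * N).

    Truncation (not rounding) matches the printed report counts derived
    from percentage tables.
    """
    if not (0.0 <= rp_percent <= 100.0):
        raise ValueError(f"rp_percent must be in [0, 100], got {rp_percent}")
    if N < 0:
        raise ValueError("N must be >= 0")
    return math.floor(rp_percent / 100.0 * N)


def wrong_confidence_histogram(
    predictions: PredictionSet,
    labels: Mapping[str, np.ndarray],
    task: str,
    bin_edges: Sequence[float],
) -> np.ndarray:
    """Histogram of prediction confidence over the wrong predictions only.

    Bins are left-closed right-open with the last bin closed (NumPy
    convention), and must partition [0, 1].
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges[0] != 0.0 or edges[-1] != 1.0 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must increase from 0 to 1")
    wrong = predictions.argmax(task) != np.asarray(labels[task])
    conf = predictions.confidence(task)[wrong]
    counts, _ = np.histogram(conf, bins=edges)
    return counts


def count_overconfident_wrong(
    predictions: PredictionSet,
    labels: Mapping[str, np.ndarray],
    task: str,
    cutoff: float = 0.97,
) -> int:
    """Wrong predictions with confidence strictly greater than ``cutoff``."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    wrong = predictions.argmax(task) != np.asarray(labels[task])
    conf = predictions.confidence(task)
    return int(((conf > cutoff) & wrong).sum())


@dataclass
class SizeCurve:
    """Overconfident-wrong counts versus ensemble size."""

    sizes: list[int]
    means: dict[str, list[float]]  # task -> mean count per size
    stds: dict[str, list[float]]
    replicates: int


def ensemble_size_curve(
    member_predictions: Sequence[PredictionSet],
    labels: Mapping[str, np.ndarray],
    sizes: Sequence[int],
    replicates: int = 50,
    seed: int = 0,
    cutoff: float = 0.97,
    exhaustive_singletons: bool = False,
    with_replacement: bool = False,
) -> SizeCurve:
    """Mean (over ``replicates`` random member subsets) of the
    overconfident-wrong count, for each ensemble size.

    Subsets of ``m`` distinct members are drawn uniformly without
    replacement by default.  When a size equals the pool size the full
    ensemble is used once (no sampling freedom).  With
    ``exhaustive_singletons`` size 1 enumerates every member instead of
    sampling.
    """
    T = len(member_predictions)
    if any(m > T for m in sizes):
        raise ValueError(f"requested size exceeds pool size {T}")
    if any(m < 1 for m in sizes):
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    tasks = list(member_predictions[0].probs)
    means: dict[str, list[float]] = {t: [] for t in tasks}
    stds: dict[str, list[float]] = {t: [] for t in tasks}
    for m in sizes:
        if m == T and not with_replacement:
            subsets = [list(range(T))]
        elif m == 1 and exhaustive_singletons:
            subsets = [[i] for i in range(T)]
        else:
            subsets = [
                list(rng.choice(T, size=m, replace=with_replacement))
                for _ in range(replicates)
            ]
        per_task_counts: dict[str, list[int]] = {t: [] for t in tasks}
        for idx in subsets:
            agg = aggregate([member_predictions[i] for i in idx])
            for t in tasks:
                per_task_counts[t].append(
                    count_overconfident_wrong(agg, labels, t, cutoff)
                )
        for t in tasks:
            arr = np.asarray(per_task_counts[t], dtype=float)
            means[t].append(float(arr.mean()))
            stds[t].append(float(arr.std()))
    return SizeCurve(sizes=list(sizes), means=means, stds=stds, replicates=replicates)


def percentile_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval over a pool of per-model metric values,
    with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a percentile interval")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def bootstrap_accuracy_ci(
    correct: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap-over-documents percentile interval for an accuracy."""
    correct = np.asarray(correct, dtype=float)
    if correct.size == 0:
        raise ValueError("empty retained set")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, correct.size, size=(n_boot, correct.size))
    accs = correct[idx].mean(axis=1)
    return percentile_ci(accs, level)
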