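"""Discrimination and calibration metrics built from first principles.

All four headline metrics of the evaluation harness live here: F1 and the
Matthews correlation coefficient (MCC) on confusion counts, the rank-based
(Mann-Whitney) AUC, and the expected calibration error (ECE) over
equal-width probability bins.  They are implemented directly from their
definitions; established library versions serve only as cross-checks in
the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ConfusionCounts:
    """The four cells of a binary confusion matrix."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError(f"confusion counts must be nonnegative: {self}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, labels, predictions) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        p = np.asarray(predictions, dtype=int)
        if y.shape != p.shape:
            raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
        return cls(
            tp=int(np.sum((y == 1) & (p == 1))),
            fp=int(np.sum((y == 0) & (p == 1))),
            tn=int(np.sum((y == 0) & (p == 0))),
            fn=int(np.sum((y == 1) & (p == 0))),
        )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    Any zero factor in the denominator means one predicted or observed
    class is absent; the prediction is then no better than random and the
    statistic is defined as 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when there are no true positives."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    if c.tp == 0:
        return 0.0
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    return 2 * precision * recall / (precision + recall)


def auc(probabilities, labels) -> float:
    """Rank-based AUC: the probability a random positive outscores a random
    negative, ties counted one half (Mann-Whitney statistic)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = sps.rankdata(p)  # average ranks handle ties as 1/2
    rank_sum_pos = float(ranks[y == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


@dataclass(frozen=True)
class CalibrationReport:
    """Reliability-diagram summary: per-bin counts, confidence, accuracy, ECE."""

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    bin_confidence: np.ndarray  # mean predicted probability, NaN for empty bins
    bin_accuracy: np.ndarray  # observed event (or correctness) fraction
    ece: float


def ece(probabilities, labels, n_bins: int = 10, mode: str = "event") -> CalibrationReport:
    """Expected calibration error over equal-width bins of [0, 1].

    Bins are right-closed except the first, so a probability p lands in bin
    ceil(p * n_bins).  In the default ``event`` mode (the reliability
    diagram for the event probability) a bin's accuracy is its observed
    event fraction and its confidence the mean predicted probability; the
    ``class`` mode instead scores the predicted class's confidence
    max(p, 1-p) against its correctness.  Empty bins contribute nothing.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if mode not in ("event", "class"):
        raise ValueError(f"unknown ECE mode {mode!r}")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if mode == "class":
        pred = (p >= 0.5).astype(int)
        conf_values = np.where(pred == 1, p, 1.0 - p)
        correct = (pred == y).astype(float)
    else:
        conf_values = p
        correct = y.astype(float)
    idx = np.clip(np.ceil(conf_values * n_bins).astype(int) - 1, 0, n_bins - 1)
    counts = np.zeros(n_bins, dtype=int)
    confidence = np.full(n_bins, np.nan)
    accuracy = np.full(n_bins, np.nan)
    total_gap = 0.0
    n = len(p)
    for b in range(n_bins):
        in_bin = idx == b
        counts[b] = int(in_bin.sum())
        if counts[b] == 0:
            continue
        confidence[b] = float(conf_values[in_bin].mean())
        accuracy[b] = float(correct[in_bin].mean())
        total_gap += counts[b] / n * abs(accuracy[b] - confidence[b])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return CalibrationReport(edges, counts, confidence, accuracy, float(total_gap))


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test on per-iteration metric differences."""

    t: float
    p: float
    n: int
    mean_difference: float
    zero_variance: bool = False
    exact_tie: bool = False


def paired_t_test(metric_a, metric_b) -> PairedTestResult:
    """Two-sided paired t-test of two per-iteration metric vectors.

    The vectors must be paired by iteration (identical splits).  When the
    differences have zero variance the t statistic is degenerate: all-zero
    differences report an exact tie (t = 0, p = 1), a constant nonzero
    shift reports an infinite statistic with the zero-variance flag set.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired test needs two equal-length vectors of length >= 2")
    d = a - b
    if float(np.std(d, ddof=1)) == 0.0:
        if d[0] == 0.0:
            return PairedTestResult(0.0, 1.0, len(d), 0.0, zero_variance=True, exact_tie=True)
        t = math.inf if d[0] > 0 else -math.inf
        return PairedTestResult(t, 0.0, len(d), float(d.mean()), zero_variance=True)
    res = sps.ttest_rel(a, b)
    return PairedTestResult(float(res.statistic), float(res.pvalue), len(d), float(d.mean()))


@dataclass(frozen=True)
class AveragedRoc:
    """Vertically averaged ROC: mean and SD of TPR on a fixed FPR grid."""

    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    tpr_sd: np.ndarray
    n_iterations: int

    def area(self) -> float:
        """Trapezoidal area under the mean curve."""
        return float(np.trapezoid(self.tpr_mean, self.fpr_grid))


def roc_points(probabilities, labels) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC step curve (FPR, TPR) sorted by ascending FPR."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, probabilities, drop_intermediate=False)
    return fpr, tpr


def averaged_roc(iterations, n_grid: int = 101) -> AveragedRoc:
    """Average per-iteration ROC curves vertically on a fixed FPR grid.

    ``iterations`` yields (probabilities, labels) pairs; each curve is
    linearly interpolated onto ``n_grid`` equally spaced FPR points and the
    per-point mean and SD of the TPR are reported.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    curves = []
    for probs, labels in iterations:
        fpr, tpr = roc_points(probs, labels)
        curves.append(np.interp(grid, fpr, tpr))
    if not curves:
        raise ValueError("averaged_roc needs at least one iteration")
    stack = np.vstack(curves)
    sd = np.std(stack, axis=0, ddof=1) if len(curves) > 1 else np.zeros(n_grid)
    return AveragedRoc(grid, stack.mean(axis=0), sd, len(curves))
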