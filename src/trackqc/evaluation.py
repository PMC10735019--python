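"""Metrics, curves and operating-point selection for the image QC models.

Conventions, used everywhere: the positive class is "Accepted"
(label 1), an image is predicted Accepted iff its probability is
*strictly* greater than the threshold (so a threshold of 1.0 rejects
everything), and zero-denominator metrics return ``None`` rather than a
number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "OperatingPoint",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "roc_curve",
    "pr_curve",
    "select_threshold_for_precision",
    "stratified_precision",
    "project_confusion",
    "prediction_histogram",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with Rejected as the negative and Accepted as the positive class."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass(frozen=True)
class OperatingPoint:
    """A decision threshold with the precision/recall it achieves."""

    threshold: float
    precision: float
    recall: float


def _check_inputs(labels, probabilities) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels).ravel().astype(np.int64)
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    return y, p


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionMatrix:
    """Confusion counts at a threshold (predicted Accepted iff p > t)."""
    y, p = _check_inputs(labels, probabilities)
    pred = p > threshold
    pos = y == 1
    return ConfusionMatrix(
        tn=int(np.sum(~pos & ~pred)),
        fp=int(np.sum(~pos & pred)),
        fn=int(np.sum(pos & ~pred)),
        tp=int(np.sum(pos & pred)),
    )


def accuracy(matrix: ConfusionMatrix) -> float | None:
    if matrix.total == 0:
        return None
    return (matrix.tp + matrix.tn) / matrix.total


def precision(matrix: ConfusionMatrix) -> float | None:
    denom = matrix.tp + matrix.fp
    return None if denom == 0 else matrix.tp / denom


def recall(matrix: ConfusionMatrix) -> float | None:
    denom = matrix.tp + matrix.fn
    return None if denom == 0 else matrix.tp / denom


def roc_curve(labels, probabilities) -> tuple[np.ndarray, np.ndarray, float]:
    """(FPR, TPR) over all distinct thresholds, plus the trapezoidal AUC."""
    y, p = _check_inputs(labels, probabilities)
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, p)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def pr_curve(labels, probabilities) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision-recall pairs at every distinct threshold.

    Returns ``(recall, precision, thresholds)``. Thresholds sweep the
    distinct scores from below the minimum (everything predicted
    Accepted, precision = class prevalence) upwards; ties are grouped.
    """
    y, p = _check_inputs(labels, probabilities)
    if np.unique(y).size < 2:
        raise ValueError("PR curve requires both classes present")
    thresholds = np.concatenate(([-np.inf], np.unique(p)))
    recalls, precisions = [], []
    n_pos = int(np.sum(y == 1))
    for t in thresholds:
        pred = p > t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        precisions.append(tp / (tp + fp) if tp + fp else 1.0)
        recalls.append(tp / n_pos)
    return np.asarray(recalls), np.asarray(precisions), thresholds


def select_threshold_for_precision(labels, probabilities, target: float = 0.97) -> OperatingPoint:
    """Smallest threshold achieving the precision target.

    Because recall is non-increasing in the threshold, the smallest
    achieving threshold has the best recall subject to the precision
    constraint. Raises ``ValueError`` (naming the maximum achievable
    precision) when no threshold reaches the target.
    """
    recalls, precisions, thresholds = pr_curve(labels, probabilities)
    # exclude the degenerate all-negative end where precision defaults to 1
    defined = recalls > 0
    ok = defined & (precisions >= target)
    if not ok.any():
        best = precisions[defined].max() if defined.any() else float("nan")
        raise ValueError(
            f"precision target {target} unachievable; maximum achievable precision is {best:.4f}"
        )
    i = int(np.argmax(ok))  # thresholds are sorted ascending
    return OperatingPoint(
        threshold=float(thresholds[i]), precision=float(precisions[i]), recall=float(recalls[i])
    )


def stratified_precision(labels, probabilities, track_counts, bin_edges, threshold: float = 0.5):
    """Precision per track-count bin (None where undefined).

    Bins follow ``numpy.digitize`` half-open convention
    ``[edge_i, edge_{i+1})``; counts below the first or above the last
    edge raise, since the bins must cover the observed counts.
    """
    y, p = _check_inputs(labels, probabilities)
    counts = np.asarray(track_counts, dtype=np.float64).ravel()
    edges = np.asarray(bin_edges, dtype=np.float64)
    if counts.shape != y.shape:
        raise ValueError("track_counts must align with labels")
    if counts.size and (counts.min() < edges[0] or counts.max() >= edges[-1]):
        raise ValueError("bin edges must cover all observed track counts")
    which = np.digitize(counts, edges) - 1
    out = []
    for b in range(edges.size - 1):
        sel = which == b
        out.append(precision(confusion(y[sel], p[sel], threshold)) if sel.any() else None)
    return out


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def project_confusion(
    precision_value: float, recall_value: float, n_positive: int, n_negative: int
) -> ConfusionMatrix:
    """Expected integer confusion matrix for given operating metrics.

    For an acquisition batch with ``n_positive`` adequate and
    ``n_negative`` inadequate images, a classifier at the stated
    precision/recall yields tp = round(recall * n_pos) accepted-and-
    adequate images, and fp = round(tp (1-prec)/prec) slipped-through
    inadequate ones. Rounding is to the nearest integer, ties away from
    zero. Raises when the implied fp exceeds ``n_negative``.
    """
    if not 0.0 < precision_value <= 1.0 or not 0.0 < recall_value <= 1.0:
        raise ValueError("precision and recall must lie in (0, 1]")
    if n_positive < 0 or n_negative < 0:
        raise ValueError("counts must be non-negative")
    tp = _round_half_away(recall_value * n_positive)
    fn = n_positive - tp
    fp = _round_half_away(tp * (1.0 - precision_value) / precision_value)
    tn = n_negative - fp
    if fp > n_negative:
        raise ValueError("implied false positives exceed the negative count")
    return ConfusionMatrix(tn=tn, fp=fp, fn=fn, tp=tp)


def prediction_histogram(labels, probabilities, bins=10):
    """Per-class counts of predicted probabilities.

    Returns ``(counts_rejected, counts_accepted, bin_edges)`` — the
    ground-truth-split histogram used to compare model confidence.
    """
    y, p = _check_inputs(labels, probabilities)
    edges = np.histogram_bin_edges(p, bins=bins, range=(0.0, 1.0)) if np.isscalar(bins) else np.asarray(bins)
    neg, _ = np.histogram(p[y == 0], bins=edges)
    pos, _ = np.histogram(p[y == 1], bins=edges)
    return neg, pos, edges
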