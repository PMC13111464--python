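"""Per-class and support-weighted semantic-segmentation metrics.

For each class k the counts TP_k, FP_k, FN_k yield precision, recall, F1 and
IoU; aggregates weight each class by its support share w_k = N_k / sum_j N_j.
Overall accuracy is sum_k TP_k / N.  Absent classes (0/0) score 0 and are
flagged rather than silently inflating the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "per_class_metrics",
    "weighted_metrics",
    "evaluate_labels",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "iou")


@dataclass
class ConfusionCounts:
    classes: np.ndarray      # class ids, sorted
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    support: np.ndarray      # N_k from the true labels
    total: int               # N


@dataclass
class MetricsReport:
    classes: np.ndarray
    per_class: dict[str, np.ndarray]      # metric name -> per-class vector
    weights: np.ndarray                   # w_k, sums to 1
    weighted: dict[str, float]            # support-weighted aggregates
    overall_accuracy: float               # sum TP_k / N
    undefined: np.ndarray                 # classes where a 0/0 was coerced to 0


def confusion(true_labels, pred_labels, classes=None) -> ConfusionCounts:
    """Tally TP/FP/FN/TN per class from paired label sequences."""
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([t, p]))
    else:
        classes = np.asarray(classes)
        unknown = np.setdiff1d(np.unique(np.concatenate([t, p])), classes)
        if unknown.size:
            raise ValueError(f"labels {unknown.tolist()} outside the class set")
    n = len(t)
    tp = np.array([np.sum((t == k) & (p == k)) for k in classes])
    fp = np.array([np.sum((t != k) & (p == k)) for k in classes])
    fn = np.array([np.sum((t == k) & (p != k)) for k in classes])
    support = np.array([np.sum(t == k) for k in classes])
    tn = n - tp - fp - fn
    return ConfusionCounts(classes, tp, fp, fn, tn, support, n)


def _safe_div(num, den):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out, ~ok


def per_class_metrics(counts: ConfusionCounts) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Precision, recall, F1, IoU and per-class accuracy (TP+TN)/N.

    Returns the metric dict and a boolean flag vector marking classes whose
    metrics were undefined (0/0) and coerced to 0.

    The per-class "accuracy" column follows the binary one-vs-rest reading
    (TP_k + TN_k)/N, the only interpretation consistent with per-label
    accuracy exceeding per-label recall in published organ-level tables.
    """
    precision, u1 = _safe_div(counts.tp, counts.tp + counts.fp)
    recall, u2 = _safe_div(counts.tp, counts.tp + counts.fn)
    f1, u3 = _safe_div(2 * precision * recall, precision + recall)
    iou, u4 = _safe_div(counts.tp, counts.tp + counts.fp + counts.fn)
    acc, _ = _safe_div(counts.tp + counts.tn, np.full_like(counts.tp, counts.total))
    metrics = dict(accuracy=acc, precision=precision, recall=recall, f1=f1, iou=iou)
    return metrics, (u1 | u2 | u3 | u4)


def weighted_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Support-weighted aggregates: Metric_weighted = sum_k w_k Metric_k."""
    if counts.support.sum() == 0:
        raise ValueError("all class supports are zero")
    per_class, undefined = per_class_metrics(counts)
    w = counts.support / counts.support.sum()
    weighted = {name: float(np.sum(w * vec)) for name, vec in per_class.items()}
    overall = float(counts.tp.sum() / counts.total) if counts.total else 0.0
    return MetricsReport(counts.classes, per_class, w, weighted, overall,
                         undefined)


def evaluate_labels(true_labels, pred_labels, classes=None) -> MetricsReport:
    """Convenience: confusion -> per-class -> weighted report in one call."""
    return weighted_metrics(confusion(true_labels, pred_labels, classes))
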