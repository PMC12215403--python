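"""Classifier metrics: ROC/PR curves, areas, F1, and confusion matrices.

Implemented natively (threshold sweep over unique scores, trapezoidal areas)
so the training pipeline has no model-evaluation dependency; an established
implementation serves as a cross-check in the test suite only.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "roc_curve",
    "pr_curve",
    "auc_roc",
    "auc_pr",
    "f1_score",
    "precision_recall",
    "confusion_matrix",
]


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to sweep thresholds")
    return scores, labels


def roc_curve(scores, labels):
    """(fpr, tpr) stepping through the unique scores in decreasing order.

    Tied scores move together (one step per distinct score), so the curve is
    the standard empirical ROC; the first point is (0, 0) and the last (1, 1).
    """
    scores, labels = _check(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    tps = np.cumsum(l)
    fps = np.cumsum(1 - l)
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], int)
    keep = np.r_[distinct, len(s) - 1]
    tpr = np.r_[0.0, tps[keep] / tps[-1]]
    fpr = np.r_[0.0, fps[keep] / fps[-1]]
    return fpr, tpr


def auc_roc(scores, labels) -> float:
    fpr, tpr = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def pr_curve(scores, labels):
    """(recall, precision) over decreasing score thresholds.

    Anchored at recall 0 with the precision of the highest-scoring block,
    ending at recall 1 (threshold below every score).
    """
    scores, labels = _check(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    tps = np.cumsum(l)
    predicted = np.arange(1, len(s) + 1)
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], int)
    keep = np.r_[distinct, len(s) - 1]
    precision = tps[keep] / predicted[keep]
    recall = tps[keep] / tps[-1]
    return np.r_[0.0, recall], np.r_[precision[0], precision]


def auc_pr(scores, labels) -> float:
    recall, precision = pr_curve(scores, labels)
    return float(np.trapezoid(precision, recall))


def precision_recall(labels, predictions):
    labels = np.asarray(labels, int)
    predictions = np.asarray(predictions, int)
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def f1_score(labels, predictions) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    p, r = precision_recall(labels, predictions)
    return 2 * p * r / (p + r) if p + r else 0.0


def confusion_matrix(labels, predictions, normalize: bool = False) -> np.ndarray:
    """2x2 matrix with true class on rows; optionally row-normalized."""
    labels = np.asarray(labels, int)
    predictions = np.asarray(predictions, int)
    cm = np.zeros((2, 2), dtype=float)
    for t, p in zip(labels, predictions):
        cm[t, p] += 1
    if normalize:
        sums = cm.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        cm = cm / sums
    return cm
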