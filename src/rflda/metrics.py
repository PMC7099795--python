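"""ROC and precision-recall evaluation for ranked association scores.

All test samples are sorted by score descending; every distinct score is a
threshold, samples at or above it are called positive, and the confusion
counts TP/FP/TN/FN give

    TPR = TP / (TP + FN)        FPR = FP / (FP + TN)
    Precision = TP / (TP + FP)  Recall = TP / (TP + FN)

Tied scores share a single threshold, so no arbitrary intra-tie ordering
can move the curves.  AUC is the trapezoidal area under (FPR, TPR), which
for these tie-grouped points equals the probability that a random positive
outranks a random negative (ties counting 1/2).  AUPR uses the step rule:
precision is held constant over each recall increment.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MetricError",
    "confusion_counts",
    "roc_points",
    "pr_points",
    "auc",
    "aupr",
]


class MetricError(ValueError):
    """Labels do not support the requested metric (e.g. one class only)."""


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-d arrays")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return labels.astype(int), scores


def confusion_counts(labels, scores) -> np.ndarray:
    """Cumulative (threshold, TP, FP, TN, FN) rows, one per distinct score.

    Thresholds run from the highest score down; row k gives the counts when
    every sample scoring >= threshold k is called positive.
    """
    labels, scores = _validate(labels, scores)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # last index of each tie group = cumulative counts at that threshold
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    boundaries = np.r_[distinct, labels.size - 1]
    tp = np.cumsum(sorted_labels)[boundaries]
    fp = (boundaries + 1) - tp
    pos, neg = labels.sum(), labels.size - labels.sum()
    return np.column_stack(
        [sorted_scores[boundaries], tp, fp, neg - fp, pos - tp]
    )


def roc_points(labels, scores) -> np.ndarray:
    """Ordered (FPR, TPR) points, anchored at (0, 0) and ending at (1, 1)."""
    labels, scores = _validate(labels, scores)
    pos = labels.sum()
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        raise MetricError("ROC needs both a positive and a negative sample")
    counts = confusion_counts(labels, scores)
    tpr = counts[:, 1] / pos
    fpr = counts[:, 2] / neg
    return np.vstack([[0.0, 0.0], np.column_stack([fpr, tpr])])


def pr_points(labels, scores) -> np.ndarray:
    """Ordered (Recall, Precision) points at each distinct threshold."""
    labels, scores = _validate(labels, scores)
    pos = labels.sum()
    if pos == 0:
        raise MetricError("precision-recall needs at least one positive sample")
    counts = confusion_counts(labels, scores)
    recall = counts[:, 1] / pos
    precision = counts[:, 1] / (counts[:, 1] + counts[:, 2])
    return np.column_stack([recall, precision])


def auc(labels, scores) -> float:
    """Area under the ROC curve (trapezoidal)."""
    points = roc_points(labels, scores)
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def aupr(labels, scores) -> float:
    """Area under the precision-recall curve, step-wise integration."""
    points = pr_points(labels, scores)
    recall, precision = points[:, 0], points[:, 1]
    deltas = np.diff(np.r_[0.0, recall])
    return float(np.sum(deltas * precision))
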