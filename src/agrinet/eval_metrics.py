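"""Segmentation metrics: confusion matrix, mIoU, overall accuracy, recall.

All scalar metrics are computed from an aggregated (micro) confusion matrix
over the evaluated pixels; mean IoU and recall are macro averages over
classes, excluding 0/0 terms (a class absent from both prediction and
truth contributes nothing to the mean rather than a 0 or 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionMatrix:
    """counts[t, p] = number of pixels with true class t predicted as p."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion(pred, truth, n_classes: int) -> ConfusionMatrix:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty masks")
    p = pred.ravel().astype(np.int64)
    t = truth.ravel().astype(np.int64)
    if p.min() < 0 or p.max() >= n_classes or t.min() < 0 or t.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.bincount(t * n_classes + p, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes))


def per_class_iou(cm: ConfusionMatrix) -> np.ndarray:
    """IoU_i = TP_i / (TP_i + FP_i + FN_i); NaN where the class is absent
    from both prediction and truth."""
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    union = c.sum(axis=0) + c.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, tp / union, np.nan)


def miou(cm: ConfusionMatrix) -> float:
    iou = per_class_iou(cm)
    present = ~np.isnan(iou)
    if not present.any():
        raise ValueError("all classes absent from both prediction and truth")
    return float(iou[present].mean())


def overall_accuracy(cm: ConfusionMatrix) -> float:
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    support = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(support > 0, tp / support, np.nan)


def recall(cm: ConfusionMatrix, averaging: str = "macro") -> float:
    """Macro-averaged per-class recall over classes present in the truth."""
    if averaging != "macro":
        raise ValueError("only macro averaging is supported")
    rec = per_class_recall(cm)
    present = ~np.isnan(rec)
    if not present.any():
        raise ValueError("no classes present in truth")
    return float(rec[present].mean())


def evaluate_masks(pred_masks, truth_masks, n_classes: int = 3) -> dict:
    """Aggregate a list of mask pairs into one confusion matrix and report
    mIoU / OA / recall plus the per-class breakdowns."""
    total = None
    for pred, truth in zip(pred_masks, truth_masks):
        cm = confusion(pred, truth, n_classes)
        total = cm if total is None else total + cm
    if total is None:
        raise ValueError("no mask pairs supplied")
    return {
        "confusion": total.counts.tolist(),
        "per_class_iou": per_class_iou(total).tolist(),
        "per_class_recall": per_class_recall(total).tolist(),
        "miou": miou(total),
        "overall_accuracy": overall_accuracy(total),
        "recall": recall(total),
    }
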