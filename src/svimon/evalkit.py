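"""Segmentation evaluation: confusion counts, P/R/F1/OA, IoU and mIoU.

Binary metrics treat one designated positive class (vegetation by default)
against the rest; IoU is computed per class and averaged over classes whose
union is non-empty. Aggregate metrics are micro-averaged: pixel counts are
pooled over every image before the ratios are formed, and per-image overall
accuracies are reported alongside with their min/max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from svimon.errors import ParameterError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "binary_metrics",
    "iou_scores",
    "evaluate_testset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts for one positive class; sums to the evaluated area."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion_counts(
    pred_mask: np.ndarray, true_mask: np.ndarray, positive_class: int = 1
) -> ConfusionCounts:
    """Exhaustive per-pixel tp/tn/fp/fn for ``positive_class``."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ParameterError(f"shape mismatch: {pred.shape} vs {true.shape}")
    p = pred == positive_class
    t = true == positive_class
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def binary_metrics(c: ConfusionCounts) -> tuple[float, float, float, float, set[str]]:
    """Precision, recall, F1 and overall accuracy from pooled counts.

    Returns ``(precision, recall, f1, overall_accuracy, degenerate)`` where
    ``degenerate`` names the metrics whose denominator was zero (those are
    reported as 0.0 rather than NaN).
    """
    if c.total == 0:
        raise ParameterError("all-zero confusion counts")
    degenerate: set[str] = set()

    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision = 0.0
        degenerate.add("precision")
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall = 0.0
        degenerate.add("recall")
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        degenerate.add("f1")
    overall_accuracy = (c.tp + c.tn) / c.total
    return precision, recall, f1, overall_accuracy, degenerate


def iou_scores(
    pred_mask: np.ndarray,
    true_mask: np.ndarray,
    class_ids: tuple[int, ...] = (0, 1, 2),
) -> tuple[dict[int, float], float]:
    """Per-class intersection-over-union and its mean.

    Classes absent from both masks (empty union) are excluded from the mean
    and omitted from the per-class dict.
    """
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ParameterError(f"shape mismatch: {pred.shape} vs {true.shape}")
    per_class: dict[int, float] = {}
    for cid in class_ids:
        p = pred == cid
        t = true == cid
        union = int(np.sum(p | t))
        if union == 0:
            continue
        per_class[cid] = float(np.sum(p & t)) / union
    if not per_class:
        raise ParameterError("no class has a non-empty union")
    miou = float(np.mean(list(per_class.values())))
    return per_class, miou


@dataclass
class MetricReport:
    """Micro-aggregated test-set metrics plus the per-image accuracy spread."""

    precision: float
    recall: float
    f1: float
    overall_accuracy: float
    iou: dict[int, float]
    miou: float
    per_image_accuracy: list[float]
    degenerate: set[str] = field(default_factory=set)

    @property
    def accuracy_min(self) -> float:
        return min(self.per_image_accuracy)

    @property
    def accuracy_max(self) -> float:
        return max(self.per_image_accuracy)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "overall_accuracy": self.overall_accuracy,
            "iou": {str(k): v for k, v in self.iou.items()},
            "miou": self.miou,
            "per_image_accuracy": self.per_image_accuracy,
            "accuracy_min": self.accuracy_min,
            "accuracy_max": self.accuracy_max,
            "degenerate": sorted(self.degenerate),
        }


def evaluate_masks(
    preds: list[np.ndarray],
    trues: list[np.ndarray],
    positive_class: int = 1,
    class_ids: tuple[int, ...] = (0, 1, 2),
) -> MetricReport:
    """Metric report for pre-computed predicted masks."""
    if not preds:
        raise ParameterError("empty test set")
    if len(preds) != len(trues):
        raise ParameterError("prediction/truth count mismatch")
    pooled = ConfusionCounts(0, 0, 0, 0)
    per_image_acc: list[float] = []
    inter = {cid: 0 for cid in class_ids}
    union = {cid: 0 for cid in class_ids}
    for pred, true in zip(preds, trues):
        c = confusion_counts(pred, true, positive_class)
        pooled = pooled + c
        per_image_acc.append((c.tp + c.tn) / c.total)
        for cid in class_ids:
            p = np.asarray(pred) == cid
            t = np.asarray(true) == cid
            inter[cid] += int(np.sum(p & t))
            union[cid] += int(np.sum(p | t))
    precision, recall, f1, oa, degenerate = binary_metrics(pooled)
    iou = {cid: inter[cid] / union[cid] for cid in class_ids if union[cid] > 0}
    miou = float(np.mean(list(iou.values())))
    return MetricReport(
        precision=precision,
        recall=recall,
        f1=f1,
        overall_accuracy=oa,
        iou=iou,
        miou=miou,
        per_image_accuracy=per_image_acc,
        degenerate=degenerate,
    )


def evaluate_testset(model, test_pairs, positive_class: int = 1) -> MetricReport:
    """Predict every test pair with ``model`` and aggregate the metrics."""
    if not test_pairs:
        raise ParameterError("empty test set")
    from svimon.segnet import predict_mask  # local import to avoid cycle

    preds = [predict_mask(model, p.image)[0] for p in test_pairs]
    trues = [p.mask for p in test_pairs]
    return evaluate_masks(preds, trues, positive_class=positive_class)
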