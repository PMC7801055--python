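"""Pixel-level segmentation metrics: sensitivity, IoU, and Dice.

TP is the intersection of true lesion and predicted lesion area, FP of true
normal and predicted lesion, TN of true normal and predicted normal, FN of
true lesion and predicted normal; the three scores are ratios of those
counts:

    SEN  = TP / (TP + FN)
    IOU  = TP / (TP + FP + FN)
    DICE = 2 TP / (2 TP + FP + FN)

DICE = 2*IOU / (1 + IOU) holds identically. When a denominator is zero the
score is reported as an explicit NaN sentinel together with a ``defined``
flag rather than silently coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError

__all__ = ["ConfusionCounts", "SegmentationScores", "confusion_counts",
           "segmentation_scores", "evaluate_masks"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class SegmentationScores:
    sen: float
    iou: float
    dice: float
    sen_defined: bool = True
    iou_defined: bool = True
    dice_defined: bool = True


def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr.pixels if hasattr(arr, "pixels") else arr)
    vals = np.unique(a)
    if not np.isin(vals, (0, 1, False, True)).all():
        raise ShapeError(f"{name} raster must be binary, found values {vals[:5]}")
    return a.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Tally the four pixel-level intersection cardinalities."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ShapeError(f"pred shape {p.shape} != truth shape {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def segmentation_scores(c: ConfusionCounts) -> SegmentationScores:
    """Derive (SEN, IOU, DICE) from confusion counts."""
    sen_den = c.tp + c.fn
    ov_den = c.tp + c.fp + c.fn
    sen = c.tp / sen_den if sen_den else float("nan")
    iou = c.tp / ov_den if ov_den else float("nan")
    dice = 2 * c.tp / (2 * c.tp + c.fp + c.fn) if ov_den else float("nan")
    return SegmentationScores(sen=sen, iou=iou, dice=dice,
                              sen_defined=sen_den > 0,
                              iou_defined=ov_den > 0,
                              dice_defined=ov_den > 0)


def evaluate_masks(preds, truths, *, average: str = "micro"):
    """Score a set of predicted/true mask pairs for one lesion class.

    micro: pool confusion counts over all images, then compute ratios
    (the default; the count-based definitions aggregate naturally).
    macro: per-image scores averaged over images where they are defined.
    """
    pairs = list(zip(preds, truths))
    if not pairs:
        raise ValueError("evaluate_masks requires at least one pair")
    if average == "micro":
        total = ConfusionCounts(0, 0, 0, 0)
        for p, t in pairs:
            total = total + confusion_counts(p, t)
        return segmentation_scores(total), total
    if average == "macro":
        per = [segmentation_scores(confusion_counts(p, t)) for p, t in pairs]
        def _mean(vals):
            vals = [v for v in vals if not np.isnan(v)]
            return float(np.mean(vals)) if vals else float("nan")
        scores = SegmentationScores(
            sen=_mean([s.sen for s in per]),
            iou=_mean([s.iou for s in per]),
            dice=_mean([s.dice for s in per]),
        )
        return scores, per
    raise ValueError(f"average must be micro|macro, got {average}")
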