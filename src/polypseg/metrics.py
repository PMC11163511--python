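"""Binary segmentation metrics with per-image aggregation.

From the pixel confusion counts of one image,

    Dice = 2TP / (2TP + FP + FN)      IoU  = TP / (TP + FP + FN)
    Prec = TP / (TP + FP)             Rec  = TP / (TP + FN)

mDice/mIoU/etc. are arithmetic means of the per-image values, the usual
protocol on polyp benchmarks.  Degenerate images follow a fixed
convention: if both the prediction and the ground truth are empty every
metric is 1 (the image is segmented perfectly); if exactly one of them
is empty the affected ratios are 0.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

METRIC_NAMES = ("dice", "iou", "precision", "recall")


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies of a binary prediction against a binary mask."""
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"prediction shape {pred.shape} != mask shape {gt.shape}")
    for name, arr in (("prediction", pred), ("ground truth", gt)):
        if not np.all(np.isin(arr, (0, 1))):
            raise ValueError(f"{name} mask must be binary {{0,1}}")
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & gt)), fp=int(np.sum(pred & ~gt)),
        fn=int(np.sum(~pred & gt)), tn=int(np.sum(~pred & ~gt)))


def metrics_from_counts(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(dice, iou, precision, recall) with the degenerate-case convention."""
    if c.tp + c.fp + c.fn == 0:
        return (1.0, 1.0, 1.0, 1.0)
    dice = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    iou = c.tp / (c.tp + c.fp + c.fn)
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    return (dice, iou, precision, recall)


@dataclasses.dataclass
class MetricsReport:
    per_image: list[tuple[float, float, float, float]]
    ids: list[str]

    @property
    def mdice(self) -> float:
        return float(np.mean([m[0] for m in self.per_image]))

    @property
    def miou(self) -> float:
        return float(np.mean([m[1] for m in self.per_image]))

    @property
    def mean_precision(self) -> float:
        return float(np.mean([m[2] for m in self.per_image]))

    @property
    def mean_recall(self) -> float:
        return float(np.mean([m[3] for m in self.per_image]))

    def summary(self) -> dict[str, float]:
        return {"mdice": self.mdice, "miou": self.miou,
                "mean_recall": self.mean_recall,
                "mean_precision": self.mean_precision}

    def to_json(self) -> str:
        return json.dumps({
            "summary": self.summary(),
            "per_image": [dict(zip(("id",) + METRIC_NAMES, (i,) + m))
                          for i, m in zip(self.ids, self.per_image)],
        }, indent=2)

    def to_table(self) -> str:
        """Aligned text table, one row per image plus the mean row."""
        header = f"{'image':<20}" + "".join(f"{n:>11}" for n in METRIC_NAMES)
        lines = [header, "-" * len(header)]
        for pid, m in zip(self.ids, self.per_image):
            lines.append(f"{pid:<20}" + "".join(f"{v:>11.4f}" for v in m))
        lines.append("-" * len(header))
        mean = (self.mdice, self.miou, self.mean_precision, self.mean_recall)
        lines.append(f"{'mean':<20}" + "".join(f"{v:>11.4f}" for v in mean))
        return "\n".join(lines)


def evaluate_dataset(predictions: Sequence[np.ndarray],
                     ground_truths: Sequence[np.ndarray],
                     ids: Sequence[str] | None = None,
                     threshold: float = 0.5) -> MetricsReport:
    """Per-image metrics for probability (or binary) maps vs binary masks."""
    if len(predictions) != len(ground_truths):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(ground_truths)} masks")
    if ids is None:
        ids = [f"image_{i:04d}" for i in range(len(predictions))]
    per_image = []
    for pred, gt in zip(predictions, ground_truths):
        pred = np.asarray(pred)
        mask = (pred >= threshold).astype(np.uint8) \
            if pred.dtype.kind == "f" else pred.astype(np.uint8)
        per_image.append(metrics_from_counts(
            confusion_counts(mask, np.asarray(gt).astype(np.uint8))))
    return MetricsReport(per_image=per_image, ids=list(ids))
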