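"""Dice loss, overlap metrics, confidence intervals and zero-dice accounting.

Definitions (pixelwise, foreground = positive class):

    Acc = (TP + TN) / N
    IoU = TP / (TP + FP + FN)
    DSC = 2 TP / (2 TP + FP + FN) = 2 IoU / (1 + IoU)

The soft dice used as training loss has squared denominators,
D = 2 sum(p g) / (sum(p^2) + sum(g^2)), and the loss is 1 - D.  When both
prediction and reference are empty the dice is taken as 1 by default (a
perfect prediction of "nothing"); slices where the prediction shares no
foreground with a non-empty reference score 0 and are counted as zero-dice
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = [
    "ConfusionCounts", "MetricReport", "dice_coefficient_soft", "dice_loss",
    "dice_loss_tensor", "confusion", "accuracy", "iou", "dsc", "aggregate",
    "zero_dice_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    """Per-sample and aggregated DSC/IoU/accuracy with 1.96-SE half-widths."""

    per_sample: list[tuple[str, float, float, float]]  # (id, dsc, iou, acc)
    mean: dict[str, float]
    half_width: dict[str, float]
    zero_dice_count: int

    @property
    def n(self) -> int:
        return len(self.per_sample)


def _check_probability(pred: np.ndarray):
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("prediction values must lie in [0, 1]")


def dice_coefficient_soft(pred: np.ndarray, gt: np.ndarray,
                          empty_value: float = 1.0) -> float:
    """Soft dice D = 2*sum(p*g) / (sum(p^2) + sum(g^2)); empty/empty -> 1."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    _check_probability(pred)
    denom = float((pred ** 2).sum() + (gt ** 2).sum())
    if denom == 0.0:
        return empty_value
    return float(2.0 * (pred * gt).sum() / denom)


def dice_loss(pred, gt) -> float:
    """1 - soft dice on arrays; see :func:`dice_loss_tensor` for training."""
    return 1.0 - dice_coefficient_soft(pred, gt)


def dice_loss_tensor(pred: Tensor, gt: np.ndarray, eps: float = 1e-7,
                     per_sample: bool = False) -> Tensor:
    """Differentiable dice loss on a probability-map Tensor.

    With ``per_sample`` the dice is computed per leading-axis sample and the
    losses averaged, so small foreground structures are not drowned out by
    empty samples in the same batch.  The small eps keeps the ratio defined
    when both maps are empty (loss 0).
    """
    g = Tensor(np.asarray(gt, dtype=np.float64))
    if per_sample:
        axes = tuple(range(1, pred.ndim))
        num = (pred * g).sum(axis=axes) * 2.0 + eps
        den = (pred * pred).sum(axis=axes) + (g * g).sum(axis=axes) + eps
        return (1.0 - num / den).mean()
    num = (pred * g).sum() * 2.0 + eps
    den = (pred * pred).sum() + (g * g).sum() + eps
    return 1.0 - num / den


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_mask).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.TP + c.TN) / c.total


def iou(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    denom = c.TP + c.FP + c.FN
    if denom == 0:
        return empty_value
    return c.TP / denom


def dsc(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        return empty_value
    return 2 * c.TP / denom


def aggregate(per_sample: list[tuple[str, float, float, float]]) -> MetricReport:
    """Mean and 1.96*SE half-width per metric over samples, plus the number
    of samples with exactly zero dice."""
    if not per_sample:
        raise ValueError("aggregate requires at least one sample")
    arr = np.array([[d, i, a] for _, d, i, a in per_sample], dtype=np.float64)
    names = ("dsc", "iou", "accuracy")
    mean = {k: float(arr[:, j].mean()) for j, k in enumerate(names)}
    n = arr.shape[0]
    if n > 1:
        se = arr.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se = np.zeros(3)
    half = {k: float(1.96 * se[j]) for j, k in enumerate(names)}
    zero = int(np.count_nonzero(arr[:, 0] == 0.0))
    return MetricReport(per_sample=list(per_sample), mean=mean,
                        half_width=half, zero_dice_count=zero)


def zero_dice_table(reports_by_fold: dict[int, MetricReport], network: str = ""):
    """Fold-wise zero-dice accounting: one row per fold with the number of
    evaluated samples and the number scoring exactly zero dice."""
    import pandas as pd

    rows = [{"network": network, "fold": fold, "total_samples": rep.n,
             "zero_dice_samples": rep.zero_dice_count}
            for fold, rep in sorted(reports_by_fold.items())]
    return pd.DataFrame(rows, columns=["network", "fold", "total_samples",
                                       "zero_dice_samples"])
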