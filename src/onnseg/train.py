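"""Training loop, k-fold cross-validation protocol and evaluation driver.

Training minimizes the dice loss on the foreground probability channel with
Adam (betas 0.9/0.999), monitors validation loss, drops the learning rate on
plateau, and stops early, returning the best-validation weights.  Splitting
is always by volume so that no volume's slices leak between train,
validation and test.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor
from .cascade import CascadeConfig, extract_roi, predict_mask, run_cascade
from .ct_preprocess import SlicePair
from .metrics_losses import MetricReport, accuracy, aggregate, confusion, dice_loss_tensor, dsc, iou
from .model_zoo import SegmentationModel

__all__ = ["TrainConfig", "FoldSplit", "TrainResult", "make_folds", "train_model",
           "evaluate_fold", "stage_arrays"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    max_epochs: int = 50
    batch_size: int = 8
    early_stop_patience: int = 10
    lr_drop_factor: float = 0.2
    lr_plateau_patience: int = 6
    min_delta: float = 1e-4  # smallest val-loss drop that counts as improvement
    seed: int = 0
    folds: int = 5

    def __post_init__(self):
        if self.learning_rate < 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")
        if not (0 < self.lr_drop_factor < 1):
            raise ValueError("lr_drop_factor must lie in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be smaller than max_epochs")


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class TrainResult:
    best_state: dict
    best_val_loss: float
    history: dict = field(default_factory=dict)
    steps: int = 0


def make_folds(volume_ids, k: int, seed: int) -> list[FoldSplit]:
    """Deterministic k-fold split by volume: rotating ~20% test blocks, with
    the last 20% (floor) of each fold's remaining volumes as validation."""
    ids = list(volume_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} volumes for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    blocks = np.array_split(np.arange(len(order)), k)
    folds = []
    for f in range(k):
        test = [order[i] for i in blocks[f]]
        remaining = [order[i] for b, blk in enumerate(blocks) if b != f for i in blk]
        n_val = int(np.floor(0.2 * len(remaining)))
        val = remaining[len(remaining) - n_val:]
        train = remaining[: len(remaining) - n_val]
        folds.append(FoldSplit(fold_index=f, train_ids=tuple(train),
                               val_ids=tuple(val), test_ids=tuple(test)))
    return folds


def stage_arrays(pairs: list[SlicePair], stage: str):
    """Model inputs/targets for one cascade stage.

    liver: windowed image -> liver mask.  tumor: ground-truth liver ROI
    (mask-multiplied image) -> tumor mask, matching the protocol of feeding
    the tumor network liver-segmented slices during training.
    """
    if stage == "liver":
        xs = [p.image for p in pairs]
        ys = [p.liver_mask for p in pairs]
    elif stage == "tumor":
        xs = [extract_roi(p.image, p.liver_mask, "multiply") for p in pairs]
        ys = [p.tumor_mask for p in pairs]
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return xs, [np.asarray(y, dtype=np.float64) for y in ys]


_FG = np.array([0.0, 1.0]).reshape(1, 2, 1, 1)


def _foreground(probs: Tensor) -> Tensor:
    return (probs * Tensor(_FG)).sum(axis=1)


def _batch_loss(model: SegmentationModel, xs, ys, idx) -> Tensor:
    batch = np.stack([model.prepare_input(xs[i]) for i in idx])
    target = np.stack([ys[i] for i in idx])
    probs = model(Tensor(batch))
    return dice_loss_tensor(_foreground(probs), target, per_sample=True)


def _validation_loss(model: SegmentationModel, xs, ys, batch_size: int) -> float:
    model.eval()
    losses = []
    for start in range(0, len(xs), batch_size):
        idx = range(start, min(start + batch_size, len(xs)))
        losses.append(_batch_loss(model, xs, ys, idx).item())
    model.train()
    return float(np.mean(losses))


def train_model(model: SegmentationModel, train_pairs: list[SlicePair],
                val_pairs: list[SlicePair], config: TrainConfig,
                stage: str = "liver", max_steps: int | None = None) -> TrainResult:
    """Seeded training with plateau LR drops and early stopping; returns the
    weights of the best-validation epoch."""
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    xs, ys = stage_arrays(train_pairs, stage)
    vxs, vys = stage_arrays(val_pairs, stage)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate, betas=config.betas)
    best_val = np.inf       # tracks the checkpoint to restore (any improvement)
    patience_ref = np.inf   # patience counters require an improvement >= min_delta
    best_state = model.state_dict()
    wait = plateau_wait = steps = 0
    history = {"train_loss": [], "val_loss": [], "lr": []}
    model.train()
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(xs))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = _batch_loss(model, xs, ys, idx)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {steps}: {loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        val_loss = _validation_loss(model, vxs, vys, config.batch_size)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        logger.info("epoch %d: train %.4f val %.4f lr %.2e",
                    epoch, history["train_loss"][-1], val_loss, opt.lr)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
        if val_loss < patience_ref - config.min_delta:
            patience_ref = val_loss
            wait = plateau_wait = 0
        else:
            wait += 1
            plateau_wait += 1
            if plateau_wait >= config.lr_plateau_patience:
                opt.lr *= config.lr_drop_factor
                plateau_wait = 0
        if wait >= config.early_stop_patience:
            break
        if max_steps is not None and steps >= max_steps:
            break
    model.load_state_dict(best_state)
    return TrainResult(best_state=copy.deepcopy(best_state), best_val_loss=float(best_val),
                       history=history, steps=steps)


def _mask_metrics(pred: np.ndarray, gt: np.ndarray):
    c = confusion(pred, gt)
    return dsc(c), iou(c), accuracy(c)


def evaluate_fold(liver_model, tumor_model, test_pairs: list[SlicePair],
                  roi_mode: str = "multiply",
                  constrain_tumor_to_liver: bool = False) -> tuple[MetricReport, MetricReport]:
    """Stage-1 liver metrics and full-cascade tumor metrics on test slices."""
    cfg = CascadeConfig(liver_model=liver_model, tumor_model=tumor_model,
                        roi_mode=roi_mode,
                        constrain_tumor_to_liver=constrain_tumor_to_liver)
    liver_rows, tumor_rows = [], []
    for p in test_pairs:
        sid = f"{p.volume_id}:{p.slice_index}"
        liver_pred = predict_mask(liver_model, p.image)
        liver_rows.append((sid, *_mask_metrics(liver_pred, p.liver_mask)))
        res = run_cascade(p.image, cfg)
        tumor_rows.append((sid, *_mask_metrics(res.tumor_mask, p.tumor_mask)))
    return aggregate(liver_rows), aggregate(tumor_rows)
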