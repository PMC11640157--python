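"""Desk-scale end-to-end experiments on synthetic phantoms.

The cascade smoke experiment trains a tiny Self-ONN U-Net cascade (both
stages) on a handful of 64x64 phantom volumes and evaluates it on a held-out
phantom.  Problem sizes — 4 volumes of 12 slices, <=200 optimizer steps per
stage, ~75k-parameter models — are chosen so the whole experiment runs in
about a minute on one CPU while still exercising preprocessing, both
training stages, the cascade and the metric stack.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cascade import CascadeConfig
from .ct_preprocess import hu_window, rescale_to_255, volume_to_slices
from .metrics_losses import MetricReport
from .model_zoo import (DecoderSpec, EncoderSpec, SegmentationModelSpec,
                        SegmentationModel, build_model)
from .phantom import PhantomConfig, generate_phantom_volume
from .train import TrainConfig, evaluate_fold, train_model

__all__ = ["SmokeResult", "tiny_selfonn_spec", "run_cascade_smoke_experiment"]

SMOKE_PHANTOM = dict(n_volumes=4, slices_per_volume=12, image_size=64,
                     n_tumors_range=(1, 3))
SMOKE_STEPS = {"liver": 120, "tumor": 200}


@dataclass
class SmokeResult:
    liver: MetricReport
    tumor: MetricReport
    liver_model: SegmentationModel
    tumor_model: SegmentationModel


def tiny_selfonn_spec(seed: int, q: int = 3) -> SegmentationModelSpec:
    return SegmentationModelSpec(
        encoder=EncoderSpec(family="tiny", in_channels=1),
        decoder=DecoderSpec(kind="selfonn_unet", decoder_channels=(16, 12, 8, 8, 8), q=q),
        seed=seed,
    )


def run_cascade_smoke_experiment(seed: int) -> SmokeResult:
    """Train both cascade stages on 3 phantom volumes, evaluate on a 4th.

    ``seed`` drives the phantom data, weight initialization and batch order.
    """
    cfg = PhantomConfig(seed=seed, **SMOKE_PHANTOM)
    vols = [generate_phantom_volume(cfg, i) for i in range(cfg.n_volumes)]

    def pairs_of(v, keep_empty=False):
        vol = rescale_to_255(hu_window(v.volume))
        return volume_to_slices(vol, keep_empty=keep_empty)

    train_pairs = [p for v in vols[:3] for p in pairs_of(v)]
    val_pairs = [p for p in pairs_of(vols[2]) if p.tumor_mask.any()] or pairs_of(vols[2])[:6]
    test_pairs = pairs_of(vols[3], keep_empty=True)

    tcfg = TrainConfig(learning_rate=3e-3, batch_size=4, max_epochs=60,
                       early_stop_patience=59, seed=seed)
    liver_model = build_model(tiny_selfonn_spec(seed))
    tumor_model = build_model(tiny_selfonn_spec(seed + 100))
    train_model(liver_model, train_pairs, val_pairs, tcfg, stage="liver",
                max_steps=SMOKE_STEPS["liver"])
    train_model(tumor_model, train_pairs, val_pairs, tcfg, stage="tumor",
                max_steps=SMOKE_STEPS["tumor"])
    liver_rep, tumor_rep = evaluate_fold(liver_model, tumor_model, test_pairs)
    return SmokeResult(liver=liver_rep, tumor=tumor_rep,
                       liver_model=liver_model, tumor_model=tumor_model)
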