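"""Assembled segmentation models: encoder + decoder + two-channel SoftMax head.

Also provides trainable-parameter counting and the calibration utilities that
recover the exact reference configuration of the two Self-ONN U-Net models
(ResNet18 and DenseNet201 encoders) from their published parameter totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .autograd import Tensor
from .decoders import FPNDecoder, UnetDecoder, UnetPPDecoder
from .encoders import ENCODER_FAMILIES, DenseNetEncoder, ResNetEncoder, TinyEncoder

__all__ = [
    "EncoderSpec", "DecoderSpec", "SegmentationModelSpec", "SegmentationModel",
    "build_encoder", "build_decoder", "build_model", "count_parameters",
    "selfonn_unet_parameter_count", "calibrate_selfonn_unet",
    "REFERENCE_DECODER_CHANNELS", "spec_to_yaml", "spec_from_yaml",
    "save_checkpoint", "load_checkpoint",
]

REFERENCE_DECODER_CHANNELS = (256, 128, 64, 32, 16)

_FAMILY_STAGE_CHANNELS = {
    "tiny": [8, 12, 16, 24, 32],
    "resnet18": [64, 64, 128, 256, 512],
    "resnet50": [64, 256, 512, 1024, 2048],
    "resnet101": [64, 256, 512, 1024, 2048],
    "resnet152": [64, 256, 512, 1024, 2048],
    "densenet121": [64, 256, 512, 1024, 1024],
    "densenet161": [96, 384, 768, 2112, 2208],
    "densenet201": [64, 256, 512, 1792, 1920],
}


@dataclass(frozen=True)
class EncoderSpec:
    family: str = "resnet18"
    pretrained: bool = False
    in_channels: int = 3
    stage_channels: tuple[int, ...] = ()

    def __post_init__(self):
        if self.family not in ENCODER_FAMILIES:
            raise ValueError(f"unknown encoder family {self.family!r}; "
                             f"choose from {sorted(ENCODER_FAMILIES)}")
        if not self.stage_channels:
            object.__setattr__(self, "stage_channels",
                               tuple(_FAMILY_STAGE_CHANNELS[self.family]))
        if len(self.stage_channels) != 5:
            raise ValueError("stage_channels must list 5 entries")


@dataclass(frozen=True)
class DecoderSpec:
    kind: str = "unet"
    decoder_channels: tuple[int, ...] = REFERENCE_DECODER_CHANNELS
    q: int = 3
    fpn_segmentation_channels: int = 128
    selfonn_bottleneck_only: bool = False

    def __post_init__(self):
        if self.kind not in ("unet", "unetpp", "fpn", "selfonn_unet"):
            raise ValueError(f"unknown decoder kind {self.kind!r}")
        if any(c < 1 for c in self.decoder_channels):
            raise ValueError("decoder_channels must be strictly positive")
        if self.q < 1:
            raise ValueError("q must be >= 1")


@dataclass(frozen=True)
class SegmentationModelSpec:
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    decoder: DecoderSpec = field(default_factory=DecoderSpec)
    classes: int = 2
    seed: int = 0

    @property
    def input_scaling(self) -> str:
        """Self-ONN decoders expect inputs in [-1, 1]; plain convs get [0, 1]."""
        return "symmetric" if self.decoder.kind == "selfonn_unet" else "unit"


def build_encoder(spec: EncoderSpec, rng: np.random.Generator | None = None,
                  weights_path: str | Path | None = None):
    """Instantiate a multi-scale feature extractor for the given family.

    When ``spec.pretrained`` is true, weights must be supplied as a local
    ``.npz`` state-dict file; no download is ever attempted.
    """
    rng = rng or np.random.default_rng(0)
    family = spec.family
    if family == "tiny":
        enc = TinyEncoder(spec.in_channels, spec.stage_channels, rng=rng)
    elif family.startswith("resnet"):
        enc = ResNetEncoder(family, spec.in_channels, rng=rng)
    else:
        enc = DenseNetEncoder(family, spec.in_channels, rng=rng)
    if list(enc.out_channels) != list(spec.stage_channels):
        raise ValueError(f"stage_channels {spec.stage_channels} inconsistent with "
                         f"family {family} ({enc.out_channels})")
    if spec.pretrained:
        if weights_path is None or not Path(weights_path).exists():
            raise FileNotFoundError(
                f"pretrained weights requested for {family} but no local weights file "
                f"was found at {weights_path!r}; downloads are never attempted")
        state = dict(np.load(weights_path))
        enc.load_state_dict(state)
    return enc


def build_decoder(spec: DecoderSpec, encoder_spec: EncoderSpec,
                  rng: np.random.Generator | None = None, activation=None):
    rng = rng or np.random.default_rng(0)
    ch = list(encoder_spec.stage_channels)
    if spec.kind == "unet":
        return UnetDecoder(ch, spec.decoder_channels, unit_kind="conv",
                           activation=activation, rng=rng)
    if spec.kind == "selfonn_unet":
        return UnetDecoder(ch, spec.decoder_channels, unit_kind="selfonn", q=spec.q,
                           activation=activation,
                           selfonn_bottleneck_only=spec.selfonn_bottleneck_only, rng=rng)
    if spec.kind == "unetpp":
        return UnetPPDecoder(ch, spec.decoder_channels, rng=rng)
    return FPNDecoder(ch, segmentation_channels=spec.fpn_segmentation_channels, rng=rng)


class SegmentationModel(nn.Module):
    """image -> per-pixel 2-class probability map (channel 1 = foreground)."""

    def __init__(self, spec: SegmentationModelSpec):
        super().__init__()
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.encoder = build_encoder(spec.encoder, rng=rng)
        self.decoder = build_decoder(spec.decoder, spec.encoder, rng=rng)
        self.head = nn.Conv2d(self.decoder.out_channels, spec.classes, 1, rng=rng)
        self.softmax = nn.Softmax2d()

    def forward(self, x):
        feats = self.encoder(x)
        y = self.decoder(feats)
        return self.softmax(self.head(y))

    def logits(self, x):
        return self.head(self.decoder(self.encoder(x)))

    # -- inference helpers ----------------------------------------------------
    def prepare_input(self, image: np.ndarray) -> np.ndarray:
        """Scale a [0, 255] image (2-D or CHW) to the model's input range and
        replicate channels to match the encoder."""
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        if self.spec.input_scaling == "symmetric":
            arr = arr / 127.5 - 1.0
        else:
            arr = arr / 255.0
        c_in = self.spec.encoder.in_channels
        if arr.shape[0] == 1 and c_in > 1:
            arr = np.repeat(arr, c_in, axis=0)
        if arr.shape[0] != c_in:
            raise ValueError(f"image has {arr.shape[0]} channels, model expects {c_in}")
        return arr

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Class probabilities (2, H, W) for one [0, 255] image."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(Tensor(self.prepare_input(image)[None]))
        finally:
            self.train(was_training)
        return out.data[0]


def build_model(spec: SegmentationModelSpec) -> SegmentationModel:
    return SegmentationModel(spec)


def count_parameters(module: nn.Module) -> int:
    """Number of trainable scalar parameters."""
    return int(sum(p.data.size for p in module.parameters()))


# ---------------------------------------------------------------------------
# Closed-form Self-ONN U-Net parameter count + reference-config calibration
# ---------------------------------------------------------------------------

_ENCODER_COUNT_CACHE: dict[str, int] = {}


def encoder_parameter_count(family: str) -> int:
    if family not in _ENCODER_COUNT_CACHE:
        _ENCODER_COUNT_CACHE[family] = count_parameters(
            build_encoder(EncoderSpec(family=family)))
    return _ENCODER_COUNT_CACHE[family]


def selfonn_unet_decoder_parameter_count(stage_channels, decoder_channels, q) -> int:
    """Closed form mirroring UnetDecoder with Self-ONN units (bias, no norm)
    and the 1x1 two-channel head."""
    c1, c2, c3, c4, c5 = stage_channels
    d = list(decoder_channels)
    ins = [c5 + c4, d[0] + c3, d[1] + c2, d[2] + c1, d[3]]
    total = 0
    for i in range(5):
        total += q * 9 * ins[i] * d[i] + d[i]       # unit1: 3x3 Self-ONN + bias
        total += q * 9 * d[i] * d[i] + d[i]          # unit2
    total += 2 * d[4] + 2                            # 1x1 head, 2 classes
    return total


def selfonn_unet_parameter_count(family: str, decoder_channels, q: int) -> int:
    return encoder_parameter_count(family) + selfonn_unet_decoder_parameter_count(
        _FAMILY_STAGE_CHANNELS[family], decoder_channels, q)


def calibrate_selfonn_unet(targets: dict[str, int],
                           nominal=REFERENCE_DECODER_CHANNELS,
                           max_width: int = 1024):
    """Find (q, decoder_channels) whose Self-ONN U-Net totals match the given
    per-encoder-family parameter targets exactly.

    The decoder widths are the only free architectural parameters the printed
    totals constrain, so the search space is the Taylor order q and the five
    decoder channel counts.  Search order prefers q closest to the default 3,
    then widths with the smallest L1 distance to the nominal configuration,
    which makes the result deterministic.  Returns (q, widths) or None.
    """
    fams = sorted(targets)
    if len(fams) != 2:
        raise ValueError("calibration needs exactly two encoder families")
    fa, fb = fams
    sa = _FAMILY_STAGE_CHANNELS[fa]
    sb = _FAMILY_STAGE_CHANNELS[fb]
    resid = {f: targets[f] - encoder_parameter_count(f) for f in fams}
    # decoder totals differ only through the skip-facing unit1 layers:
    # diff = 9q * [ (headA+skipA1 - headB-skipB1) d1 + (skipA2-skipB2) d2 + ... ]
    coeff = [sa[4] + sa[3] - sb[4] - sb[3], sa[2] - sb[2], sa[1] - sb[1], sa[0] - sb[0]]
    diff = resid[fa] - resid[fb]
    best = None
    for q in sorted(range(1, 8), key=lambda v: (abs(v - 3), v)):
        if diff % (9 * q):
            continue
        r = diff // (9 * q)
        solutions = _solve_widths(q, r, coeff, resid[fa], sa, max_width)
        if solutions:
            best = min(solutions, key=lambda d: (sum(abs(x - y) for x, y in zip(d, nominal)), d))
            return q, tuple(best)
    return best


def _solve_widths(q, r, coeff, target_a, stage_a, max_width):
    """Enumerate decoder widths (d1..d5) satisfying both the between-family
    difference equation and family A's exact total."""
    a1, a2, a3, a4 = coeff
    if a4 != 0:
        raise NotImplementedError("stride-2 skip channels expected to match")
    c1, c2, c3, c4, c5 = stage_a
    sols = []
    d4_grid = np.arange(1, max_width + 1, dtype=np.int64)
    for d1 in range(1, max_width + 1):
        rem1 = r - a1 * d1
        if rem1 <= 0:
            break
        for d2 in range(1, min(max_width, rem1 // a2 if a2 else max_width) + 1):
            rem2 = rem1 - a2 * d2
            if rem2 <= 0 or rem2 % a3:
                continue
            d3 = rem2 // a3
            if d3 > max_width:
                continue
            fixed = (9 * q * ((c5 + c4) * d1 + d1 * d1 + (d1 + c3) * d2 + d2 * d2
                              + (d2 + c2) * d3 + d3 * d3)
                     + 2 * (d1 + d2 + d3) + 2)
            # remaining unknowns: unit1/unit2 of blocks 4, 5 and the head
            c0 = fixed + 9 * q * ((d3 + c1) * d4_grid + d4_grid * d4_grid) \
                + 2 * d4_grid - target_a
            bq = 9 * q * d4_grid + 4  # d5 coefficient: unit1 of b5 + biases + head
            disc = bq * bq - 4 * (9 * q) * c0
            ok = disc >= 0
            root = np.zeros_like(disc)
            root[ok] = np.sqrt(disc[ok].astype(np.float64)).astype(np.int64)
            for rr in (root - 1, root, root + 1):
                hits = ok & (rr * rr == disc) & ((rr - bq) % (18 * q) == 0)
                for idx in np.nonzero(hits)[0]:
                    d5 = int((rr[idx] - bq[idx]) // (18 * q))
                    if 1 <= d5 <= max_width:
                        d = (d1, d2, int(d3), int(d4_grid[idx]), d5)
                        if selfonn_unet_decoder_parameter_count(stage_a, d, q) == target_a + 0:
                            sols.append(d)
    return sols


# ---------------------------------------------------------------------------
# YAML serialization and checkpoints
# ---------------------------------------------------------------------------

def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def spec_to_yaml(spec: SegmentationModelSpec) -> str:
    return yaml.safe_dump(_listify(asdict(spec)), sort_keys=False)


def spec_from_yaml(text: str) -> SegmentationModelSpec:
    raw = yaml.safe_load(text)
    enc = raw.get("encoder", {})
    dec = raw.get("decoder", {})
    return SegmentationModelSpec(
        encoder=EncoderSpec(
            family=enc.get("family", "resnet18"),
            pretrained=enc.get("pretrained", False),
            in_channels=enc.get("in_channels", 3),
            stage_channels=tuple(enc.get("stage_channels") or ()),
        ),
        decoder=DecoderSpec(
            kind=dec.get("kind", "unet"),
            decoder_channels=tuple(dec.get("decoder_channels", REFERENCE_DECODER_CHANNELS)),
            q=dec.get("q", 3),
            fpn_segmentation_channels=dec.get("fpn_segmentation_channels", 128),
            selfonn_bottleneck_only=dec.get("selfonn_bottleneck_only", False),
        ),
        classes=raw.get("classes", 2),
        seed=raw.get("seed", 0),
    )


def save_checkpoint(path: str | Path, model: SegmentationModel) -> None:
    state = model.state_dict()
    np.savez(path, __spec__=np.frombuffer(
        json.dumps(_listify(asdict(model.spec))).encode(), dtype=np.uint8),
        **state)


def load_checkpoint(path: str | Path) -> SegmentationModel:
    data = np.load(path)
    raw = json.loads(bytes(data["__spec__"]).decode())
    model = build_model(spec_from_yaml(yaml.safe_dump(raw)))
    model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return model
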