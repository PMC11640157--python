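"""Two-stage inference: liver segmentation -> ROI extraction -> tumor segmentation.

The first model produces a binary liver mask from a windowed CT slice; the
mask is placed over the image (elementwise product by default) to form the
liver region of interest, which the second model searches for tumor.  Both
stage models only need a ``predict_proba(image) -> (2, H, W)`` method, so
trained networks and test oracles are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .ct_preprocess import CTVolume

__all__ = [
    "SliceModel", "CascadeConfig", "CascadeResult", "CascadeVolumeResult",
    "predict_mask", "extract_roi", "run_cascade", "run_cascade_volume",
]


class SliceModel(Protocol):
    def predict_proba(self, image: np.ndarray) -> np.ndarray: ...


@dataclass
class CascadeConfig:
    liver_model: SliceModel
    tumor_model: SliceModel
    roi_mode: str = "multiply"
    constrain_tumor_to_liver: bool = False

    def __post_init__(self):
        if self.roi_mode not in ("multiply", "concat_channel"):
            raise ValueError(f"roi_mode must be 'multiply' or 'concat_channel', "
                             f"got {self.roi_mode!r}")


@dataclass
class CascadeResult:
    liver_mask: np.ndarray
    roi_image: np.ndarray
    tumor_mask: np.ndarray


@dataclass
class CascadeVolumeResult:
    slices: list[CascadeResult]
    liver_volume: np.ndarray
    tumor_volume: np.ndarray


def predict_mask(model: SliceModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the two-channel SoftMax output.

    Exact 0.5/0.5 ties resolve to background (conservative for lesion calls).
    """
    probs = np.asarray(model.predict_proba(image))
    if probs.ndim != 3 or probs.shape[0] != 2:
        raise ValueError(f"expected (2, H, W) probabilities, got {probs.shape}")
    if probs.shape[1:] != np.asarray(image).shape[-2:]:
        raise ValueError(f"probability map {probs.shape[1:]} does not match "
                         f"image {np.asarray(image).shape[-2:]}")
    return (probs[1] > probs[0]).astype(np.uint8)


def extract_roi(image: np.ndarray, liver_mask: np.ndarray, roi_mode: str = "multiply") -> np.ndarray:
    """multiply: elementwise image*mask; concat_channel: stack (image, mask)."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(liver_mask)
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    if roi_mode == "multiply":
        return image * mask
    if roi_mode == "concat_channel":
        return np.stack([image, mask.astype(np.float64)], axis=0)
    raise ValueError(f"unknown roi_mode {roi_mode!r}")


def run_cascade(image: np.ndarray, config: CascadeConfig) -> CascadeResult:
    """Liver mask -> ROI -> tumor mask on one [0, 255] slice."""
    liver = predict_mask(config.liver_model, image)
    roi = extract_roi(image, liver, config.roi_mode)
    tumor = predict_mask(config.tumor_model, roi)
    if config.constrain_tumor_to_liver:
        tumor = (tumor & liver).astype(np.uint8)
    return CascadeResult(liver_mask=liver, roi_image=roi, tumor_mask=tumor)


def run_cascade_volume(volume: CTVolume, config: CascadeConfig) -> CascadeVolumeResult:
    """Apply the cascade slice-by-slice and reassemble 3-D masks.

    The volume is expected already windowed and rescaled to [0, 255].
    """
    results = []
    liver_vol = np.zeros(volume.voxels.shape, dtype=np.uint8)
    tumor_vol = np.zeros(volume.voxels.shape, dtype=np.uint8)
    for k in range(volume.n_slices):
        res = run_cascade(np.asarray(volume.voxels[:, :, k], dtype=np.float64), config)
        results.append(res)
        liver_vol[:, :, k] = res.liver_mask
        tumor_vol[:, :, k] = res.tumor_mask
    return CascadeVolumeResult(slices=results, liver_volume=liver_vol, tumor_volume=tumor_vol)
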