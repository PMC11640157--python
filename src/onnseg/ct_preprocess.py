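"""CT volume I/O, Hounsfield-unit windowing and 3-D -> 2-D slice extraction.

The pipeline follows the usual abdominal-CT preparation for liver work:
voxels are clipped to the liver window [-100, 400] HU, linearly rescaled to
[0, 255], and the volume is cut into axial slices.  Labels use the LiTS
convention: 0 background, 1 liver, 2 tumor (tumor voxels are liver tissue,
so the liver mask is labels in {1, 2}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CTVolume", "SlicePair", "load_nifti", "save_nifti",
    "hu_window", "rescale_to_255", "volume_to_slices", "build_manifest",
    "HU_WINDOW_DEFAULT",
]

logger = logging.getLogger(__name__)

HU_WINDOW_DEFAULT = (-100.0, 400.0)
VALID_LABELS = frozenset({0, 1, 2})


@dataclass
class CTVolume:
    """A 3-D HU array with spacing/affine and an optional label array."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    labels: np.ndarray | None = None
    volume_id: str = "volume"

    def __post_init__(self):
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if self.labels is not None:
            if self.labels.shape != self.voxels.shape:
                raise ValueError(f"labels shape {self.labels.shape} != voxels "
                                 f"shape {self.voxels.shape}")
            self.validate_labels()
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing entries must be positive")

    def validate_labels(self):
        vals = set(np.unique(self.labels).tolist())
        if not vals <= VALID_LABELS:
            raise ValueError(f"labels contain values outside {{0,1,2}}: {sorted(vals)}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]  # axial axis = third array axis


@dataclass
class SlicePair:
    """One axial slice with its liver and tumor masks, image in [0, 255]."""

    image: np.ndarray
    liver_mask: np.ndarray
    tumor_mask: np.ndarray
    volume_id: str
    slice_index: int


def load_nifti(path: str | Path, labels_path: str | Path | None = None) -> CTVolume:
    """Load a .nii/.nii.gz volume (and optionally its segmentation) as stored,
    without reorientation."""
    path = Path(path)
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj)
    if voxels.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D image, got {voxels.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    labels = None
    if labels_path is not None:
        seg = nib.load(str(labels_path))
        labels = np.asarray(seg.dataobj).astype(np.int16)
        if labels.ndim != 3:
            raise ValueError("segmentation must be 3-D")
    return CTVolume(voxels=voxels, spacing=tuple(float(z) for z in zooms),
                    affine=np.asarray(img.affine), labels=labels,
                    volume_id=path.name.split(".")[0])


def save_nifti(volume: CTVolume, path: str | Path,
               labels_path: str | Path | None = None) -> None:
    nib.save(nib.Nifti1Image(volume.voxels, volume.affine), str(path))
    if labels_path is not None:
        if volume.labels is None:
            raise ValueError("volume has no labels to save")
        nib.save(nib.Nifti1Image(volume.labels.astype(np.uint8), volume.affine),
                 str(labels_path))


def hu_window(volume: CTVolume, lo: float = HU_WINDOW_DEFAULT[0],
              hi: float = HU_WINDOW_DEFAULT[1]) -> CTVolume:
    """Clip voxels to the [lo, hi] HU window; labels untouched.  Idempotent."""
    if lo >= hi:
        raise ValueError(f"degenerate window: lo={lo} >= hi={hi}")
    return replace(volume, voxels=np.clip(volume.voxels, lo, hi))


def rescale_to_255(volume: CTVolume, lo: float = HU_WINDOW_DEFAULT[0],
                   hi: float = HU_WINDOW_DEFAULT[1], as_uint8: bool = False) -> CTVolume:
    """Map [lo, hi] linearly onto [0, 255].

    Real-valued by default; with ``as_uint8`` values are rounded half away
    from zero and stored as uint8.
    """
    if lo >= hi:
        raise ValueError(f"degenerate window: lo={lo} >= hi={hi}")
    scaled = 255.0 * (volume.voxels - lo) / (hi - lo)
    if as_uint8:
        scaled = np.floor(scaled + 0.5).astype(np.uint8)
    return replace(volume, voxels=scaled)


def volume_to_slices(volume: CTVolume, keep_empty: bool = False) -> list[SlicePair]:
    """Cut a labelled volume into axial SlicePairs in index order.

    With ``keep_empty=False``, slices whose liver mask is empty are dropped
    (the kept/dropped counts are logged).
    """
    if volume.labels is None:
        raise ValueError("volume has no labels; masks cannot be derived")
    volume.validate_labels()
    pairs = []
    dropped = 0
    for k in range(volume.n_slices):
        img = np.asarray(volume.voxels[:, :, k], dtype=np.float64)
        lab = volume.labels[:, :, k]
        liver = (lab > 0)
        tumor = (lab == 2)
        if not keep_empty and not liver.any():
            dropped += 1
            continue
        pairs.append(SlicePair(image=img, liver_mask=liver.astype(np.uint8),
                               tumor_mask=tumor.astype(np.uint8),
                               volume_id=volume.volume_id, slice_index=k))
    logger.info("volume %s: kept %d slices, dropped %d liver-empty slices",
                volume.volume_id, len(pairs), dropped)
    return pairs


def build_manifest(pairs: list[SlicePair]) -> pd.DataFrame:
    rows = [{
        "volume_id": p.volume_id,
        "slice_index": p.slice_index,
        "has_liver": bool(p.liver_mask.any()),
        "has_tumor": bool(p.tumor_mask.any()),
    } for p in pairs]
    return pd.DataFrame(rows, columns=["volume_id", "slice_index", "has_liver", "has_tumor"])
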