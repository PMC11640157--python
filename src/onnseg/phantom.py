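"""Synthetic abdominal-CT phantoms with liver and tumor labels.

Each phantom volume mimics the structure of a contrast-CT liver study: a
smooth elliptical "liver" occupying a consecutive run of axial slices, with
zero or more hypodense spherical "tumors" strictly inside it, on a soft-
tissue background, plus additive Gaussian HU noise.  The label volume uses
the LiTS convention (0/1/2) and is noiseless.  The phantoms are deliberately
easy — high contrast and smooth shapes — because they exist to validate the
machinery, not to emulate clinical difficulty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .ct_preprocess import CTVolume, save_nifti

__all__ = ["PhantomConfig", "PhantomVolume", "generate_phantom_volume", "generate_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    seed: int = 0
    n_volumes: int = 4
    slices_per_volume: int = 16
    image_size: int = 64
    liver_hu_range: tuple[float, float] = (50.0, 70.0)
    tumor_hu_range: tuple[float, float] = (10.0, 40.0)
    background_hu: float = -80.0
    n_tumors_range: tuple[int, int] = (0, 3)
    tumor_radius_range: tuple[float, float] = (4.0, 9.0)  # mm
    noise_sd: float = 8.0

    def __post_init__(self):
        if self.image_size < 64 or self.image_size % 32:
            raise ValueError("image_size must be >= 64 and divisible by 32")
        if self.tumor_hu_range[1] >= self.liver_hu_range[0]:
            raise ValueError("tumor HU range must lie strictly below the liver range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class PhantomVolume:
    volume: CTVolume
    config: PhantomConfig
    volume_index: int


def _liver_masks(rng: np.random.Generator, cfg: PhantomConfig) -> np.ndarray:
    """Per-slice elliptical liver masks on a consecutive slice run, with axes
    varying smoothly across slices."""
    n, s = cfg.slices_per_volume, cfg.image_size
    run = rng.integers(max(3, n // 2), n + 1)
    start = rng.integers(0, n - run + 1)
    cx, cy = rng.uniform(0.35 * s, 0.65 * s, 2)
    a0 = rng.uniform(0.22 * s, 0.32 * s)
    b0 = rng.uniform(0.16 * s, 0.26 * s)
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:s, 0:s]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    masks = np.zeros((s, s, n), dtype=bool)
    for j in range(run):
        # smooth waxing/waning of the cross-section along the run
        frac = np.sin(np.pi * (j + 0.5) / run)
        scale = 0.45 + 0.55 * frac
        masks[:, :, start + j] = (u / (a0 * scale)) ** 2 + (v / (b0 * scale)) ** 2 <= 1.0
    return masks


def generate_phantom_volume(config: PhantomConfig, volume_index: int,
                            max_attempts: int = 25) -> PhantomVolume:
    """Deterministic phantom: fully determined by (config.seed, volume_index)."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(volume_index,))
    rng = np.random.default_rng(ss)
    s, n = config.image_size, config.slices_per_volume
    liver = _liver_masks(rng, config)
    labels = liver.astype(np.int16)

    n_tumors = int(rng.integers(config.n_tumors_range[0], config.n_tumors_range[1] + 1))
    spacing = (1.0, 1.0, 2.5)  # anisotropic voxels, in-plane mm vs slice thickness
    # distance to the liver boundary in millimetres, so spherical (in mm)
    # tumors stay strictly inside the liver despite the thick slices
    dist = ndimage.distance_transform_edt(liver, sampling=spacing)
    zz, yy, xx = np.mgrid[0:s, 0:s, 0:n]
    margin = max(spacing) + 0.1  # at least one voxel of liver in every direction
    for _ in range(n_tumors):
        placed = False
        for _attempt in range(max_attempts):
            r = rng.uniform(*config.tumor_radius_range)
            candidates = np.argwhere(dist > r + margin)
            if candidates.size == 0:
                continue
            cz, cy, ct_ = candidates[rng.integers(len(candidates))]
            ball = ((zz - cz) * spacing[0]) ** 2 + ((yy - cy) * spacing[1]) ** 2 \
                + ((xx - ct_) * spacing[2]) ** 2 <= r ** 2
            labels[ball] = 2
            placed = True
            break
        if not placed and config.tumor_radius_range[0] > dist.max():
            raise ValueError("tumor radius range infeasible for the generated liver")

    hu = np.full((s, s, n), config.background_hu, dtype=np.float64)
    hu[liver] = rng.uniform(*config.liver_hu_range)
    hu[labels == 2] = rng.uniform(*config.tumor_hu_range)
    hu += rng.normal(0.0, config.noise_sd, hu.shape)
    affine = np.diag([*spacing, 1.0])
    vol = CTVolume(voxels=hu.astype(np.float32), spacing=spacing, affine=affine,
                   labels=labels.astype(np.uint8), volume_id=f"volume-{volume_index}")
    return PhantomVolume(volume=vol, config=config, volume_index=volume_index)


def generate_dataset(config: PhantomConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write LiTS-style volume-i/segmentation-i NIfTI pairs plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(config.n_volumes):
        pv = generate_phantom_volume(config, i)
        vol_path = out_dir / f"volume-{i}.nii.gz"
        seg_path = out_dir / f"segmentation-{i}.nii.gz"
        save_nifti(pv.volume, vol_path, seg_path)
        rows.append({
            "volume_id": pv.volume.volume_id,
            "volume_path": vol_path.name,
            "segmentation_path": seg_path.name,
            "n_slices": config.slices_per_volume,
            "n_tumor_voxels": int((pv.volume.labels == 2).sum()),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
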