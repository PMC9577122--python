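"""Slide tiling: tissue masking, sliding-window patch extraction,
color normalization, and training-time augmentation.

Coordinates are 0-based and half-open throughout. The default grid uses
224-pixel patches with 1/3 overlap, i.e. a stride of floor(224 * 2/3) =
149 pixels along both axes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage.color import rgb2hsv

from wsirisk._random import substream
from wsirisk.synthetic import AnnotationRegion

__all__ = [
    "TilingConfig",
    "Patch",
    "tissue_mask",
    "extract_patches",
    "normalize_patch",
    "augment_patch",
    "label_patches",
    "grid_positions",
    "save_patch_set",
    "load_patch_set",
    "NORMALIZE_TARGET_MEAN",
    "NORMALIZE_TARGET_STD",
]

#: Reference per-channel statistics (8-bit scale) for color normalization.
NORMALIZE_TARGET_MEAN = np.array([180.0, 150.0, 160.0])
NORMALIZE_TARGET_STD = np.array([35.0, 35.0, 35.0])


class FormatError(ValueError):
    """Raised for malformed image or patch input."""


@dataclass(frozen=True)
class TilingConfig:
    patch_size: int = 224
    overlap: float = 1.0 / 3.0
    background_rgb_min: int = 220
    background_patch_fraction: float = 0.5
    marker_saturation_min: float = 0.7
    #: HSV hue windows (fractions of the circle) treated as marker ink.
    marker_hue_windows: tuple[tuple[float, float], ...] = (
        (0.20, 0.45),  # green ink
        (0.50, 0.75),  # blue ink
    )

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")

    @property
    def stride(self) -> int:
        return max(int(math.floor(self.patch_size * (1.0 - self.overlap))), 1)


@dataclass
class Patch:
    slide_id: str
    origin: tuple[int, int]  # (x, y) top-left
    pixels: np.ndarray  # (patch_size, patch_size, 3)
    annotation_class: str | None = None


def _check_rgb(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise FormatError(f"expected 8-bit image, got dtype {image.dtype}")


def tissue_mask(image: np.ndarray, config: TilingConfig = TilingConfig()) -> np.ndarray:
    """Boolean mask, True where a pixel is tissue.

    A pixel is background when all channels reach `background_rgb_min`;
    it is marker ink when its HSV saturation reaches
    `marker_saturation_min` with hue inside one of the marker windows.
    Everything else is tissue.
    """
    _check_rgb(image)
    background = np.all(image >= config.background_rgb_min, axis=2)
    hsv = rgb2hsv(image)
    marker = hsv[..., 1] >= config.marker_saturation_min
    in_window = np.zeros(image.shape[:2], dtype=bool)
    for lo, hi in config.marker_hue_windows:
        in_window |= (hsv[..., 0] >= lo) & (hsv[..., 0] <= hi)
    return ~(background | (marker & in_window))


def grid_positions(extent: int, patch_size: int, stride: int) -> list[int]:
    """Window origins: multiples of stride with origin + patch_size <= extent."""
    if extent < patch_size:
        return []
    return list(range(0, extent - patch_size + 1, stride))


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    config: TilingConfig = TilingConfig(),
    slide_id: str = "",
) -> list[Patch]:
    """Sliding-window patches over the tissue grid, row-major by origin.

    Patches whose background fraction (per `mask`) exceeds
    `background_patch_fraction` are dropped. `mask=None` computes the
    tissue mask from the image.
    """
    _check_rgb(image)
    if mask is None:
        mask = tissue_mask(image, config)
    if mask.shape != image.shape[:2]:
        raise FormatError("mask shape does not match image")
    h, w = image.shape[:2]
    ps = config.patch_size
    if h < ps or w < ps:
        warnings.warn(
            f"image {w}x{h} smaller than patch size {ps}; no patches extracted",
            stacklevel=2,
        )
        return []
    patches = []
    area = ps * ps
    for y in grid_positions(h, ps, config.stride):
        for x in grid_positions(w, ps, config.stride):
            window = mask[y : y + ps, x : x + ps]
            background_fraction = 1.0 - window.sum() / area
            if background_fraction > config.background_patch_fraction:
                continue
            patches.append(
                Patch(
                    slide_id=slide_id,
                    origin=(x, y),
                    pixels=image[y : y + ps, x : x + ps].copy(),
                )
            )
    return patches


def label_patches(
    patches: Iterable[Patch], regions: Sequence[AnnotationRegion]
) -> list[Patch]:
    """Assign `annotation_class` to patches fully contained in a region.

    Patches straddling region boundaries (or outside every region) keep
    annotation_class None and are excluded from training.
    """
    out = []
    for patch in patches:
        x, y = patch.origin
        ps = patch.pixels.shape[0]
        for region in regions:
            x0, y0, x1, y1 = region.box
            if x >= x0 and y >= y0 and x + ps <= x1 and y + ps <= y1:
                patch.annotation_class = region.class_label
                break
        out.append(patch)
    return out


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Per-channel affine map to the reference mean/std (8-bit scale).

    Returns float64. Idempotent up to float tolerance; a zero-variance
    channel is centered to the target mean without scaling.
    """
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise FormatError(f"expected (H, W, 3) patch, got shape {patch.shape}")
    x = patch.astype(np.float64)
    mean = x.mean(axis=(0, 1))
    std = x.std(axis=(0, 1))
    out = np.empty_like(x)
    for c in range(3):
        if std[c] < 1e-12:
            out[..., c] = x[..., c] - mean[c] + NORMALIZE_TARGET_MEAN[c]
        else:
            out[..., c] = (x[..., c] - mean[c]) / std[c] * NORMALIZE_TARGET_STD[
                c
            ] + NORMALIZE_TARGET_MEAN[c]
    return out


@dataclass(frozen=True)
class AugmentConfig:
    brightness: float = 0.1
    contrast: float = 0.1
    saturation: float = 0.1
    flips: bool = True
    rotations: bool = True


def augment_patch(
    patch: np.ndarray, seed: int, config: AugmentConfig = AugmentConfig()
) -> np.ndarray:
    """Seeded flip / 90-degree rotation / color jitter; shape- and
    dtype-preserving; the same seed reproduces the same output."""
    rng = substream(seed, "augment")
    x = patch.astype(np.float64)
    if config.flips:
        if rng.random() < 0.5:
            x = x[:, ::-1]
        if rng.random() < 0.5:
            x = x[::-1, :]
    if config.rotations:
        x = np.rot90(x, k=int(rng.integers(0, 4)))
    # Jitter factors drawn even when ranges are zero, to keep the stream
    # layout stable across configs.
    b = rng.uniform(1.0 - config.brightness, 1.0 + config.brightness)
    c = rng.uniform(1.0 - config.contrast, 1.0 + config.contrast)
    s = rng.uniform(1.0 - config.saturation, 1.0 + config.saturation)
    x = x * b
    mean = x.mean()
    x = (x - mean) * c + mean
    gray = x.mean(axis=2, keepdims=True)
    x = gray + (x - gray) * s
    x = np.ascontiguousarray(x)
    if np.issubdtype(patch.dtype, np.integer):
        info = np.iinfo(patch.dtype)
        return np.clip(np.rint(x), info.min, info.max).astype(patch.dtype)
    return x.astype(patch.dtype)


# ---------------------------------------------------------------------------
# Patch-set persistence: a directory of PNGs plus a CSV index.


def save_patch_set(patches: Sequence[Patch], out_dir) -> Path:
    import pandas as pd
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, patch in enumerate(patches):
        name = f"patch_{i:06d}.png"
        Image.fromarray(patch.pixels).save(out_dir / name)
        rows.append(
            {
                "file": name,
                "slide_id": patch.slide_id,
                "x": patch.origin[0],
                "y": patch.origin[1],
                "class": patch.annotation_class if patch.annotation_class else "",
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "index.csv", index=False)
    return out_dir


def load_patch_set(in_dir) -> list[Patch]:
    import pandas as pd
    from PIL import Image

    in_dir = Path(in_dir)
    index = pd.read_csv(in_dir / "index.csv", keep_default_na=False).rename(
        columns={"class": "cls"}
    )
    patches = []
    for row in index.itertuples(index=False):
        pixels = np.asarray(Image.open(in_dir / row.file).convert("RGB"))
        patches.append(
            Patch(
                slide_id=row.slide_id,
                origin=(int(row.x), int(row.y)),
                pixels=pixels,
                annotation_class=row.cls or None,
            )
        )
    return patches
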