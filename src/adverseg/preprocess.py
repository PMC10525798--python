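"""Image enhancement, resizing, paired geometric augmentation and noise.

CLAHE and bilinear resizing are delegated to scikit-image; nearest-neighbor
label resizing and the paired affine transform are implemented here so the
coordinate conventions (0-based, row-major, center-aligned) are explicit and
identical for image and mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

from .errors import ShapeError, ValidationError

__all__ = [
    "ClaheParams",
    "AugmentParams",
    "apply_clahe",
    "resize_to",
    "augment_pair",
    "apply_affine_pair",
    "add_gaussian_noise",
]


@dataclass(frozen=True)
class ClaheParams:
    """clip_limit follows the common 0-255-histogram convention (default 2.0);
    tile_grid is the number of contextual tiles (rows, cols)."""

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)

    def validate(self) -> None:
        if self.clip_limit <= 0:
            raise ValidationError(
                f"clip_limit must be > 0, got {self.clip_limit}", "clip_limit"
            )
        if any(t < 1 for t in self.tile_grid):
            raise ValidationError(
                f"tile counts must be >= 1, got {self.tile_grid}", "tile_grid"
            )


@dataclass(frozen=True)
class AugmentParams:
    """Sampling ranges for the paired affine augmentation.

    Flips default to off: left/right lungs are distinct labels and a flip
    would silently swap them.
    """

    rotation_degrees: tuple[float, float] = (-15.0, 15.0)
    translation: tuple[float, float] = (-0.10, 0.10)  # fraction of the side
    scale: tuple[float, float] = (0.9, 1.1)
    horizontal_flip: float = 0.0
    apply_probability: float = 1.0

    def validate(self) -> None:
        for name in ("rotation_degrees", "translation", "scale"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValidationError(f"invalid range ({lo}, {hi})", name)
        for name in ("horizontal_flip", "apply_probability"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability {p} outside [0, 1]", name)

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(rotation_degrees=(0, 0), translation=(0, 0), scale=(1, 1),
                   horizontal_flip=0.0, apply_probability=1.0)


def apply_clahe(image: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] grid."""
    params = params or ClaheParams()
    params.validate()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError(f"expected an H×W grid, got shape {image.shape}")
    if image.max() - image.min() == 0:
        # degenerate single-bin histogram: equalization cannot separate
        # equal values; return the input unchanged
        return image.copy()
    h, w = image.shape
    kernel = (max(1, h // params.tile_grid[0]), max(1, w // params.tile_grid[1]))
    # map the 0-255-histogram clip limit onto skimage's [0, 1] convention
    out = exposure.equalize_adapthist(
        np.clip(image, 0.0, 1.0), kernel_size=kernel,
        clip_limit=params.clip_limit / 256.0, nbins=256,
    )
    return np.clip(out, 0.0, 1.0)


def _nearest_indices(n_out: int, n_in: int) -> np.ndarray:
    # center-aligned sampling: src = floor((dst + 0.5) * n_in / n_out)
    idx = np.floor((np.arange(n_out) + 0.5) * n_in / n_out).astype(np.intp)
    return np.clip(idx, 0, n_in - 1)


def resize_to(grid: np.ndarray, side: int, is_mask: bool = False) -> np.ndarray:
    """Resize to ``side``×``side``: bilinear for images, nearest for masks."""
    if side < 8:
        raise ValidationError(f"target side must be >= 8, got {side}", "side")
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ShapeError(f"expected an H×W grid, got shape {grid.shape}")
    if grid.shape == (side, side):
        return grid.copy()
    if is_mask:
        rows = _nearest_indices(side, grid.shape[0])
        cols = _nearest_indices(side, grid.shape[1])
        return grid[np.ix_(rows, cols)]
    out = transform.resize(
        grid.astype(np.float64), (side, side), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def apply_affine_pair(
    image: np.ndarray,
    mask: np.ndarray,
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
    flip: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one spatial transform to an (image, mask) pair.

    Rotation is about the grid center ``((H-1)/2, (W-1)/2)``; a +90° rotation
    of a square grid moves pixel (r, c) to (c, H-1-r) exactly. Translation is
    in output pixels (row, col). Out-of-canvas regions are filled with
    intensity 0 / label 0. Image is interpolated bilinearly, mask by nearest.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ShapeError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    theta = np.deg2rad(rotation_deg)
    # inverse map: in = R @ (out - center - t) / s + center
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # exact multiples of 90° must map gridpoints to gridpoints exactly
    if abs(rotation_deg) % 90 == 0:
        cos_t, sin_t = round(cos_t), round(sin_t)
    rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]])
    if flip:
        rot = rot @ np.diag([1.0, -1.0])
    matrix = rot / scale
    center = (np.array(image.shape, dtype=np.float64) - 1.0) / 2.0
    offset = center - matrix @ (center + np.asarray(translation, dtype=np.float64))
    img_out = ndimage.affine_transform(
        image, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )
    msk_out = ndimage.affine_transform(
        mask, matrix, offset=offset, order=0, mode="constant", cval=0
    )
    return np.clip(img_out, 0.0, 1.0), msk_out.astype(mask.dtype)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    params: AugmentParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one transform from ``params`` and apply it to both arrays."""
    params = params or AugmentParams()
    params.validate()
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ShapeError(f"image shape {image.shape} != mask shape {mask.shape}")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if rng.random() >= params.apply_probability:
        return image.copy(), mask.copy()
    rot = rng.uniform(*params.rotation_degrees)
    h, w = image.shape
    t = (
        rng.uniform(*params.translation) * h,
        rng.uniform(*params.translation) * w,
    )
    scale = rng.uniform(*params.scale)
    flip = bool(rng.random() < params.horizontal_flip)
    return apply_affine_pair(image, mask, rot, t, scale, flip)


def add_gaussian_noise(arr: np.ndarray, sigma: float, seed: int | np.random.Generator):
    """Add i.i.d. zero-mean Gaussian noise element-wise, then clip to [0, 1]."""
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}", "sigma")
    arr = np.asarray(arr, dtype=np.float64)
    if sigma == 0:
        return arr.copy()
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    return np.clip(arr + rng.normal(0.0, sigma, size=arr.shape), 0.0, 1.0)
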