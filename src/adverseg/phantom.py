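"""Synthetic chest-radiograph-like phantoms with exact multi-organ ground truth.

A phantom is a low-contrast torso on a smooth intensity gradient with two
bright elliptical lung fields and a heart ellipse occluding the medial-inferior
zone of the left lung (occlusion order: heart over lungs), plus optional rib
intensity bands and additive Gaussian noise. The label mask is a deterministic
function of the geometry alone; noise only perturbs intensities.

Labels follow :data:`adverseg.dataio.MULTI_SCHEME`:
0 background, 1 left lung, 2 right lung, 3 heart.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from .dataio import MULTI_SCHEME, DatasetManifest, write_image, write_mask
from .errors import ValidationError

__all__ = ["PhantomSpec", "render_phantom", "generate_dataset", "jitter_spec"]

BACKGROUND, LEFT_LUNG, RIGHT_LUNG, HEART = 0, 1, 2, 3

_BASE_INTENSITY = 0.35
_TORSO_OFFSET = 0.08


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and rendering parameters of one phantom.

    Centers are (row, col) pixels, axes are (semi-row, semi-col) pixels.
    ``organ_contrasts`` are mean intensity offsets (left lung, right lung,
    heart) in [-1, 1] relative to the local background.
    """

    height: int = 64
    width: int = 64
    lung_centers: tuple[tuple[float, float], tuple[float, float]] = ((29.0, 19.0), (29.0, 45.0))
    lung_axes: tuple[tuple[float, float], tuple[float, float]] = ((18.0, 11.0), (18.0, 11.0))
    heart_center: tuple[float, float] = (42.0, 27.0)
    heart_axes: tuple[float, float] = (12.0, 10.0)
    organ_contrasts: tuple[float, float, float] = (0.30, 0.30, 0.22)
    background_gradient_amplitude: float = 0.08
    noise_sigma: float = 0.02
    rib_band_count: int = 0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValidationError("image must be at least 8×8", "height")
        centers = list(self.lung_centers) + [self.heart_center]
        names = ["lung_centers[0]", "lung_centers[1]", "heart_center"]
        for name, (r, c) in zip(names, centers):
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise ValidationError(f"center ({r}, {c}) lies outside the image", name)
        axes = list(self.lung_axes) + [self.heart_axes]
        names = ["lung_axes[0]", "lung_axes[1]", "heart_axes"]
        for name, (a, b) in zip(names, axes):
            if a <= 0 or b <= 0:
                raise ValidationError(f"semi-axes ({a}, {b}) must be > 0", name)
        for v in self.organ_contrasts:
            if not (-1.0 <= v <= 1.0):
                raise ValidationError(
                    f"contrast {v} outside [-1, 1]", "organ_contrasts"
                )
        if self.noise_sigma < 0:
            raise ValidationError(
                f"noise_sigma must be >= 0, got {self.noise_sigma}", "noise_sigma"
            )
        if self.rib_band_count < 0:
            raise ValidationError(
                f"rib_band_count must be >= 0, got {self.rib_band_count}",
                "rib_band_count",
            )

    @classmethod
    def default_for(cls, height: int, width: int) -> "PhantomSpec":
        """Scale the 64×64 default geometry to another resolution."""
        sr, sc = height / 64.0, width / 64.0
        d = cls()
        sc_pt = lambda p: (p[0] * sr, p[1] * sc)
        return replace(
            d,
            height=height,
            width=width,
            lung_centers=(sc_pt(d.lung_centers[0]), sc_pt(d.lung_centers[1])),
            lung_axes=(sc_pt(d.lung_axes[0]), sc_pt(d.lung_axes[1])),
            heart_center=sc_pt(d.heart_center),
            heart_axes=sc_pt(d.heart_axes),
        )


def _ellipse_interior(rr, cc, center, axes):
    dr = (rr - center[0]) / axes[0]
    dc = (cc - center[1]) / axes[1]
    return dr * dr + dc * dc <= 1.0


def render_mask(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the label mask (geometry only; heart occludes lungs)."""
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    mask[_ellipse_interior(rr, cc, spec.lung_centers[0], spec.lung_axes[0])] = LEFT_LUNG
    mask[_ellipse_interior(rr, cc, spec.lung_centers[1], spec.lung_axes[1])] = RIGHT_LUNG
    mask[_ellipse_interior(rr, cc, spec.heart_center, spec.heart_axes)] = HEART
    return mask


def heart_lung_overlap_pixels(spec: PhantomSpec) -> int:
    """Number of rasterized pixels where the heart occludes a lung field."""
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    lung = _ellipse_interior(rr, cc, spec.lung_centers[0], spec.lung_axes[0])
    lung |= _ellipse_interior(rr, cc, spec.lung_centers[1], spec.lung_axes[1])
    heart = _ellipse_interior(rr, cc, spec.heart_center, spec.heart_axes)
    return int((lung & heart).sum())


def render_phantom(spec: PhantomSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom. Returns ``(image, mask)``.

    The image is float64 in [0, 1]; the mask is uint8 with labels
    {0 background, 1 left lung, 2 right lung, 3 heart}. Identical
    ``(spec, seed)`` gives bit-identical output.
    """
    spec.validate()
    h, w = spec.height, spec.width
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    mask = render_mask(spec)

    # smooth diagonal gradient + soft torso ellipse = the "local background"
    amp = spec.background_gradient_amplitude
    bg = _BASE_INTENSITY + amp * (0.6 * rr / max(h - 1, 1) + 0.4 * cc / max(w - 1, 1) - 0.5)
    torso_q = ((rr - 0.55 * h) / (0.52 * h)) ** 2 + ((cc - 0.5 * w) / (0.44 * w)) ** 2
    bg = bg + _TORSO_OFFSET / (1.0 + np.exp(12.0 * (torso_q - 1.0)))

    offsets = np.array([0.0, *spec.organ_contrasts], dtype=np.float64)
    img = bg + offsets[mask]

    if spec.rib_band_count > 0:
        # faint horizontal bands inside the lung fields only; amplitude kept
        # well under half the lung contrast so interior contrast survives
        rib_amp = 0.2 * min(abs(spec.organ_contrasts[0]), abs(spec.organ_contrasts[1]))
        bands = rib_amp * np.sin(2.0 * np.pi * spec.rib_band_count * rr / h)
        lungs = (mask == LEFT_LUNG) | (mask == RIGHT_LUNG)
        img = img + np.where(lungs, bands, 0.0)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    return np.clip(img, 0.0, 1.0), mask


def jitter_spec(spec: PhantomSpec, jitter: float, rng: np.random.Generator) -> PhantomSpec:
    """Perturb centers, axes and contrasts by up to ±jitter (fractional)."""
    if jitter == 0:
        return spec

    def frac(x):
        return x * (1.0 + rng.uniform(-jitter, jitter))

    def pt(p, lo_r, hi_r, lo_c, hi_c):
        return (
            float(np.clip(frac(p[0]), lo_r, hi_r)),
            float(np.clip(frac(p[1]), lo_c, hi_c)),
        )

    h, w = spec.height, spec.width
    return replace(
        spec,
        lung_centers=(
            pt(spec.lung_centers[0], 0, h - 1, 0, w - 1),
            pt(spec.lung_centers[1], 0, h - 1, 0, w - 1),
        ),
        lung_axes=(
            (max(frac(spec.lung_axes[0][0]), 2.0), max(frac(spec.lung_axes[0][1]), 2.0)),
            (max(frac(spec.lung_axes[1][0]), 2.0), max(frac(spec.lung_axes[1][1]), 2.0)),
        ),
        heart_center=pt(spec.heart_center, 0, h - 1, 0, w - 1),
        heart_axes=(max(frac(spec.heart_axes[0]), 2.0), max(frac(spec.heart_axes[1]), 2.0)),
        organ_contrasts=tuple(
            float(np.clip(frac(v), -1.0, 1.0)) for v in spec.organ_contrasts
        ),
    )


def generate_dataset(
    n: int,
    spec: PhantomSpec,
    jitter: float,
    seed: int,
    out_dir,
) -> DatasetManifest:
    """Render ``n`` phantoms to PNG pairs under ``out_dir`` plus a manifest.

    Per-sample randomness comes from the substream ``default_rng([seed, i])``
    so sample ``i`` is reproducible independently of the others.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}", "n")
    if not (0.0 <= jitter < 0.5):
        raise ValidationError(f"jitter must lie in [0, 0.5), got {jitter}", "jitter")
    spec.validate()

    os.makedirs(out_dir, exist_ok=True)
    img_dir = os.path.join(out_dir, "images")
    msk_dir = os.path.join(out_dir, "masks")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(msk_dir, exist_ok=True)

    records = []
    width = max(4, len(str(n - 1)))
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        spec_i = jitter_spec(spec, jitter, rng)
        # the render seed is drawn from the same substream
        img, mask = render_phantom(spec_i, int(rng.integers(0, 2**31 - 1)))
        img_path = os.path.join(img_dir, f"img_{i:0{width}d}.png")
        msk_path = os.path.join(msk_dir, f"mask_{i:0{width}d}.png")
        write_image(img_path, img)
        write_mask(msk_path, mask, MULTI_SCHEME)
        records.append((img_path, msk_path))

    manifest = DatasetManifest(records=records, scheme=MULTI_SCHEME.name)
    manifest.write(os.path.join(out_dir, "manifest.csv"))
    return manifest
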