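"""Image/mask PNG I/O, color-coded label schemes, manifests and dataset splits.

Conventions
-----------
* Pixel coordinates are 0-based, row-major ``(row, col)``.
* Grayscale images are ``float64`` arrays in ``[0, 1]`` (an *ImageGrid*).
* Label masks are small-integer arrays; label 0 is always background.
* Mask PNGs use exact, saturated RGB codes (no tolerance on decode):
  blue = left lung, green = right lung, red = heart, black = background.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .errors import ShapeError, UnknownColorError, UnsupportedImageError, ValidationError

__all__ = [
    "LabelScheme",
    "MULTI_SCHEME",
    "BINARY_SCHEME",
    "get_scheme",
    "DatasetManifest",
    "read_image",
    "write_image",
    "decode_mask",
    "encode_mask",
    "read_mask",
    "write_mask",
    "split_dataset",
    "mask_to_binary",
]

MANIFEST_HEADER = "image_path,mask_path"


@dataclass(frozen=True)
class LabelScheme:
    """Ordered label list with one display color per label.

    Label indices are positions in ``labels``; background must be index 0.
    """

    name: str
    labels: tuple[str, ...]
    colors: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        if len(self.labels) != len(self.colors):
            raise ValidationError("labels and colors must have equal length", "colors")
        if self.labels[0] != "background":
            raise ValidationError("label 0 must be 'background'", "labels")
        if len(set(self.colors)) != len(self.colors):
            raise ValidationError("colors must be pairwise distinct", "colors")
        for c in self.colors:
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ValidationError(f"invalid RGB triple {c}", "colors")

    @property
    def num_labels(self) -> int:
        return len(self.labels)

    def color_array(self) -> np.ndarray:
        return np.asarray(self.colors, dtype=np.uint8)


MULTI_SCHEME = LabelScheme(
    name="multi",
    labels=("background", "left_lung", "right_lung", "heart"),
    colors=((0, 0, 0), (0, 0, 255), (0, 255, 0), (255, 0, 0)),
)

BINARY_SCHEME = LabelScheme(
    name="binary",
    labels=("background", "lung"),
    colors=((0, 0, 0), (255, 255, 255)),
)

_SCHEMES = {s.name: s for s in (MULTI_SCHEME, BINARY_SCHEME)}


def get_scheme(name: str) -> LabelScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ValidationError(
            f"unknown label scheme {name!r}; available: {sorted(_SCHEMES)}", "scheme"
        ) from None


def mask_to_binary(mask: np.ndarray) -> np.ndarray:
    """Collapse a multi-organ mask to the binary scheme (lung vs background).

    Left and right lung become label 1; the heart is not lung and maps to 0.
    """
    mask = np.asarray(mask)
    return ((mask == 1) | (mask == 2)).astype(mask.dtype)


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------


def read_image(path, with_depth: bool = False):
    """Read a PNG as a float grid in [0, 1].

    8-/16-bit grayscale is accepted directly; RGB(A) is converted to
    luminance with the Rec. 601 weights (0.299, 0.587, 0.114).

    With ``with_depth=True`` returns ``(grid, bit_depth)``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"image not found: {path}")
    with Image.open(path) as im:
        mode = im.mode
        if mode in ("L", "P"):
            arr = np.asarray(im.convert("L"), dtype=np.float64)
            depth = 8
            grid = arr / 255.0
        elif mode in ("I;16", "I;16B", "I;16L"):
            arr = np.asarray(im, dtype=np.float64)
            depth = 16
            grid = arr / 65535.0
        elif mode in ("RGB", "RGBA"):
            arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
            depth = 8
            grid = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
        else:
            raise UnsupportedImageError(
                f"unsupported image mode {mode!r} in {path}; expected 8/16-bit "
                "grayscale or RGB PNG"
            )
    grid = np.clip(grid, 0.0, 1.0)
    return (grid, depth) if with_depth else grid


def write_image(path, grid: np.ndarray) -> None:
    """Write a [0, 1] grid as an 8-bit grayscale PNG."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2:
        raise ShapeError(f"expected an H×W grid, got shape {grid.shape}")
    arr = np.rint(np.clip(grid, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


# ---------------------------------------------------------------------------
# mask codec
# ---------------------------------------------------------------------------


def encode_mask(mask: np.ndarray, scheme: LabelScheme) -> np.ndarray:
    """Encode integer labels into an H×W×3 uint8 array with exact scheme colors."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ShapeError(f"expected an H×W mask, got shape {mask.shape}")
    if mask.size and (mask.min() < 0 or mask.max() >= scheme.num_labels):
        bad = int(mask.max() if mask.max() >= scheme.num_labels else mask.min())
        raise ValidationError(
            f"label {bad} outside scheme {scheme.name!r} range 0..{scheme.num_labels - 1}",
            "mask",
        )
    return scheme.color_array()[mask.astype(np.intp)]


def decode_mask(rgb, scheme: LabelScheme) -> np.ndarray:
    """Decode an RGB mask (H×W×3 array or PNG path) into integer labels.

    Any pixel whose color is not exactly in the scheme raises
    :class:`UnknownColorError` naming the color and the first offending pixel.
    """
    if isinstance(rgb, (str, os.PathLike)):
        with Image.open(rgb) as im:
            rgb = np.asarray(im.convert("RGB"))
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ShapeError(f"expected an H×W×3 RGB array, got shape {rgb.shape}")
    colors = scheme.color_array().astype(np.int32)
    match = (rgb[..., None, :].astype(np.int32) == colors).all(axis=-1)  # H,W,L
    known = match.any(axis=-1)
    if not known.all():
        r, c = np.argwhere(~known)[0]
        raise UnknownColorError(rgb[r, c], (r, c))
    return match.argmax(axis=-1).astype(np.uint8)


def write_mask(path, mask: np.ndarray, scheme: LabelScheme) -> None:
    Image.fromarray(encode_mask(mask, scheme), mode="RGB").save(path, format="PNG")


def read_mask(path, scheme: LabelScheme) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"mask not found: {path}")
    return decode_mask(path, scheme)


# ---------------------------------------------------------------------------
# manifests and splits
# ---------------------------------------------------------------------------


@dataclass
class DatasetManifest:
    """Ordered (image_path, mask_path) records plus the label-scheme name."""

    records: list[tuple[str, str]] = field(default_factory=list)
    scheme: str = "multi"

    def __post_init__(self):
        images = [r[0] for r in self.records]
        if len(set(images)) != len(images):
            dup = sorted({p for p in images if images.count(p) > 1})[0]
            raise ValidationError(f"duplicate image_path {dup!r}", "records")
        for rec in self.records:
            if len(rec) != 2 or not rec[0] or not rec[1]:
                raise ValidationError(f"record {rec!r} must carry both paths", "records")

    def __len__(self) -> int:
        return len(self.records)

    def write(self, path) -> None:
        """Write as comma-separated text, paths relative to the manifest dir."""
        base = os.path.dirname(os.path.abspath(path))
        lines = [MANIFEST_HEADER]
        for img, msk in self.records:
            lines.append(
                f"{os.path.relpath(os.path.abspath(img), base)},"
                f"{os.path.relpath(os.path.abspath(msk), base)}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path, scheme: str = "multi") -> "DatasetManifest":
        if not os.path.exists(path):
            raise FileNotFoundError(f"manifest not found: {path}")
        base = os.path.dirname(os.path.abspath(path))
        records = []
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if not lines or lines[0] != MANIFEST_HEADER:
            raise ValidationError(
                f"manifest must start with header {MANIFEST_HEADER!r}", "manifest"
            )
        for ln in lines[1:]:
            parts = ln.split(",")
            if len(parts) != 2:
                raise ValidationError(f"malformed manifest line {ln!r}", "manifest")
            records.append(
                (os.path.join(base, parts[0]), os.path.join(base, parts[1]))
            )
        return cls(records=records, scheme=scheme)


def split_dataset(
    manifest: DatasetManifest, train_frac: float, seed: int
) -> tuple[DatasetManifest, DatasetManifest]:
    """Seeded uniform split; train size is floor(train_frac * n)."""
    if not (0.0 < train_frac < 1.0):
        raise ValidationError(
            f"train_frac must lie strictly in (0, 1), got {train_frac}", "train_frac"
        )
    n = len(manifest)
    if n == 0:
        raise ValidationError("manifest is empty", "manifest")
    n_train = math.floor(train_frac * n)
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = sorted(perm[:n_train].tolist())
    test_idx = sorted(perm[n_train:].tolist())
    mk = lambda idx: DatasetManifest(
        records=[manifest.records[i] for i in idx], scheme=manifest.scheme
    )
    return mk(train_idx), mk(test_idx)
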