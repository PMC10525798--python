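"""SE-gated residual U-Net generator emitting per-pixel label probabilities.

Layout per encoder level: [3×3 conv + nonlinearity] ×2 → squeeze-and-excitation
channel gate → residual add of the 1×1-projected block input → 2×2 max-pool.
Decoder levels mirror this with nearest-neighbor 2× upsampling followed by a
3×3 conv, concatenation of the matching encoder skip, and the same block. The
head adds the last decoder features to a 1×1-projected copy of the input,
applies the nonlinearity, projects to ``num_labels`` with a 1×1 conv and
normalizes per pixel with a softmax.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import autograd.numpy as anp
import numpy as np

from . import nn
from .errors import ShapeError, ValidationError

__all__ = ["GeneratorConfig", "Generator", "build_generator", "se_gate", "generator_forward"]

_ACTIVATIONS = {"relu": nn.relu, "leaky_relu": nn.leaky_relu}


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 1
    num_labels: int = 4
    base_filters: int = 64
    depth: int = 4
    se_reduction: int = 16
    activation: str = "relu"

    def validate(self) -> None:
        if self.depth < 1:
            raise ValidationError(f"depth must be >= 1, got {self.depth}", "depth")
        if self.base_filters < 1:
            raise ValidationError(
                f"base_filters must be >= 1, got {self.base_filters}", "base_filters"
            )
        if not (1 <= self.se_reduction <= self.base_filters):
            raise ValidationError(
                f"se_reduction must lie in [1, base_filters], got {self.se_reduction}",
                "se_reduction",
            )
        if self.in_channels < 1 or self.num_labels < 2:
            raise ValidationError(
                "need in_channels >= 1 and num_labels >= 2", "num_labels"
            )
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(
                f"unknown activation {self.activation!r}", "activation"
            )


def se_gate(x, p):
    """Squeeze-and-excitation: pooled descriptor → bottleneck → sigmoid gates."""
    s = anp.mean(x, axis=(1, 2))  # (B, C)
    h = nn.relu(nn.dense(s, p["w1"], p["b1"]))
    g = nn.sigmoid(nn.dense(h, p["w2"], p["b2"]))  # (B, C), gates in (0, 1)
    return x * g[:, None, None, :]


def _init_se(rng, channels, reduction, dtype):
    hidden = max(1, channels // reduction)
    d1 = nn.he_dense(rng, channels, hidden, dtype)
    d2 = nn.he_dense(rng, hidden, channels, dtype)
    return {"w1": d1["W"], "b1": d1["b"], "w2": d2["W"], "b2": d2["b"]}


def _init_block(rng, cin, cout, reduction, dtype):
    return {
        "c1": nn.he_conv(rng, 3, cin, cout, dtype),
        "c2": nn.he_conv(rng, 3, cout, cout, dtype),
        "se": _init_se(rng, cout, reduction, dtype),
        "proj": nn.he_conv(rng, 1, cin, cout, dtype),
    }


def _block(x, p, act):
    h = act(nn.conv3x3(x, p["c1"]["W"], p["c1"]["b"]))
    h = act(nn.conv3x3(h, p["c2"]["W"], p["c2"]["b"]))
    h = se_gate(h, p["se"])
    return h + nn.conv1x1(x, p["proj"]["W"], p["proj"]["b"])


class Generator:
    """Parameterized map from image batches to probability-map batches."""

    def __init__(self, config: GeneratorConfig, params):
        self.config = config
        self.params = params

    def forward(self, x, params=None):
        """``x``: (B, H, W) or (B, H, W, in_channels) → (B, H, W, num_labels)."""
        params = self.params if params is None else params
        cfg = self.config
        x = x if hasattr(x, "_value") or isinstance(x, anp.ndarray) else anp.asarray(x)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4 or x.shape[-1] != cfg.in_channels:
            raise ShapeError(
                f"expected (B, H, W, {cfg.in_channels}) input, got shape {x.shape}"
            )
        div = 2**cfg.depth
        if x.shape[1] % div or x.shape[2] % div:
            raise ShapeError(
                f"input sides {x.shape[1]}×{x.shape[2]} must be divisible by "
                f"2^depth = {div}"
            )
        act = _ACTIVATIONS[cfg.activation]
        skips = []
        h = x
        for lvl in range(cfg.depth):
            h = _block(h, params["enc"][lvl], act)
            skips.append(h)
            h = nn.maxpool2(h)
        h = _block(h, params["bottleneck"], act)
        for lvl in reversed(range(cfg.depth)):
            p = params["dec"][lvl]
            h = act(nn.conv3x3(nn.upsample2(h), p["up"]["W"], p["up"]["b"]))
            h = anp.concatenate([h, skips[lvl]], axis=-1)
            h = _block(h, p["block"], act)
        head = params["head"]
        feat = act(h + nn.conv1x1(x, head["proj"]["W"], head["proj"]["b"]))
        logits = nn.conv1x1(feat, head["out"]["W"], head["out"]["b"])
        return nn.softmax_channels(logits)

    def config_dict(self) -> dict:
        return asdict(self.config)


def build_generator(
    config: GeneratorConfig, seed: int, dtype=np.float64
) -> Generator:
    """Seeded parameter initialization; identical (config, seed) is bit-identical."""
    config.validate()
    rng = np.random.default_rng(seed)
    f, d, r = config.base_filters, config.depth, config.se_reduction
    enc = []
    cin = config.in_channels
    for lvl in range(d):
        cout = f * 2**lvl
        enc.append(_init_block(rng, cin, cout, r, dtype))
        cin = cout
    bottleneck = _init_block(rng, cin, f * 2**d, r, dtype)
    dec = [None] * d
    cin = f * 2**d
    for lvl in reversed(range(d)):
        cout = f * 2**lvl
        dec[lvl] = {
            "up": nn.he_conv(rng, 3, cin, cout, dtype),
            "block": _init_block(rng, 2 * cout, cout, r, dtype),
        }
        cin = cout
    head = {
        "proj": nn.he_conv(rng, 1, config.in_channels, f, dtype),
        "out": nn.he_conv(rng, 1, f, config.num_labels, dtype),
    }
    params = {"enc": enc, "bottleneck": bottleneck, "dec": dec, "head": head}
    return Generator(config, params)


def generator_forward(g: Generator, batch) -> np.ndarray:
    """Functional alias for :meth:`Generator.forward` on plain arrays."""
    return g.forward(np.asarray(batch))
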