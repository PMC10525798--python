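"""Convolutional WGAN critic scoring (image, mask) pairs with one real scalar.

Per stage: [3×3 conv → normalization → leaky nonlinearity] ×2 → 2×2 max-pool;
after the configured number of stages the features are flattened into a single
fully connected unit with no output squashing (no sigmoid, no log anywhere).

The default is conditional: the input image is concatenated with the mask
probability channels. Layer normalization is the default because batch
normalization couples the samples of a batch and conflicts with the
per-sample gradient penalty; ``norm_kind="batch"`` stays available.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import autograd.numpy as anp
import numpy as np

from . import nn
from .errors import ShapeError, ValidationError

__all__ = ["CriticConfig", "Critic", "build_critic", "critic_score"]

_NORM_KINDS = ("layer", "batch", "none")


@dataclass(frozen=True)
class CriticConfig:
    in_channels: int = 5  # image (1) + num_labels (4) in conditional mode
    base_filters: int = 64
    stages: int = 4
    input_side: int = 64
    norm_kind: str = "layer"
    leaky_slope: float = 0.2
    conditional: bool = True

    def validate(self) -> None:
        if self.stages < 1:
            raise ValidationError(f"stages must be >= 1, got {self.stages}", "stages")
        if self.base_filters < 1:
            raise ValidationError(
                f"base_filters must be >= 1, got {self.base_filters}", "base_filters"
            )
        if self.input_side % 2**self.stages:
            raise ValidationError(
                f"input_side {self.input_side} must be divisible by "
                f"2^stages = {2**self.stages}",
                "input_side",
            )
        if self.norm_kind not in _NORM_KINDS:
            raise ValidationError(
                f"norm_kind must be one of {_NORM_KINDS}, got {self.norm_kind!r}",
                "norm_kind",
            )
        if self.in_channels < 1:
            raise ValidationError(
                f"in_channels must be >= 1, got {self.in_channels}", "in_channels"
            )


class Critic:
    def __init__(self, config: CriticConfig, params):
        self.config = config
        self.params = params

    # -- input assembly ----------------------------------------------------
    def make_input(self, image, mask_channels):
        """Concatenate image and mask channels (conditional) or masks only.

        ``image``: (B, H, W) or (B, H, W, 1); ``mask_channels``: (B, H, W, L)
        one-hot for real masks or soft probabilities for generated ones —
        both enter through the same interface.
        """
        image = np.asarray(image)
        if image.ndim == 3:
            image = image[..., None]
        if self.config.conditional:
            return anp.concatenate([image, mask_channels], axis=-1)
        return mask_channels

    # -- scoring -----------------------------------------------------------
    def score_input(self, params, x):
        """Score a pre-assembled (B, H, W, C_in) input; returns (B,) scalars."""
        cfg = self.config
        if x.ndim != 4 or x.shape[-1] != cfg.in_channels:
            raise ShapeError(
                f"expected (B, H, W, {cfg.in_channels}) input, got shape "
                f"{tuple(x.shape)}"
            )
        if x.shape[1] != cfg.input_side or x.shape[2] != cfg.input_side:
            raise ShapeError(
                f"expected spatial side {cfg.input_side}, got "
                f"{x.shape[1]}×{x.shape[2]}"
            )
        slope = cfg.leaky_slope
        h = x
        for stage in params["stages"]:
            for layer in (stage["l1"], stage["l2"]):
                h = nn.conv3x3(h, layer["conv"]["W"], layer["conv"]["b"])
                if cfg.norm_kind == "layer":
                    h = nn.layer_norm(h, layer["norm"]["g"], layer["norm"]["b"])
                elif cfg.norm_kind == "batch":
                    h = nn.batch_norm(h, layer["norm"]["g"], layer["norm"]["b"])
                h = nn.leaky_relu(h, slope)
            h = nn.maxpool2(h)
        flat = anp.reshape(h, (h.shape[0], -1))
        out = nn.dense(flat, params["fc"]["W"], params["fc"]["b"])
        return anp.reshape(out, (-1,))

    def score(self, image, mask_channels, params=None):
        params = self.params if params is None else params
        return self.score_input(params, self.make_input(image, mask_channels))

    def config_dict(self) -> dict:
        return asdict(self.config)


def build_critic(config: CriticConfig, seed: int, dtype=np.float64) -> Critic:
    """Seeded initialization; identical (config, seed) is bit-identical."""
    config.validate()
    rng = np.random.default_rng(seed)
    f = config.base_filters
    stages = []
    cin = config.in_channels
    for s in range(config.stages):
        cout = f * 2**s
        def layer(ci, co):
            return {
                "conv": nn.he_conv(rng, 3, ci, co, dtype),
                "norm": {
                    "g": np.ones(co, dtype=dtype),
                    "b": np.zeros(co, dtype=dtype),
                },
            }
        stages.append({"l1": layer(cin, cout), "l2": layer(cout, cout)})
        cin = cout
    side = config.input_side // 2**config.stages
    fan_in = side * side * cin
    fc = nn.he_dense(rng, fan_in, 1, dtype)
    fc["W"] = (fc["W"] * np.sqrt(0.5)).astype(dtype)  # Xavier-ish head
    return Critic(config, {"stages": stages, "fc": fc})


def critic_score(c: Critic, image, mask_or_probmaps) -> np.ndarray:
    """Score a batch of (image, mask) pairs with the critic's own parameters."""
    return c.score(image, mask_or_probmaps)
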