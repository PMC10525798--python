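"""Minimal array-network toolkit on top of HIPS autograd.

All layers are pure functions on channels-last batches ``(B, H, W, C)`` with
parameters held in nested dicts/lists of ndarrays, so autograd can
differentiate arbitrary compositions — including the second-order term needed
by the gradient penalty (a gradient of a gradient norm).

Only what the generator and critic need is provided; this is deliberately not
a general framework.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.misc import flatten
from autograd.tracer import getval

__all__ = [
    "conv3x3",
    "conv1x1",
    "dense",
    "maxpool2",
    "upsample2",
    "relu",
    "leaky_relu",
    "sigmoid",
    "softmax_channels",
    "layer_norm",
    "batch_norm",
    "Adam",
    "tree_map",
    "tree_equal",
    "flatten_tree",
    "unflatten_like",
    "param_count",
]

# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


# 3×3 'same' correlation as a custom primitive: autograd's slice VJPs
# accumulate with np.add.at, which dominates runtime; here every VJP is
# itself expressed through the same primitives, so gradients of any order
# stay matmul-bound.


@primitive
def _corr3x3(x, W):
    """(B, H, W, Cin) ⋆ (3, 3, Cin, Cout) with zero 'same' padding."""
    B, H, Wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.zeros((B, H, Wd, W.shape[-1]), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            out += xp[:, di : di + H, dj : dj + Wd, :] @ W[di, dj]
    return out


@primitive
def _corr3x3_wgrad(x, g):
    """dW[di,dj,ci,co] = Σ_bhw pad(x)[b,h+di,w+dj,ci] · g[b,h,w,co]."""
    B, H, Wd, Ci = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.empty((3, 3, Ci, g.shape[-1]), dtype=x.dtype)
    gf = g.reshape(-1, g.shape[-1])
    for di in range(3):
        for dj in range(3):
            patch = xp[:, di : di + H, dj : dj + Wd, :].reshape(-1, Ci)
            out[di, dj] = patch.T @ gf
    return out


def _flip_t(W):
    # spatially flipped, channel-transposed kernel (transposed correlation)
    return anp.transpose(W[::-1, ::-1], (0, 1, 3, 2))


defvjp(
    _corr3x3,
    lambda ans, x, W: lambda g: _corr3x3(g, _flip_t(W)),
    lambda ans, x, W: lambda g: _corr3x3_wgrad(x, g),
)

defvjp(
    _corr3x3_wgrad,
    lambda ans, x, g: lambda u: _corr3x3(g, _flip_t(u)),
    lambda ans, x, g: lambda u: _corr3x3(x, u),
)


def conv3x3(x, W, b):
    """'Same'-padded 3×3 convolution; ``W`` is (3, 3, C_in, C_out)."""
    return _corr3x3(x, W) + b


def conv1x1(x, W, b):
    """Pointwise channel projection; ``W`` is (C_in, C_out)."""
    return anp.matmul(x, W) + b


def dense(x, W, b):
    return anp.matmul(x, W) + b


@primitive
def _maxpool2(x):
    B, H, W, C = x.shape
    return x.reshape(B, H // 2, 2, W // 2, 2, C).max(axis=(2, 4))


def _upsample2_plain(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _maxpool2_vjp(ans, x):
    # route gradient to the block maxima (ties share equally); the selection
    # pattern is locally constant, so treating it as such is exact a.e.
    xv, av = getval(x), getval(ans)
    hit = (xv == _upsample2_plain(av)).astype(xv.dtype)
    B, H, W, C = xv.shape
    counts = hit.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))
    weight = hit / _upsample2_plain(counts)
    return lambda g: upsample2(g) * weight


defvjp(_maxpool2, _maxpool2_vjp)


def maxpool2(x):
    """2×2 max pooling with stride 2 (requires even spatial sides)."""
    return _maxpool2(x)


def upsample2(x):
    """Nearest-neighbor 2× upsampling."""
    return anp.repeat(anp.repeat(x, 2, axis=1), 2, axis=2)


def relu(x):
    return anp.maximum(x, 0.0)


def leaky_relu(x, slope=0.2):
    return anp.where(x > 0, x, slope * x)


@primitive
def sigmoid(x):
    # tanh form is stable at both tails; the vjp below avoids cosh overflow
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


defvjp(sigmoid, lambda ans, x: lambda g: g * ans * (1.0 - ans))


def softmax_channels(x):
    """Per-pixel softmax over the last (channel) axis."""
    z = x - anp.max(x, axis=-1, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=-1, keepdims=True)


def layer_norm(x, gain, bias, eps=1e-5):
    """Per-sample normalization over all non-batch axes, per-channel affine."""
    m = anp.mean(x, axis=(1, 2, 3), keepdims=True)
    v = anp.mean((x - m) ** 2, axis=(1, 2, 3), keepdims=True)
    return (x - m) / anp.sqrt(v + eps) * gain + bias


def batch_norm(x, gain, bias, eps=1e-5):
    """Per-channel normalization over batch and spatial axes (training stats).

    Couples the samples of a batch, which interacts badly with the per-sample
    gradient penalty; kept available for fidelity, not as the default.
    """
    m = anp.mean(x, axis=(0, 1, 2), keepdims=True)
    v = anp.mean((x - m) ** 2, axis=(0, 1, 2), keepdims=True)
    return (x - m) / anp.sqrt(v + eps) * gain + bias


# ---------------------------------------------------------------------------
# parameter pytrees
# ---------------------------------------------------------------------------


def tree_map(fn, tree):
    if isinstance(tree, dict):
        return {k: tree_map(fn, v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return type(tree)(tree_map(fn, v) for v in tree)
    return fn(tree)


def tree_equal(a, b) -> bool:
    fa, _ = flatten(a)
    fb, _ = flatten(b)
    return fa.shape == fb.shape and bool(np.array_equal(fa, fb))


def flatten_tree(tree, prefix="", out=None):
    """Flatten a nested dict/list of arrays into {'a.0.W': array, ...}."""
    if out is None:
        out = {}
    if isinstance(tree, dict):
        for k, v in tree.items():
            flatten_tree(v, f"{prefix}{k}.", out)
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            flatten_tree(v, f"{prefix}{i}.", out)
    else:
        out[prefix[:-1]] = tree
    return out


def unflatten_like(template, flat: dict, prefix=""):
    """Inverse of :func:`flatten_tree` given a structural template."""
    if isinstance(template, dict):
        return {k: unflatten_like(v, flat, f"{prefix}{k}.") for k, v in template.items()}
    if isinstance(template, (list, tuple)):
        return type(template)(
            unflatten_like(v, flat, f"{prefix}{i}.") for i, v in enumerate(template)
        )
    return flat[prefix[:-1]]


def param_count(params) -> int:
    vec, _ = flatten(params)
    return int(vec.size)


class Adam:
    """Adaptive-moment optimizer over a parameter pytree."""

    def __init__(self, params, lr=2e-4, betas=(0.5, 0.9), eps=1e-8):
        vec, _ = flatten(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = np.zeros_like(vec)
        self.v = np.zeros_like(vec)
        self.t = 0

    def step(self, params, grads):
        """Return updated params; optimizer state advances in place."""
        p, unflat = flatten(params)
        g, _ = flatten(grads)
        self.t += 1
        self.m = self.b1 * self.m + (1.0 - self.b1) * g
        self.v = self.b2 * self.v + (1.0 - self.b2) * g * g
        mhat = self.m / (1.0 - self.b1**self.t)
        vhat = self.v / (1.0 - self.b2**self.t)
        newp = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return unflat(newp.astype(p.dtype))


# ---------------------------------------------------------------------------
# initializers
# ---------------------------------------------------------------------------


def he_conv(rng, k, cin, cout, dtype):
    W = rng.standard_normal((k, k, cin, cout)) * np.sqrt(2.0 / (k * k * cin))
    if k == 1:
        W = W[0, 0]
    return {"W": W.astype(dtype), "b": np.zeros(cout, dtype=dtype)}


def he_dense(rng, fan_in, fan_out, dtype):
    W = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
    return {"W": W.astype(dtype), "b": np.zeros(fan_out, dtype=dtype)}
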