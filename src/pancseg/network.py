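"""The 2.5D U-like encoder-decoder with dense blocks and hybrid attention.

Architecture
------------
The model consumes a 3-channel 2.5D input (three adjacent slices) and emits
a single-channel probability map for the centre slice.  Encoder and decoder
are built from dense convolution blocks (6 conv layers with DenseNet-style
concatenation and a 1x1 transition).  The first ``n3d_blocks`` encoder
blocks operate volumetrically: the 3 input channels are reinterpreted as a
depth-3 single-channel volume and convolved with 3x3x3 kernels
(depth-preserving padding); after each 3D block the depth is folded into
channels and projected by a 1x1 conv to the level's nominal 2D width, so
every skip connection exposes a plain 2D feature map whose width doubles
per level.  Spatial resolution halves between encoder blocks (2x2 max
pooling; spatial-only inside the 3D section) and doubles between decoder
blocks (bilinear upsampling).

Skip connections carry a hybrid attention gate: a spatial branch
``X * sigma(conv(f(X, Y)))`` and a channel branch driven by global average
+ max pooling through a shared 1x1 conv, where X is the encoder feature at
level k and Y the (deeper, half-resolution, double-width) feature at level
k+1.  The two gated maps are summed.  With ``attention="none"`` skips pass
through untouched (the plain 2.5D U-net ablation arm).

Feature maps are represented as autograd ``Tensor``s in ``(N, C, H, W)``
layout (``(N, C, D, H, W)`` inside the 3D section).

Normalisation is instance norm by default: the training regime uses batch
size 1, where batch statistics are degenerate.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .slicing import Input25D

__all__ = [
    "ModelConfig",
    "Module",
    "Conv2d",
    "Conv3d",
    "InstanceNorm",
    "DenseBlock2D",
    "DenseBlock3D",
    "SpatialAttention",
    "ChannelAttention",
    "HybridAttention",
    "SegModel",
    "build_model",
    "predict_slice",
    "channel_pool",
    "count_parameters",
    "zero_parameters",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the segmentation network.

    in_size: in-plane input size; must be divisible by 2**n_blocks.
    n_blocks: dense blocks per path (encoder depth).
    base_channels: width of the first level; doubles per level.
    dense_layers: conv layers inside each dense block.
    growth: channels added per dense layer (default: the block's width).
    n3d_blocks: leading encoder blocks that convolve volumetrically.
    attention: "hybrid" (spatial + channel gates on skips) or "none".
    norm: "instance" or "none".
    """

    in_size: Tuple[int, int] = (224, 224)
    n_blocks: int = 4
    base_channels: int = 32
    dense_layers: int = 6
    growth: Optional[int] = None
    n3d_blocks: int = 2
    attention: str = "hybrid"
    norm: str = "instance"

    def __post_init__(self) -> None:
        self.in_size = tuple(int(s) for s in self.in_size)
        if self.attention not in ("none", "hybrid"):
            raise ValueError(f"attention must be 'none' or 'hybrid', got {self.attention!r}")
        if self.norm not in ("none", "instance"):
            raise ValueError(f"norm must be 'none' or 'instance', got {self.norm!r}")
        for name in ("n_blocks", "base_channels", "dense_layers", "n3d_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n3d_blocks > self.n_blocks:
            raise ValueError("n3d_blocks must be <= n_blocks")
        f = 2 ** self.n_blocks
        if any(s % f for s in self.in_size):
            raise ValueError(f"in_size {self.in_size} not divisible by 2^n_blocks={f}")

    def level_width(self, k: int) -> int:
        """Nominal channel width at encoder level k (1-based)."""
        return self.base_channels * 2 ** (k - 1)


# -- module infrastructure -------------------------------------------------

class Module:
    """Container base class: recursive parameter collection."""

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        for v in self.__dict__.values():
            out.extend(_collect(v))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v) -> List[Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out: List[Tensor] = []
        for u in v:
            out.extend(_collect(u))
        return out
    return []


def _he(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.k = k
        self.weight = Tensor(_he(rng, (cout, cin, k, k), cin * k * k), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, pad=self.k // 2)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.k = k
        self.weight = Tensor(_he(rng, (cout, cin, k, k, k), cin * k ** 3), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias, pad=self.k // 2)


class InstanceNorm(Module):
    """Per-sample, per-channel normalisation over all spatial axes.

    Works for both (N, C, H, W) and (N, C, D, H, W) tensors.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.instance_norm(x, self.gamma, self.beta, eps=self.eps)


class _Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def _make_norm(cfg: ModelConfig, c: int) -> Module:
    return InstanceNorm(c) if cfg.norm == "instance" else _Identity()


# -- dense blocks ----------------------------------------------------------

class DenseBlock2D(Module):
    """Dense block: each conv layer sees the block input concatenated with
    every previous layer's output; a 1x1 transition sets the output width.

    Six stacked 3x3 convolutions give the block a receptive field of at
    least 13x13.
    """

    def __init__(self, cin: int, width: int, cfg: ModelConfig, rng: np.random.Generator):
        growth = cfg.growth or width
        self.convs: List[Conv2d] = []
        self.norms: List[Module] = []
        c = cin
        for _ in range(cfg.dense_layers):
            self.convs.append(Conv2d(c, growth, 3, rng))
            self.norms.append(_make_norm(cfg, growth))
            c += growth
        self.transition = Conv2d(c, width, 1, rng)
        self.t_norm = _make_norm(cfg, width)

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for conv, norm in zip(self.convs, self.norms):
            inp = feats[0] if len(feats) == 1 else ag.concat(feats, axis=1)
            feats.append(ag.relu(norm(conv(inp))))
        return ag.relu(self.t_norm(self.transition(ag.concat(feats, axis=1))))


class DenseBlock3D(Module):
    """Volumetric dense block (3x3x3 kernels, depth-preserving padding)."""

    def __init__(self, cin: int, width: int, cfg: ModelConfig, rng: np.random.Generator):
        growth = cfg.growth or width
        self.convs: List[Conv3d] = []
        self.norms: List[Module] = []
        c = cin
        for _ in range(cfg.dense_layers):
            self.convs.append(Conv3d(c, growth, 3, rng))
            self.norms.append(_make_norm(cfg, growth))
            c += growth
        self.transition = Conv3d(c, width, 1, rng)
        self.t_norm = _make_norm(cfg, width)

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for conv, norm in zip(self.convs, self.norms):
            inp = feats[0] if len(feats) == 1 else ag.concat(feats, axis=1)
            feats.append(ag.relu(norm(conv(inp))))
        return ag.relu(self.t_norm(self.transition(ag.concat(feats, axis=1))))


# -- attention -------------------------------------------------------------

def _check_attention_shapes(x: Tensor, y: Tensor) -> None:
    n, c, h, w = x.shape
    ny, cy, hy, wy = y.shape
    if (hy, wy) != (h // 2, w // 2) or cy != 2 * c:
        raise ValueError(
            f"attention expects Y of shape (N, 2c, h/2, w/2); got X {x.shape}, Y {y.shape}"
        )


class SpatialAttention(Module):
    """Spatial gate: X * sigma(conv(f(X, Y))).

    Y is upsampled x2, matched to c channels by a 1x1 conv and fused with X
    by addition; two 1x1 convolutions (c -> c/2 with ReLU, c/2 -> 1)
    produce a single-channel weight map squashed by a sigmoid, which gates
    X multiplicatively (broadcast over channels).
    """

    def __init__(self, c: int, rng: np.random.Generator):
        mid = max(c // 2, 1)
        self.match = Conv2d(2 * c, c, 1, rng)
        self.conv1 = Conv2d(c, mid, 1, rng)
        self.conv2 = Conv2d(mid, 1, 1, rng)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        _check_attention_shapes(x, y)
        yu = ag.upsample2x_bilinear(y)
        f = x + self.match(yu)
        wmap = ag.sigmoid(self.conv2(ag.relu(self.conv1(f))))
        return x * wmap


def channel_pool(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Global average and max pooling per channel.

    Accepts (C, H, W) or (N, C, H, W); returns (gap, gmp) vectors of
    length C (per sample in the batched case).
    """
    x = np.asarray(x)
    if x.ndim not in (3, 4):
        raise ValueError("channel_pool expects (C, H, W) or (N, C, H, W)")
    if x.shape[-1] == 0 or x.shape[-2] == 0:
        raise ValueError("empty spatial extent")
    return x.mean(axis=(-2, -1)), x.max(axis=(-2, -1))


class ChannelAttention(Module):
    """Channel gate from global average + max pooling of concat(X, up(Y)).

    Both pooled 3c-vectors pass through one shared 1x1 conv (3c -> c), are
    summed and squashed by a sigmoid into per-channel weights that scale X.
    """

    def __init__(self, c: int, rng: np.random.Generator):
        self.shared = Conv2d(3 * c, c, 1, rng)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        _check_attention_shapes(x, y)
        n, c, h, w = x.shape
        yu = ag.upsample2x_bilinear(y)
        z = ag.concat([x, yu], axis=1)  # (N, 3c, H, W)
        gap = z.sum(axis=(2, 3), keepdims=True) * (1.0 / (h * w))
        gmp = ag.amax(z, axis=(2, 3), keepdims=True)
        wvec = ag.sigmoid(self.shared(gap) + self.shared(gmp))  # (N, c, 1, 1)
        return x * wvec


class HybridAttention(Module):
    """Sum of the spatial and channel attention maps (same shape as X)."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.spatial = SpatialAttention(c, rng)
        self.channel = ChannelAttention(c, rng)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        return self.spatial(x, y) + self.channel(x, y)


# -- the full model --------------------------------------------------------

class SegModel(Module):
    """2.5D attention U-net: (N, 3, H, W) -> (N, 1, H, W) probabilities."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        B, T = config.n_blocks, config.n3d_blocks
        self.enc3d: List[DenseBlock3D] = []
        self.folds: List[Conv2d] = []
        for k in range(1, T + 1):
            cin = 1 if k == 1 else config.level_width(k - 1)
            w = config.level_width(k)
            self.enc3d.append(DenseBlock3D(cin, w, config, rng))
            self.folds.append(Conv2d(3 * w, w, 1, rng))
        self.enc2d: List[DenseBlock2D] = []
        for k in range(T + 1, B + 1):
            self.enc2d.append(
                DenseBlock2D(config.level_width(k - 1), config.level_width(k), config, rng)
            )
        self.attn: List[Optional[HybridAttention]] = []
        if config.attention == "hybrid":
            self.attn = [HybridAttention(config.level_width(k), rng) for k in range(1, B)]
        self.dec: List[DenseBlock2D] = []
        for k in range(B - 1, 0, -1):
            cin = config.level_width(k + 1) + config.level_width(k)
            self.dec.append(DenseBlock2D(cin, config.level_width(k), config, rng))
        self.head = Conv2d(config.level_width(1), 1, 1, rng)

    def forward(self, x) -> Tensor:
        """x: array or Tensor (N, 3, H, W) with intensities on [0, 1]."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        n, c, h, w = x.shape
        if c != 3 or (h, w) != self.config.in_size:
            raise ValueError(
                f"expected input (N, 3, {self.config.in_size[0]}, "
                f"{self.config.in_size[1]}), got {x.shape}"
            )
        B, T = self.config.n_blocks, self.config.n3d_blocks
        feats: List[Tensor] = []
        # 3D section: channels reinterpreted as depth 3
        e3 = ag.reshape(x, (n, 1, 3, h, w))
        for k in range(1, T + 1):
            e3 = self.enc3d[k - 1](e3)
            dd, hh, ww = e3.shape[2], e3.shape[3], e3.shape[4]
            folded = ag.reshape(e3, (n, e3.shape[1] * dd, hh, ww))
            feats.append(self.folds[k - 1](folded))
            if k < T:
                e3 = ag.maxpool2x2(e3)
        # 2D section
        cur = feats[-1]
        for k in range(T + 1, B + 1):
            cur = self.enc2d[k - T - 1](ag.maxpool2x2(cur))
            feats.append(cur)
        # decoder with attention-gated skips
        d = feats[B - 1]
        for j, k in enumerate(range(B - 1, 0, -1)):
            skip = feats[k - 1]
            if self.config.attention == "hybrid":
                skip = self.attn[k - 1](skip, feats[k])
            d = self.dec[j](ag.concat([ag.upsample2x_bilinear(d), skip], axis=1))
        return ag.sigmoid(self.head(d))


def build_model(cfg: ModelConfig, seed: int = 0) -> SegModel:
    """Construct a SegModel with deterministic (seeded) initialisation."""
    return SegModel(cfg, seed=seed)


def predict_slice(m: SegModel, x: "Input25D | np.ndarray", scale: float = 255.0) -> np.ndarray:
    """Probability map for the centre slice of one 2.5D input.

    ``scale`` divides the input intensities (255 for the standard [0, 255]
    preprocessed range).  Accepts a batched array (N, 3, H, W) as well and
    then returns (N, H, W).
    """
    arr = x.channels if isinstance(x, Input25D) else np.asarray(x)
    batched = arr.ndim == 4
    if not batched:
        arr = arr[None]
    if arr.shape[2:] != m.config.in_size:
        raise ValueError(f"input size {arr.shape[2:]} != model in_size {m.config.in_size}")
    with ag.no_grad():
        out = m.forward(arr.astype(np.float32) / scale).data[:, 0]
    return out if batched else out[0]


def count_parameters(m: Module) -> int:
    return sum(int(p.data.size) for p in m.parameters())


def zero_parameters(m: Module) -> Module:
    """Set every trainable parameter to zero (analytic-check utility)."""
    for p in m.parameters():
        p.data[...] = 0
    return m


# -- checkpoints -----------------------------------------------------------

def save_model(m: SegModel, out_dir: str) -> None:
    """Native weights (.npz, in construction order) + JSON config sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    params = m.parameters()
    np.savez_compressed(
        os.path.join(out_dir, "weights.npz"),
        **{f"p{i}": p.data for i, p in enumerate(params)},
    )
    with open(os.path.join(out_dir, "config.json"), "w") as f:
        json.dump(asdict(m.config), f, indent=2)


def load_model(model_dir: str) -> SegModel:
    with open(os.path.join(model_dir, "config.json")) as f:
        raw = json.load(f)
    cfg = ModelConfig(**raw)
    m = SegModel(cfg, seed=0)
    with np.load(os.path.join(model_dir, "weights.npz")) as zf:
        params = m.parameters()
        if len(zf.files) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for i, p in enumerate(params):
            arr = zf[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data[...] = arr
    return m
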