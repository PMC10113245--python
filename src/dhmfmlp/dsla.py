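"""Dynamic spatial linear attention (DSLA): adaptive spatial attention (ASAM)
composed with a grid-gated axial MLP.

ASAM builds a per-pixel attention weight from a learnable convex mixture of
channel-average and channel-max pooling, rectified and squashed through a
logistic; because the logistic argument is nonnegative the weight always lies
in [0.5, 1). The axial MLP is the global half of a multi-axis gated MLP: the
image is partitioned into a d x d grid of contiguous tiles, a linear map
shared across channels and within-tile offsets mixes information across the
d^2 tiles, a second (ungated) branch gates the result multiplicatively, and a
final projection feeds a residual connection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import engine
from .nn.engine import Tensor, as_tensor

logger = logging.getLogger(__name__)


def channel_pool(f, mode: str) -> Tensor:
    """Per-pixel pooling across the channel axis, giving a (B,1,H,W) map."""
    f = as_tensor(f)
    if f.ndim != 4:
        raise ValueError(f"expected rank-4 input, got rank {f.ndim}")
    if mode == "avg":
        return engine.tmean(f, axis=1, keepdims=True)
    if mode == "max":
        return engine.max_axis(f, axis=1, keepdims=True)
    raise ValueError(f"mode must be 'avg' or 'max', got {mode!r}")


class ASAM(nn.Module):
    """Adaptive spatial attention.

    w = logistic(ReLU(mu * avgpool_C(F) + (1 - mu) * maxpool_C(F))), applied
    multiplicatively to F with broadcasting over channels. The mixing
    coefficient mu is stored as an unconstrained pre-activation and mapped
    through a logistic, so 0 < mu < 1 by construction; it initializes at 0.5.
    With ``learnable=False`` mu is the constant 0.5 and no parameter exists.
    """

    def __init__(self, learnable: bool = True):
        super().__init__()
        if learnable:
            self.mu_pre = nn.Parameter(np.zeros(()))
        else:
            self.mu_pre = None

    @property
    def mu(self) -> float:
        if self.mu_pre is None:
            return 0.5
        # evaluated in float64 and clamped to the open interval so mu stays
        # strictly inside (0, 1) even for saturated pre-activations
        s = 1.0 / (1.0 + np.exp(-float(self.mu_pre.data)))
        return float(min(max(s, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0)))

    def attention(self, f) -> Tensor:
        f = as_tensor(f)
        avg = channel_pool(f, "avg")
        mx = channel_pool(f, "max")
        if self.mu_pre is None:
            pre = engine.add(engine.mul(avg, 0.5), engine.mul(mx, 0.5))
        else:
            mu = engine.sigmoid(self.mu_pre)
            pre = engine.add(engine.mul(avg, mu), engine.mul(mx, engine.add(engine.mul(mu, -1.0), 1.0)))
        return engine.sigmoid(engine.relu(pre))

    def forward(self, f):
        f = as_tensor(f)
        return engine.mul(self.attention(f), f)


@dataclass
class GridBlocks:
    """Grid re-layout of a feature map: (B, C, tile-index g, within-tile
    offset p) with g in row-major tile order and p in row-major pixel order.
    The re-layout is a bijection; ``height``/``width`` record the source size."""

    values: Tensor
    grid_size: int
    height: int
    width: int


def _grid_tensor(f: Tensor, d: int) -> Tensor:
    b, c, h, w = f.shape
    if h % d or w % d:
        raise ValueError(f"grid: spatial size ({h},{w}) not divisible by d={d}")
    th, tw = h // d, w // d
    x = engine.reshape(f, (b, c, d, th, d, tw))        # (B,C,by,iy,bx,ix)
    x = engine.transpose(x, (0, 1, 2, 4, 3, 5))        # (B,C,by,bx,iy,ix)
    return engine.reshape(x, (b, c, d * d, th * tw))


def _ungrid_tensor(x: Tensor, d: int, h: int, w: int) -> Tensor:
    b, c = x.shape[0], x.shape[1]
    th, tw = h // d, w // d
    y = engine.reshape(x, (b, c, d, d, th, tw))
    y = engine.transpose(y, (0, 1, 2, 4, 3, 5))
    return engine.reshape(y, (b, c, h, w))


def grid(f, d: int = 8) -> GridBlocks:
    """Partition a (B,C,H,W) map into d x d contiguous tiles of size
    (H/d) x (W/d); tiles are indexed row-major on axis 2, pixels within a
    tile row-major on axis 3."""
    f = as_tensor(f)
    _, _, h, w = f.shape
    return GridBlocks(_grid_tensor(f, d), d, h, w)


def ungrid(g: GridBlocks) -> Tensor:
    """Exact inverse of :func:`grid`."""
    d, h, w = g.grid_size, g.height, g.width
    b, c, ng, np_ = g.values.shape
    if ng != d * d or np_ != (h // d) * (w // d):
        raise ValueError(f"inconsistent grid axes: {(ng, np_)} for d={d}, "
                         f"source ({h},{w})")
    return _ungrid_tensor(g.values, d, h, w)


class AxialMLP(nn.Module):
    """Grid-gated global token mixer (residual).

    LN -> per-pixel linear C->2C -> GELU -> grid -> split channels into two
    halves -> linear map along the tile axis (length d^2, shared across
    channels and offsets) on the first half -> elementwise product with the
    second half -> per-pixel linear C->C -> ungrid -> add the input.
    """

    def __init__(self, channels: int, rng: np.random.Generator, d: int = 8):
        super().__init__()
        self.norm = nn.LayerNorm2d(channels)
        self.expand = nn.ChannelLinear(channels, 2 * channels, rng)
        self.tile_mix = nn.AxisLinear(d * d, d * d, axis=2, rng=rng)
        self.project = nn.ChannelLinear(channels, channels, rng)
        self.channels = channels
        self.d = d

    def forward(self, f):
        f = as_tensor(f)
        _, c, h, w = f.shape
        if h % self.d or w % self.d:
            raise ValueError(f"axial_mlp: ({h},{w}) not divisible by d={self.d}")
        x = self.norm(f)
        x = self.expand(x)
        x = engine.gelu(x)
        x = _grid_tensor(x, self.d)                      # (B, 2C, d^2, p)
        f2 = engine.narrow(x, 1, 0, c)
        f3 = engine.narrow(x, 1, c, c)
        gated = engine.mul(self.tile_mix(f2), f3)
        y = engine.channel_linear(gated, self.project.weight, self.project.bias)
        y = _ungrid_tensor(y, self.d, h, w)
        return engine.add(f, y)


def effective_grid_size(h: int, w: int, d: int = 8) -> int:
    """Largest grid size <= d usable at a given resolution (at least 1);
    divisibility is still checked at forward time. At the coarsest stages of
    small inputs the grid degenerates toward one pixel per tile, where the
    tile-axis map mixes every pixel globally."""
    return max(1, min(d, h, w))


class DSLA(nn.Module):
    """Serial composition: feature selection by ASAM, then global context by
    the axial MLP. Either branch can be switched off (ablation variants);
    with both off the block is the identity (logged once)."""

    def __init__(self, channels: int, rng: np.random.Generator, d: int = 8,
                 use_asam: bool = True, use_axial: bool = True,
                 learnable_mu: bool = True):
        super().__init__()
        self.asam = ASAM(learnable=learnable_mu) if use_asam else None
        self.axial = AxialMLP(channels, rng, d=d) if use_axial else None
        if self.asam is None and self.axial is None:
            logger.warning("DSLA with both branches disabled is the identity "
                           "(equivalent to the no-DSLA ablation)")

    def forward(self, f):
        f = as_tensor(f)
        if self.asam is not None:
            f = self.asam(f)
        if self.axial is not None:
            f = self.axial(f)
        return f
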