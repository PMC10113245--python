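"""Backbone building blocks: axial channel-group shifting, the tokenized-MLP
block, and the depth-wise strided convolution used for fusion down-sampling.

The tokenized-MLP ("Tok-MLP") block mixes spatial information without
attention: channel groups are translated by different pixel offsets along one
spatial axis (so that each pixel's channel vector gathers values from a small
axial neighbourhood), pixels are treated as tokens, and two per-token linear
maps with a depth-wise convolution in between do the mixing. The block is
residual: with a zeroed output projection it is the exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import engine
from .nn.engine import Tensor, as_tensor

_AXIS = {"height": 2, "width": 3}

DEFAULT_GROUPS = 5
DEFAULT_OFFSETS = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class ShiftSpec:
    """Axial shift specification: which axis, how many contiguous channel
    groups, and the per-group pixel offsets (symmetric around 0 by default)."""

    axis: str = "width"
    groups: int = DEFAULT_GROUPS
    offsets: tuple[int, ...] = DEFAULT_OFFSETS

    def __post_init__(self):
        if self.axis not in _AXIS:
            raise ValueError(f"axis must be 'height' or 'width', got {self.axis!r}")
        if len(self.offsets) != self.groups:
            raise ValueError(f"{len(self.offsets)} offsets for {self.groups} groups")


def _equal_group_slices(channels: int, groups: int) -> list[slice]:
    if channels % groups:
        raise ValueError(
            f"channel count C={channels} is not divisible by h={groups} groups")
    size = channels // groups
    return [slice(j * size, (j + 1) * size) for j in range(groups)]


def near_equal_group_slices(channels: int, groups: int) -> list[slice]:
    """Contiguous near-equal channel groups (sizes differ by at most one),
    with the larger groups first, so every channel belongs to a group."""
    base, rem = divmod(channels, groups)
    sizes = [base + 1] * rem + [base] * (groups - rem)
    slices, start = [], 0
    for s in sizes:
        slices.append(slice(start, start + s))
        start += s
    return slices


def axial_shift(t, spec: ShiftSpec) -> Tensor:
    """Translate each contiguous channel group of a (B, C, H, W) map by its
    offset along ``spec.axis``; vacated positions are zero-filled and values
    shifted past the border are discarded."""
    t = as_tensor(t)
    if t.ndim != 4:
        raise ValueError(f"expected a rank-4 (B,C,H,W) array, got rank {t.ndim}")
    slices = _equal_group_slices(t.shape[1], spec.groups)
    return engine.shift2d(t, slices, spec.offsets, axis=_AXIS[spec.axis])


def _shift_uneven(t: Tensor, axis_name: str, offsets=DEFAULT_OFFSETS) -> Tensor:
    """Axial shift with near-equal grouping, used inside Tok-MLP where the
    channel widths (32..256, and the 768 hidden width) are not multiples of
    the group count."""
    slices = near_equal_group_slices(t.shape[1], len(offsets))
    return engine.shift2d(t, slices, offsets, axis=_AXIS[axis_name])


class TokMLPBlock(nn.Module):
    """Residual tokenized-MLP block.

    Pipeline: layer norm -> width-axis shift -> per-token linear C->hidden ->
    3x3 depth-wise convolution -> GELU -> height-axis shift -> per-token
    linear hidden->C -> add the block input. Tokenization is the row-major
    flattening of (y, x); since the per-token linear maps act pointwise on the
    channel axis it is carried implicitly by the (B, C, H, W) layout and its
    inverse is bit-exact.

    Parameters
    ----------
    channels : block width C (input and output).
    hidden : token embedding width of the first linear map (default 768).
    """

    def __init__(self, channels: int, rng: np.random.Generator, hidden: int = 768,
                 offsets: tuple[int, ...] = DEFAULT_OFFSETS):
        super().__init__()
        self.norm = nn.LayerNorm2d(channels)
        self.fc1 = nn.ChannelLinear(channels, hidden, rng)
        self.dwconv = nn.Conv2d(hidden, hidden, 3, rng, padding=1, groups=hidden)
        self.fc2 = nn.ChannelLinear(hidden, channels, rng)
        self.offsets = tuple(offsets)

    def forward(self, t):
        t = as_tensor(t)
        x = self.norm(t)
        x = _shift_uneven(x, "width", self.offsets)
        x = self.fc1(x)
        x = self.dwconv(x)
        x = engine.gelu(x)
        x = _shift_uneven(x, "height", self.offsets)
        x = self.fc2(x)
        out = engine.add(t, x)
        if not np.isfinite(out.data).all():
            raise FloatingPointError("non-finite values in Tok-MLP block output")
        return out


class DWConvDownsample(nn.Module):
    """3x3 depth-wise convolution with stride 2 and padding 1: halves both
    spatial dimensions, preserves the channel count (one filter per channel)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 3, rng, stride=2, padding=1,
                              groups=channels)

    def forward(self, x):
        x = as_tensor(x)
        _, _, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"dwconv_downsample requires even H, W; got ({h},{w})")
        return self.conv(x)
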