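"""Hierarchical multi-scale fusion (HMSF).

Two passes over the encoder pyramid {f1..f5}:

* first pass — layerwise fusion: the top level only receives global context
  (axial MLP, no attention, nothing above it to fuse); every deeper level i
  fuses the previous fused map (depth-wise stride-2 down-sampled) with the
  encoder feature f_i by channel concatenation, projects back to C_i with a
  1x1 convolution, and refines with DSLA. Each fused map f_i' is retained.
* second pass — f1'..f4' are adaptive-max-pooled to the size of f5', all five
  are channel-concatenated (sum(C_i) = 640 channels for the standard
  schedule) and a 3x3 convolution maps to C5, giving the decoder bottleneck.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .blocks import DWConvDownsample
from .dsla import DSLA, AxialMLP, effective_grid_size
from .nn import engine
from .nn.engine import Tensor, as_tensor


def validate_pyramid(features, channels) -> None:
    """Check the encoder pyramid invariants: channel schedule and successive
    spatial halving."""
    if len(features) != len(channels):
        raise ValueError(f"expected {len(channels)} pyramid levels, got {len(features)}")
    prev_hw = None
    for i, (f, c) in enumerate(zip(features, channels), start=1):
        b, fc, h, w = f.shape
        if fc != c:
            raise ValueError(f"level {i}: expected {c} channels, got {fc}")
        if prev_hw is not None and (prev_hw[0] != 2 * h or prev_hw[1] != 2 * w):
            raise ValueError(f"level {i}: resolution ({h},{w}) does not halve "
                             f"level {i-1} ({prev_hw[0]},{prev_hw[1]})")
        prev_hw = (h, w)


class HMSF(nn.Module):
    """Hierarchical multi-scale fusion over a five-level encoder pyramid.

    ``stage_sizes`` are the (H, W) of f1..f5, needed to size each axial MLP's
    grid; at the full 256/512 configurations every instance uses the default
    d = 8, while very small synthetic inputs fall back to coarser grids.
    Ablation switches: ``with_dsla`` drops every DSLA call (identity, fusion
    plumbing kept); ``with_asam``/``with_axial``/``learnable_mu`` are passed
    through to the DSLA instances at levels 2..5.
    """

    def __init__(self, rng: np.random.Generator,
                 channels: tuple[int, ...] = (32, 64, 128, 160, 256),
                 stage_sizes: tuple[tuple[int, int], ...] | None = None,
                 d: int = 8, with_dsla: bool = True, with_asam: bool = True,
                 with_axial: bool = True, learnable_mu: bool = True):
        super().__init__()
        self.channels = tuple(channels)
        if stage_sizes is None:
            stage_sizes = tuple((256 >> i, 256 >> i) for i in range(1, 6))
        use_axial = with_dsla and with_axial
        use_asam = with_dsla and with_asam

        if use_axial:
            d1 = effective_grid_size(*stage_sizes[0], d)
            self.level1 = AxialMLP(channels[0], rng, d=d1)
        else:
            self.level1 = nn.Identity()

        for i in range(2, 6):  # levels 2..5
            c_prev, c_i = channels[i - 2], channels[i - 1]
            setattr(self, f"down{i}", DWConvDownsample(c_prev, rng))
            setattr(self, f"proj{i}", nn.Conv2d(c_prev + c_i, c_i, 1, rng))
            setattr(self, f"proj_bn{i}", nn.BatchNorm2d(c_i))
            if use_asam or use_axial:
                di = effective_grid_size(*stage_sizes[i - 1], d)
                block = DSLA(c_i, rng, d=di, use_asam=use_asam,
                             use_axial=use_axial, learnable_mu=learnable_mu)
            else:
                block = nn.Identity()
            setattr(self, f"dsla{i}", block)

        total = sum(channels)
        self.fuse = nn.Conv2d(total, channels[-1], 3, rng, padding=1)
        self.fuse_bn = nn.BatchNorm2d(channels[-1])

    # ------------------------------------------------------------ first pass
    def first_fusion(self, features) -> list[Tensor]:
        features = [as_tensor(f) for f in features]
        validate_pyramid(features, self.channels)
        fused = [self.level1(features[0])]
        for i in range(2, 6):
            down = getattr(self, f"down{i}")(fused[-1])
            cat = engine.concat([down, features[i - 1]], axis=1)
            proj = engine.relu(getattr(self, f"proj_bn{i}")(getattr(self, f"proj{i}")(cat)))
            fused.append(getattr(self, f"dsla{i}")(proj))
        return fused

    # ----------------------------------------------------------- second pass
    def second_fusion(self, fused) -> Tensor:
        target = fused[-1].shape[2:]
        pooled = [engine.adaptive_maxpool(f, target) for f in fused[:-1]]
        cat = engine.concat(pooled + [fused[-1]], axis=1)
        return engine.relu(self.fuse_bn(self.fuse(cat)))

    def forward(self, features) -> Tensor:
        return self.second_fusion(self.first_fusion(features))
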