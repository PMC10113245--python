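"""Parameterized layers on top of the autodiff engine.

Modules follow the familiar container pattern: parameters and sub-modules are
registered on attribute assignment, ``named_parameters`` walks the tree, and
``state_dict``/``load_state_dict`` move plain numpy arrays in and out.
"""

from __future__ import annotations

import numpy as np

from . import engine
from .engine import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield f"{prefix}{name}", b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix=f"{prefix}{name}.")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({f"buffer::{name}": b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in d.items():
            if key.startswith("buffer::"):
                buf = buffers[key[len("buffer::"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.data.shape} vs {value.shape}")
                p.data = np.asarray(value, dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated to +-2 std, by resampling."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(DTYPE)


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.normal(0.0, std, size=shape)).astype(DTYPE)


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1, bias: bool = True):
        super().__init__()
        if in_ch % groups:
            raise ValueError(f"in_ch {in_ch} not divisible by groups {groups}")
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Parameter(kaiming_normal(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return engine.conv2d(x, self.weight, self.bias, stride=self.stride,
                             padding=self.padding, groups=self.groups)


class ChannelLinear(Module):
    """Per-pixel fully connected layer over the channel axis of (B,C,H,W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (out_ch, in_ch)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return engine.channel_linear(x, self.weight, self.bias)


class AxisLinear(Module):
    """Fully connected layer applied along one arbitrary axis (shared elsewhere)."""

    def __init__(self, n_in: int, n_out: int, axis: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (n_out, n_in)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None
        self.axis = axis

    def forward(self, x):
        nd = x.data.ndim
        axis = self.axis % nd
        if axis != nd - 1:
            perm = [i for i in range(nd) if i != axis] + [axis]
            x = engine.transpose(x, perm)
        y = engine.linear_last(x, self.weight, self.bias)
        if axis != nd - 1:
            inv = list(range(nd - 1))
            inv.insert(axis, nd - 1)
            y = engine.transpose(y, inv)
        return y


class LayerNorm2d(Module):
    """Per-pixel layer normalization over channels of (B,C,H,W)."""

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x):
        return engine.layernorm_channel(x, self.weight, self.bias, eps=self.eps)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float64))
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return engine.batchnorm2d(x, self.weight, self.bias, self.running_mean,
                                  self.running_var, training=self.training,
                                  momentum=self.momentum, eps=self.eps)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._order = [f"m{i}" for i in range(len(mods))]

    def forward(self, x):
        for name in self._order:
            x = getattr(self, name)(x)
        return x
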