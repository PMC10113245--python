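"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every operation builds a ``Tensor``
node holding the forward value and a closure that accumulates gradients into
its parents. Backward traverses the tape in reverse topological order.

Only the operations the segmentation network needs are implemented, each with
an analytically derived adjoint. Dtypes are preserved (float64 inputs give
float64 graphs), which lets the test suite run finite-difference gradient
checks in double precision while training runs in float32.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "as_tensor"]

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = _backward
        self._parents = _parents

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    # --------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; the graphs here can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad)
        else:
            self.grad = self.grad + grad

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _node(data, parents: Sequence[Tensor], backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents),
                  _backward=backward if req else None)


# ---------------------------------------------------------------- arithmetic

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _node(out_data, (a, b), backward)


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            gx = np.broadcast_to(g, x.data.shape)
        elif keepdims:
            gx = np.broadcast_to(g, x.data.shape)
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(a % x.data.ndim for a in axes)
            gx = np.expand_dims(g, axes)
            gx = np.broadcast_to(gx, x.data.shape)
        x._accumulate(np.ascontiguousarray(gx))

    return _node(out_data, (x,), backward)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    if axis is None:
        n = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


def max_axis(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max over one axis; gradient flows to the (first) argmax only."""
    x = as_tensor(x)
    idx = np.argmax(x.data, axis=axis)
    out_data = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def backward(g):
        gx = np.zeros_like(x.data)
        g_exp = g if keepdims else np.expand_dims(g, axis)
        np.put_along_axis(gx, np.expand_dims(idx, axis), g_exp, axis=axis)
        x._accumulate(gx)

    return _node(out_data, (x,), backward)


# ------------------------------------------------------------- element-wise

def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g):
        x._accumulate(g * mask)

    return _node(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return _node(s, (x,), backward)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = as_tensor(x)
    phi = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out_data = x.data * phi

    def backward(g):
        pdf = np.exp(-0.5 * x.data ** 2) * _INV_SQRT2PI
        x._accumulate(g * (phi + x.data * pdf))

    return _node(out_data, (x,), backward)


# ------------------------------------------------------------------ layout

def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return _node(out_data, (x,), backward)


def transpose(x: Tensor, axes: Sequence[int]) -> Tensor:
    x = as_tensor(x)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = np.transpose(x.data, axes)

    def backward(g):
        x._accumulate(np.ascontiguousarray(np.transpose(g, inv)))

    return _node(out_data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(np.ascontiguousarray(piece))

    return _node(out_data, tuple(tensors), backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries from ``start`` along ``axis``."""
    x = as_tensor(x)
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out_data = x.data[sl]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[sl] = g
        x._accumulate(gx)

    return _node(out_data, (x,), backward)


def shift2d(x: Tensor, group_slices: Sequence[slice], offsets: Sequence[int],
            axis: int) -> Tensor:
    """Translate each channel group by its offset along a spatial axis.

    ``axis`` is 2 (rows) or 3 (columns) of a (B, C, H, W) tensor. Positions
    vacated by the shift are zero-filled; values shifted past the border are
    discarded.
    """
    x = as_tensor(x)
    out_data = np.zeros_like(x.data)
    n = x.data.shape[axis]

    def _place(dst, src, cs, off):
        if abs(off) >= n:
            return
        d = [slice(None)] * dst.ndim
        s = [slice(None)] * dst.ndim
        d[1] = cs
        s[1] = cs
        if off >= 0:
            d[axis] = slice(off, n)
            s[axis] = slice(0, n - off)
        else:
            d[axis] = slice(0, n + off)
            s[axis] = slice(-off, n)
        dst[tuple(d)] = src[tuple(s)]

    for cs, off in zip(group_slices, offsets):
        _place(out_data, x.data, cs, off)

    def backward(g):
        gx = np.zeros_like(x.data)
        for cs, off in zip(group_slices, offsets):
            _place(gx, g, cs, -off)  # adjoint of a shift is the opposite shift
        x._accumulate(gx)

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------- contractions

def linear_last(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map on the last axis: ``y = x @ w.T + b`` with w (out, in)."""
    x, w = as_tensor(x), as_tensor(w)
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        if x.requires_grad or x._parents:
            x._accumulate(g @ w.data)
        if w.requires_grad:
            gw = np.tensordot(g, x.data, axes=(range(g.ndim - 1), range(g.ndim - 1)))
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def channel_linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Per-pixel affine map on the channel axis of (B, C, H, W)."""
    x, w = as_tensor(x), as_tensor(w)
    out_data = np.einsum("oc,bchw->bohw", w.data, x.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        if x.requires_grad or x._parents:
            x._accumulate(np.einsum("oc,bohw->bchw", w.data, g, optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("bohw,bchw->oc", g, x.data, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation. ``w`` has shape (Cout, Cin/groups, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    if C % groups or Cout % groups or Cg != C // groups:
        raise ValueError(f"conv2d group mismatch: C={C}, Cout={Cout}, groups={groups}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho, Wo = (Hp - kh) // s + 1, (Wp - kw) // s + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::s, ::s]  # (B, C, Ho, Wo, kh, kw)
    vg = view.reshape(B, groups, Cg, Ho, Wo, kh, kw)
    wg = w.data.reshape(groups, Cout // groups, Cg, kh, kw)
    out_data = np.einsum("bgchwij,gocij->bgohw", vg, wg, optimize=True)
    out_data = out_data.reshape(B, Cout, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        gg = g.reshape(B, groups, Cout // groups, Ho, Wo)
        if w.requires_grad:
            gw = np.einsum("bgohw,bgchwij->gocij", gg, vg, optimize=True)
            w._accumulate(gw.reshape(Cout, Cg, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            # scatter the kernel-weighted gradient back over the 9 (kh*kw) taps
            dcols = np.einsum("bgohw,gocij->bgcijhw", gg, wg, optimize=True)
            dcols = dcols.reshape(B, C, kh, kw, Ho, Wo)
            gx = np.zeros((B, C, Hp, Wp), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, i, j]
            if p:
                gx = gx[:, :, p:Hp - p, p:Wp - p]
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


# -------------------------------------------------------------------- pooling

def block_maxpool(x: Tensor, kh: int, kw: int) -> Tensor:
    """Non-overlapping max pooling over (kh, kw) blocks; H, W must divide."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H % kh or W % kw:
        raise ValueError(f"block_maxpool: ({H},{W}) not divisible by ({kh},{kw})")
    Ho, Wo = H // kh, W // kw
    blocks = x.data.reshape(B, C, Ho, kh, Wo, kw).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(B, C, Ho, Wo, kh * kw)
    idx = np.argmax(flat, axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(B, C, Ho, Wo, kh, kw).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(np.ascontiguousarray(gx.reshape(B, C, H, W)))

    return _node(out_data, (x,), backward)


def adaptive_maxpool(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Adaptive max pooling for target sizes that divide the input evenly."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    oh, ow = out_hw
    if (H, W) == (oh, ow):
        return x
    if H % oh or W % ow:
        raise ValueError(f"adaptive_maxpool: ({H},{W}) not a multiple of ({oh},{ow})")
    return block_maxpool(x, H // oh, W // ow)


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        c = (i + 0.5) * scale - 0.5
        i0 = int(np.floor(c))
        t = c - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        m[i, i0c] += 1.0 - t
        m[i, i1c] += t
    return m


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear upsampling by a factor of 2 (align_corners=False convention)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    mh = _interp_matrix(2 * H, H, x.data.dtype)
    mw = _interp_matrix(2 * W, W, x.data.dtype)
    out_data = np.einsum("oh,bchw,pw->bcop", mh, x.data, mw, optimize=True)

    def backward(g):
        x._accumulate(np.einsum("oh,bcop,pw->bchw", mh, g, mw, optimize=True))

    return _node(out_data, (x,), backward)


# ------------------------------------------------------------- normalization

def layernorm_channel(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer norm over the channel axis of (B, C, H, W), per spatial position."""
    x = as_tensor(x)
    mu = x.data.mean(axis=1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
    C = x.data.shape[1]

    def backward(g):
        gam = gamma.data[None, :, None, None]
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gh = g * gam
            t1 = gh.sum(axis=1, keepdims=True)
            t2 = (gh * xhat).sum(axis=1, keepdims=True)
            x._accumulate(inv * (gh - t1 / C - xhat * t2 / C))

    return _node(out_data, (x, gamma, beta), backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                running_var: np.ndarray, training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Batch norm over (B, H, W) per channel; updates running stats in place."""
    x = as_tensor(x)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gam_inv = (gamma.data * inv)[None, :, None, None]
            if training:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                t1 = g.sum(axis=(0, 2, 3), keepdims=True)
                t2 = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                x._accumulate(gam_inv * (g - t1 / n - xhat * t2 / n))
            else:
                x._accumulate(gam_inv * g)

    return _node(out_data, (x, gamma, beta), backward)


# ------------------------------------------------------------------- losses

def bce_with_logits_mean(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed from logits (numerically stable)."""
    z = as_tensor(logits)
    y = np.asarray(targets, dtype=z.data.dtype)
    val = np.maximum(z.data, 0) - z.data * y + np.log1p(np.exp(-np.abs(z.data)))
    out_data = np.asarray(val.mean(), dtype=z.data.dtype)
    n = z.data.size

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-z.data))
        z._accumulate(g * (s - y) / n)

    return _node(out_data, (z,), backward)
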