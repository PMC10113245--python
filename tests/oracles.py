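"""Naive straight-line reference implementations (explicit loops, no batched
reshapes). These exist only to cross-check the vectorized implementations and
are deliberately written from the operation definitions, not from the code
they test."""

import math

import numpy as np
from scipy.special import erf


def axial_shift_loop(x, group_slices, offsets, axis):
    """Quadruple-loop axial shift oracle over (b, c, y, x)."""
    b, c, h, w = x.shape
    out = np.zeros_like(x)
    group_of = np.empty(c, dtype=int)
    for j, sl in enumerate(group_slices):
        group_of[sl] = j
    for bi in range(b):
        for ci in range(c):
            off = offsets[group_of[ci]]
            for yi in range(h):
                for xi in range(w):
                    if axis == 2:
                        src = yi - off
                        ok = 0 <= src < h
                        val = x[bi, ci, src, xi] if ok else 0.0
                    else:
                        src = xi - off
                        ok = 0 <= src < w
                        val = x[bi, ci, yi, src] if ok else 0.0
                    out[bi, ci, yi, xi] = val
    return out


def conv2d_loop(x, w, b=None, stride=1, padding=0):
    """Sliding-window correlation oracle (single group)."""
    B, C, H, W = x.shape
    Cout, Cin, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((B, Cout, Ho, Wo), dtype=x.dtype)
    for bi in range(B):
        for o in range(Cout):
            for yo in range(Ho):
                for xo in range(Wo):
                    acc = 0.0
                    for c in range(Cin):
                        for i in range(kh):
                            for j in range(kw):
                                acc += xp[bi, c, yo * stride + i, xo * stride + j] \
                                    * w[o, c, i, j]
                    out[bi, o, yo, xo] = acc + (b[o] if b is not None else 0.0)
    return out


def dwconv_loop(x, w, b=None, stride=1, padding=0):
    """Depth-wise convolution oracle: one (1, kh, kw) filter per channel."""
    B, C, H, W = x.shape
    outs = [conv2d_loop(x[:, c:c + 1], w[c:c + 1], None, stride, padding)
            for c in range(C)]
    out = np.concatenate(outs, axis=1)
    if b is not None:
        out = out + b[None, :, None, None]
    return out


def channel_pool_loop(x, mode):
    """Per-pixel loop oracle for channel pooling."""
    B, C, H, W = x.shape
    out = np.zeros((B, 1, H, W), dtype=x.dtype)
    for bi in range(B):
        for y in range(H):
            for xx in range(W):
                vals = [x[bi, c, y, xx] for c in range(C)]
                out[bi, 0, y, xx] = (sum(vals) / C) if mode == "avg" else max(vals)
    return out


def _gelu(v):
    return v * 0.5 * (1.0 + erf(v / math.sqrt(2.0)))


def axial_mlp_loop(f, params, d):
    """Straight-line axial-MLP oracle from the operation definition.

    ``params`` holds numpy arrays: ln_g, ln_b (C,), w1 (2C, C), b1 (2C,),
    wg (d^2, d^2), bg (d^2,), w2 (C, C), b2 (C,). All arithmetic is explicit
    per-element loops over small inputs.
    """
    B, C, H, W = f.shape
    th, tw = H // d, W // d
    ln_g, ln_b = params["ln_g"], params["ln_b"]
    w1, b1 = params["w1"], params["b1"]
    wg, bg = params["wg"], params["bg"]
    w2, b2 = params["w2"], params["b2"]

    # layer norm per pixel over channels (eps matches the implementation)
    normed = np.zeros_like(f, dtype=np.float64)
    for bi in range(B):
        for y in range(H):
            for x in range(W):
                vec = f[bi, :, y, x].astype(np.float64)
                mu = vec.mean()
                var = ((vec - mu) ** 2).mean()
                normed[bi, :, y, x] = (vec - mu) / math.sqrt(var + 1e-6) * ln_g + ln_b

    # per-pixel expansion C -> 2C, then GELU
    expanded = np.zeros((B, 2 * C, H, W))
    for bi in range(B):
        for o in range(2 * C):
            for y in range(H):
                for x in range(W):
                    expanded[bi, o, y, x] = _gelu(
                        sum(w1[o, c] * normed[bi, c, y, x] for c in range(C)) + b1[o])

    # grid layout (tile index g row-major, within-tile offset p row-major)
    g_axis, p_axis = d * d, th * tw
    gridded = np.zeros((B, 2 * C, g_axis, p_axis))
    for bi in range(B):
        for c in range(2 * C):
            for y in range(H):
                for x in range(W):
                    g = (y // th) * d + (x // tw)
                    p = (y % th) * tw + (x % tw)
                    gridded[bi, c, g, p] = expanded[bi, c, y, x]

    f2, f3 = gridded[:, :C], gridded[:, C:]

    # tile-axis linear map on f2, gated by f3
    gated = np.zeros_like(f2)
    for bi in range(B):
        for c in range(C):
            for o in range(g_axis):
                for p in range(p_axis):
                    mixed = sum(wg[o, g] * f2[bi, c, g, p] for g in range(g_axis)) + bg[o]
                    gated[bi, c, o, p] = mixed * f3[bi, c, o, p]

    # per-position projection C -> C, then ungrid and residual add
    out = np.array(f, dtype=np.float64, copy=True)
    for bi in range(B):
        for o in range(C):
            for g in range(g_axis):
                for p in range(p_axis):
                    proj = sum(w2[o, c] * gated[bi, c, g, p] for c in range(C)) + b2[o]
                    y = (g // d) * th + p // tw
                    x = (g % d) * tw + p % tw
                    out[bi, o, y, x] += proj
    return out
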