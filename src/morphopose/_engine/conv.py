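"""Convolution, pooling and resampling primitives (NCHW layout).

Forward passes use ``sliding_window_view`` + BLAS contractions; backward
passes are written as explicit scatter/contract VJPs.  Only the cases the
networks need are supported: odd square kernels, stride 1 or 2, symmetric
zero padding, groups that evenly divide the channels.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _make, as_tensor

# When not None, every conv2d call appends its multiply-accumulate count here
# (kernel_ops x output positions; bias and BN excluded, matching the fused
# conv-MAC convention of common FLOP profilers).
MAC_TRACE: list | None = None


def _windows(x, k, stride):
    """(N, C, Ho, Wo, k, k) view of padded input ``x``."""
    w = sliding_window_view(x, (k, k), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


def _col2im(gcol, x_shape, k, stride, pad):
    """Scatter window gradients (N, C, Ho, Wo, k, k) back to the input."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    gx = np.zeros((n, c, hp, wp), dtype=gcol.dtype)
    ho, wo = gcol.shape[2], gcol.shape[3]
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gcol[:, :, :, :, i, j]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0, groups: int = 1):
    """2-D cross-correlation.  ``weight``: (Cout, Cin/groups, k, k)."""
    x, weight = as_tensor(x), as_tensor(weight)
    if bias is not None:
        bias = as_tensor(bias)
    n, cin, h, w = x.data.shape
    cout, cin_g, kh, kw = weight.data.shape
    if kh != kw:
        raise ValueError("only square kernels are supported")
    k = kh
    if cin % groups or cout % groups or cin_g != cin // groups:
        raise ValueError(
            f"channel/group mismatch: x has {cin} channels, weight expects {cin_g}x{groups}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    win = _windows(xp, k, stride)  # (N, Cin, Ho, Wo, k, k)
    ho, wo = win.shape[2], win.shape[3]
    if MAC_TRACE is not None:
        MAC_TRACE.append(int(weight.data.size) * ho * wo)

    if groups == 1:
        out = np.tensordot(win, weight.data, axes=([1, 4, 5], [1, 2, 3]))  # (N,Ho,Wo,Cout)
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    elif groups == cin and cin_g == 1:
        # depthwise: weight (Cout=Cin*m, 1, k, k); m==1 in all our nets
        wd = weight.data.reshape(cout, k, k)
        out = np.einsum("ncijhw,chw->ncij", win, wd, optimize=True)
    else:
        cg_in, cg_out = cin // groups, cout // groups
        out = np.empty((n, cout, ho, wo), dtype=x.data.dtype)
        for g in range(groups):
            wg = weight.data[g * cg_out : (g + 1) * cg_out]
            sub = win[:, g * cg_in : (g + 1) * cg_in]
            out[:, g * cg_out : (g + 1) * cg_out] = np.tensordot(
                sub, wg, axes=([1, 4, 5], [1, 2, 3])
            ).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g = np.ascontiguousarray(g)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            if weight.requires_grad:
                gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # (Cout,Cin,k,k)
                weight._accum(gw)
            if x.requires_grad:
                gcol = np.einsum("noij,ochw->ncijhw", g, weight.data, optimize=True)
                x._accum(_col2im(gcol, x.data.shape, k, stride, padding))
        elif groups == cin and cin_g == 1:
            wd = weight.data.reshape(cout, k, k)
            if weight.requires_grad:
                gw = np.einsum("ncij,ncijhw->chw", g, win, optimize=True)
                weight._accum(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gcol = np.einsum("ncij,chw->ncijhw", g, wd, optimize=True)
                x._accum(_col2im(gcol, x.data.shape, k, stride, padding))
        else:
            cg_in, cg_out = cin // groups, cout // groups
            if weight.requires_grad:
                gw = np.empty_like(weight.data)
            gcol = np.empty(win.shape, dtype=g.dtype) if x.requires_grad else None
            for gi in range(groups):
                gg = g[:, gi * cg_out : (gi + 1) * cg_out]
                sub = win[:, gi * cg_in : (gi + 1) * cg_in]
                wg = weight.data[gi * cg_out : (gi + 1) * cg_out]
                if weight.requires_grad:
                    gw[gi * cg_out : (gi + 1) * cg_out] = np.tensordot(
                        gg, sub, axes=([0, 2, 3], [0, 2, 3])
                    )
                if gcol is not None:
                    gcol[:, gi * cg_in : (gi + 1) * cg_in] = np.einsum(
                        "noij,ochw->ncijhw", gg, wg, optimize=True
                    )
            if weight.requires_grad:
                weight._accum(gw)
            if x.requires_grad:
                x._accum(_col2im(gcol, x.data.shape, k, stride, padding))

    return _make(out, parents, backward)


def max_pool2d(x, kernel: int, stride: int = 1, padding: int = 0):
    x = as_tensor(x)
    fill = np.finfo(x.data.dtype).min
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)), constant_values=fill)
        if padding
        else x.data
    )
    win = _windows(xp, kernel, stride)
    n, c, ho, wo = win.shape[:4]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gcol = np.zeros_like(flat)
        np.put_along_axis(gcol, arg[..., None], g[..., None], axis=-1)
        gcol = gcol.reshape(win.shape)
        gx = _col2im(gcol, x.data.shape, kernel, stride, padding)
        x._accum(gx)

    return _make(out, (x,), backward)


def upsample_nearest2(x):
    """Nearest-neighbour 2x upsampling of the last two axes."""
    x = as_tensor(x)
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accum(gx)

    return _make(data, (x,), backward)


def global_avg_pool(x):
    """(N, C, H, W) -> (N, C) spatial mean; the squeeze step of SE blocks."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    data = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x._accum(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy())

    return _make(data, (x,), backward)
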