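"""Structured differentiable operations: convolution, resizing, warping.

Convolutions use an im2col + BLAS matmul forward pass and a slice-accumulate
col2im backward pass; depthwise convolution has a dedicated einsum path so the
(C, kh*kw) weight never expands to a dense (C, C*kh*kw) matrix.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import DTYPE, _make, _t


def _windows(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """Sliding (kh, kw) windows of an (N, C, H, W) array with stride (sh, sw)."""
    N, C, H, W = x.shape
    OH = (H - kh) // sh + 1
    OW = (W - kw) // sw + 1
    s = x.strides
    return as_strided(
        x,
        shape=(N, C, kh, kw, OH, OW),
        strides=(s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw),
    )


def _col2im(dcols: np.ndarray, x_shape: tuple, kh: int, kw: int,
            sh: int, sw: int) -> np.ndarray:
    """Scatter-add window gradients back onto the (padded) input grid."""
    N, C, H, W = x_shape
    OH, OW = dcols.shape[-2:]
    dx = np.zeros(x_shape, dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + sh * OH:sh, j:j + sw * OW:sw] += dcols[:, :, i, j]
    return dx


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0):
    """2-D cross-correlation: x (N,Cin,H,W), weight (Cout,Cin,kh,kw)."""
    x, weight = _t(x), _t(weight)
    bias = _t(bias) if bias is not None else None
    Cout, Cin, kh, kw = weight.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) \
        if padding else x.data
    win = _windows(xp, kh, kw, stride, stride)
    N = xp.shape[0]
    OH, OW = win.shape[-2:]
    cols = win.reshape(N, Cin * kh * kw, OH * OW)  # copies
    W2 = weight.data.reshape(Cout, Cin * kh * kw)
    y = np.matmul(W2, cols).reshape(N, Cout, OH, OW)
    if bias is not None:
        y = y + bias.data.reshape(1, Cout, 1, 1)

    def backward(g):
        g2 = g.reshape(N, Cout, OH * OW)
        if weight.requires_grad:
            dW = np.tensordot(g2, cols, axes=([0, 2], [0, 2]))
            weight._accum(dW.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g2.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(W2.T, g2).reshape(N, Cin, kh, kw, OH, OW)
            dxp = _col2im(dcols, xp.shape, kh, kw, stride, stride)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(y, parents, backward)


def depthwise_conv2d(x, weight, bias=None, padding: int | None = None):
    """Per-channel convolution: x (N,C,H,W), weight (C,kh,kw), stride 1."""
    x, weight = _t(x), _t(weight)
    bias = _t(bias) if bias is not None else None
    C, kh, kw = weight.data.shape
    if padding is None:
        padding = kh // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) \
        if padding else x.data
    win = _windows(xp, kh, kw, 1, 1)
    y = np.einsum("ncijop,cij->ncop", win, weight.data, optimize=True)
    if bias is not None:
        y = y + bias.data.reshape(1, C, 1, 1)

    def backward(g):
        if weight.requires_grad:
            dW = np.einsum("ncop,ncijop->cij", g, win, optimize=True)
            weight._accum(dW)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = weight.data[None, :, :, :, None, None] * g[:, :, None, None]
            dxp = _col2im(dcols, xp.shape, kh, kw, 1, 1)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(y, parents, backward)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel-centre convention)."""
    M = np.zeros((n_out, n_in), dtype=DTYPE)
    for o in range(n_out):
        src = (o + 0.5) * n_in / n_out - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        M[o, min(max(i0, 0), n_in - 1)] += 1.0 - t
        M[o, min(max(i0 + 1, 0), n_in - 1)] += t
    return M


def bilinear_resize(x, out_h: int, out_w: int):
    """Separable bilinear resize of an (N, C, H, W) tensor."""
    x = _t(x)
    N, C, H, W = x.data.shape
    Mr = _interp_matrix(H, out_h)
    Mc = _interp_matrix(W, out_w)
    y = Mr @ x.data @ Mc.T

    def backward(g):
        if x.requires_grad:
            x._accum(Mr.T @ g @ Mc)

    return _make(y, (x,), backward)


def warp(image, dvf):
    """Backward-warp ``image`` by a displacement field.

    output(i, j) = image(i + v(i, j), j + u(i, j)), sampled bilinearly with
    border replication; u = dvf[:, 0] is the horizontal (column) displacement
    and v = dvf[:, 1] the vertical (row) displacement, both in pixels.
    Differentiable with respect to both the image and the field.
    """
    image, dvf = _t(image), _t(dvf)
    N, C, H, W = image.data.shape
    if dvf.data.shape != (N, 2, H, W):
        raise ValueError(f"DVF shape {dvf.data.shape} does not match image {image.data.shape}")

    jj, ii = np.meshgrid(np.arange(W, dtype=DTYPE), np.arange(H, dtype=DTYPE))
    px = jj[None] + dvf.data[:, 0]  # (N, H, W) sample column
    py = ii[None] + dvf.data[:, 1]  # (N, H, W) sample row
    px = np.clip(px, 0.0, W - 1.0)
    py = np.clip(py, 0.0, H - 1.0)
    x0 = np.floor(px).astype(np.int64)
    y0 = np.floor(py).astype(np.int64)
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    tx = (px - x0).astype(DTYPE)
    ty = (py - y0).astype(DTYPE)

    flat = image.data.reshape(N, C, H * W)
    idx00 = (y0 * W + x0)[:, None, :, :].reshape(N, 1, H * W)
    idx01 = (y0 * W + x1)[:, None, :, :].reshape(N, 1, H * W)
    idx10 = (y1 * W + x0)[:, None, :, :].reshape(N, 1, H * W)
    idx11 = (y1 * W + x1)[:, None, :, :].reshape(N, 1, H * W)

    def gather(idx):
        return np.take_along_axis(flat, np.broadcast_to(idx, (N, C, H * W)),
                                  axis=2).reshape(N, C, H, W)

    I00, I01, I10, I11 = gather(idx00), gather(idx01), gather(idx10), gather(idx11)
    w00 = ((1 - tx) * (1 - ty))[:, None]
    w01 = (tx * (1 - ty))[:, None]
    w10 = ((1 - tx) * ty)[:, None]
    w11 = (tx * ty)[:, None]
    y = w00 * I00 + w01 * I01 + w10 * I10 + w11 * I11

    def backward(g):
        if image.requires_grad:
            dflat = np.zeros((N, C, H * W), dtype=DTYPE)
            for idx, w in ((idx00, w00), (idx01, w01), (idx10, w10), (idx11, w11)):
                contrib = (g * w).reshape(N, C, H * W)
                idx_b = np.broadcast_to(idx, (N, C, H * W))
                np.add.at(dflat.reshape(-1), (np.arange(N * C)[:, None] * H * W
                          + idx_b.reshape(N * C, H * W)).ravel(),
                          contrib.reshape(-1))
            image._accum(dflat.reshape(N, C, H, W))
        if dvf.requires_grad:
            # d out / d px and d out / d py, summed over channels
            dpx = ((1 - ty)[:, None] * (I01 - I00) + ty[:, None] * (I11 - I10))
            dpy = ((1 - tx)[:, None] * (I10 - I00) + tx[:, None] * (I11 - I01))
            gu = (g * dpx).sum(axis=1)
            gv = (g * dpy).sum(axis=1)
            # border clamp kills the gradient outside the grid
            gu = np.where((px <= 0) | (px >= W - 1), 0.0, gu)
            gv = np.where((py <= 0) | (py >= H - 1), 0.0, gv)
            dvf._accum(np.stack([gu, gv], axis=1))

    return _make(y, (image, dvf), backward)


def avg_pool2d(x, k: int):
    """Non-overlapping k x k average pooling."""
    x = _t(x)
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError("spatial size must be divisible by the pool size")
    y = x.data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accum(gx.astype(DTYPE))

    return _make(y, (x,), backward)
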