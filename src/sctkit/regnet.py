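"""Registration network and differentiable warping.

Given the synthesized sCT and the (possibly misaligned) planning-CT target,
the registration network predicts a dense 2-D deformation vector field (DVF,
in pixels: component 0 horizontal/column, component 1 vertical/row).
Backward-warping the sCT by the DVF yields the registered sCT (rsCT), which
the intensity/structure losses compare against the pCT target.  The final
DVF layer is zero-initialized so that training starts from the identity
transform; gradients flow through the warp into both networks.

The registration network is a training-time device: at inference the
released product is the synthesizer output itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from ._autodiff import nn as adnn
from ._autodiff import ops as adops
from ._autodiff.tensor import leaky_relu


@dataclass
class RegNetConfig:
    """Encoder-decoder configuration.

    The reference-scale configuration has seven downsampling stages with
    filters (32, 64, 64, 64, 64, 64, 64, 64) and three residual blocks at
    the bottleneck; a shallower profile (fewer stages) can be configured for
    small images, since the input must be divisible by 2^stages (the network
    reflect-pads internally otherwise).
    """

    down_filters: tuple[int, ...] = (32, 64, 64, 64, 64, 64, 64, 64)
    num_residual: int = 3

    @property
    def num_stages(self) -> int:
        return len(self.down_filters) - 1


class _ResidualBlock(adnn.Module):
    def __init__(self, channels, rng):
        self.conv1 = adnn.Conv2d(channels, channels, 3, rng)
        self.conv2 = adnn.Conv2d(channels, channels, 3, rng)

    def forward(self, x):
        h = leaky_relu(self.conv1(x), 0.2)
        return x + self.conv2(h)


class RegNet(adnn.Module):
    """U-Net that maps the 2-channel (sCT, pCT) stack to a 2-channel DVF."""

    def __init__(self, config: RegNetConfig | None = None,
                 rng: np.random.Generator | int = 0):
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.config = config or RegNetConfig()
        f = self.config.down_filters
        self.stem = adnn.Conv2d(2, f[0], 3, rng)
        self.down = adnn.ModuleList(
            [adnn.Conv2d(f[i], f[i + 1], 3, rng, stride=2)
             for i in range(self.config.num_stages)])
        self.residual = adnn.ModuleList(
            [_ResidualBlock(f[-1], rng) for _ in range(self.config.num_residual)])
        self.up = adnn.ModuleList(
            [adnn.Conv2d(f[i + 1], f[i], 3, rng)
             for i in reversed(range(self.config.num_stages))])
        self.fuse = adnn.ModuleList(
            [adnn.Conv2d(2 * f[i], f[i], 3, rng)
             for i in reversed(range(self.config.num_stages))])
        # zero-init: the predicted field starts as the identity transform
        self.head = adnn.Conv2d(f[0], 2, 3, rng, zero_init=True)

    def forward(self, sct: Tensor, pct: Tensor) -> Tensor:
        if sct.shape != pct.shape:
            raise ValueError(f"sct {sct.shape} and pct {pct.shape} must match")
        x = concat([sct, pct], axis=1)
        N, C, H, W = x.shape
        div = 2 ** self.config.num_stages
        ph = (-H) % div
        pw = (-W) % div
        if ph or pw:
            x = _pad_to_multiple(x, div)
        h = leaky_relu(self.stem(x), 0.2)
        skips = []
        for down in self.down:
            skips.append(h)
            h = leaky_relu(down(h), 0.2)
        for blk in self.residual:
            h = blk(h)
        for up, fuse, skip in zip(self.up, self.fuse, reversed(skips)):
            _, _, hh, ww = h.shape
            h = adops.bilinear_resize(h, 2 * hh, 2 * ww)
            h = leaky_relu(up(h), 0.2)
            h = concat([h, skip], axis=1)
            h = leaky_relu(fuse(h), 0.2)
        dvf = self.head(h)
        if ph or pw:
            dvf = dvf[:, :, :H, :W]
        return dvf


def _pad_to_multiple(x: Tensor, div: int) -> Tensor:
    """Reflect-pad the bottom/right edges up to a multiple of ``div``."""
    from ._autodiff.tensor import DTYPE, _make

    N, C, H, W = x.shape
    ph = (-H) % div
    pw = (-W) % div
    ridx = np.concatenate([np.arange(H), H - 2 - np.arange(ph)]).astype(int)
    cidx = np.concatenate([np.arange(W), W - 2 - np.arange(pw)]).astype(int)
    Sr = np.zeros((H + ph, H), dtype=DTYPE)
    Sr[np.arange(H + ph), ridx] = 1.0
    Sc = np.zeros((W + pw, W), dtype=DTYPE)
    Sc[np.arange(W + pw), cidx] = 1.0
    data = x.data[:, :, ridx][:, :, :, cidx]

    def backward(g):
        if x.requires_grad:
            x._accum(Sr.T @ g @ Sc)

    return _make(data, (x,), backward)


def predict_dvf(sct, pct, model: RegNet | None = None,
                config: RegNetConfig | None = None) -> Tensor:
    """Dense DVF at input resolution; deterministic given weights."""
    if model is None:
        model = RegNet(config)
    sct = _as_nchw(sct)
    pct = _as_nchw(pct)
    return model(sct, pct)


def _as_nchw(x) -> Tensor:
    from .io_preprocess import NormalizedImage

    if isinstance(x, NormalizedImage):
        x = x.pixels
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    if x.ndim == 2:
        x = x.reshape((1, 1) + x.shape)
    return x


def warp(image, dvf):
    """Backward-warp ``image`` by ``dvf``: out(p) = image(p + dvf(p)).

    Bilinear interpolation with border replication; differentiable with
    respect to both arguments.  Accepts (H, W) images with (H, W, 2) fields
    or NCHW tensors with (N, 2, H, W) fields.
    """
    arr_in = not isinstance(image, Tensor) and np.asarray(image).ndim == 2
    img = _as_nchw(image)
    d = dvf if isinstance(dvf, Tensor) else Tensor(np.asarray(dvf))
    if d.ndim == 3 and d.shape[-1] == 2:  # (H, W, 2) -> (1, 2, H, W)
        d = d.transpose((2, 0, 1)).reshape((1, 2) + d.shape[:2])
    out = adops.warp(img, d)
    if arr_in:
        return out.data[0, 0]
    return out


def compose_rsct(cbct, pct, synthesizer_model, regnet_model):
    """sCT = synthesize(CBCT); DVF = regnet(sCT, pCT); rsCT = warp(sCT, DVF).

    Returns (sct, dvf, rsct) as tensors with gradients flowing through the
    warp into both networks, enabling joint training.
    """
    x = _as_nchw(cbct)
    y = _as_nchw(pct)
    sct = synthesizer_model(x)
    dvf = regnet_model(sct, y)
    rsct = adops.warp(sct, dvf)
    return sct, dvf, rsct
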