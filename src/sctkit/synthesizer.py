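"""Hybrid CNN-transformer synthesizer mapping a normalized CBCT slice to a
normalized synthetic-CT slice.

The generator is a U-Net: a 1x1 stem produces low-level features, an encoder
of conv + stride-2 downsampling levels feeds a bottleneck stack of
depthwise-convolution transformer blocks (DTBs), and a decoder with skip
connections restores full resolution.  Each DTB applies multihead
depthwise-convolution transposed attention (MDTA) - self-attention computed
across the CHANNEL dimension, so the attention matrix is (C/h) x (C/h) and
cost is linear in the number of pixels - followed by a multiscale
feed-forward network (MSFN) with parallel 3x3 and 5x5 depthwise branches.
The output is a clamped global residual on the input, keeping the
(-1, 1) intensity domain.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat, softmax
from ._autodiff import nn as adnn
from ._autodiff import ops as adops
from ._autodiff.tensor import DTYPE, leaky_relu


@dataclass
class AttentionConfig:
    num_heads: int = 4


@dataclass
class SynthesizerConfig:
    base_channels: int = 32
    encoder_depth: int = 4
    num_dtb: int = 9
    num_heads: int = 4
    msfn_expansion: int = 2
    max_channels: int | None = None  # cap on the doubling (default: 8x base)

    def __post_init__(self):
        if self.num_dtb < 1 or self.encoder_depth < 1:
            raise ValueError("num_dtb and encoder_depth must be >= 1")
        if self.max_channels is None:
            self.max_channels = 8 * self.base_channels

    @property
    def channel_progression(self) -> list[int]:
        return [min(self.base_channels * 2 ** d, self.max_channels)
                for d in range(self.encoder_depth + 1)]


class MDTA(adnn.Module):
    """Multihead depthwise-convolution transposed (channel) attention.

    Q, K, V are produced by a pointwise convolution followed by a 3x3
    depthwise convolution; per head, attention is
    softmax(Q K^T / lambda) V over the channel dimension, with one learnable
    temperature lambda per head (initialized to sqrt(C / heads)).
    """

    def __init__(self, channels: int, num_heads: int, rng: np.random.Generator):
        if channels % num_heads:
            raise ValueError(f"channels ({channels}) must be divisible by "
                             f"num_heads ({num_heads})")
        self.num_heads = num_heads
        self.qkv = adnn.Conv2d(channels, 3 * channels, 1, rng)
        self.qkv_dw = adnn.DepthwiseConv2d(3 * channels, 3, rng)
        self.proj = adnn.Conv2d(channels, channels, 1, rng)
        self.lam = adnn.Parameter(
            np.full((num_heads, 1, 1), np.sqrt(channels / num_heads), dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        h = self.num_heads
        ch = C // h
        qkv = self.qkv_dw(self.qkv(x))  # (N, 3C, H, W)
        qkv = qkv.reshape((N, 3, h, ch, H * W))
        q = qkv[:, 0]  # (N, h, ch, HW)
        k = qkv[:, 1]
        v = qkv[:, 2]
        # channel-by-channel cross covariance: (N, h, ch, ch)
        att = q @ k.transpose((0, 1, 3, 2))
        att = softmax(att * (1.0 / self.lam), axis=-1)
        out = att @ v  # (N, h, ch, HW)
        out = out.reshape((N, C, H, W))
        return self.proj(out)


class MSFN(adnn.Module):
    """Multiscale feed-forward network.

    LayerNorm, 1x1 expansion, then two multiscale extraction rounds: split
    the expanded channels into two halves processed by 3x3 and 5x5 depthwise
    convolutions (GELU-gated), concatenate; finally a 1x1 projection back to
    the input width.
    """

    def __init__(self, channels: int, expansion: int, rng: np.random.Generator):
        ce = channels * expansion
        if ce % 2:
            ce += 1
        self.half = ce // 2
        self.norm = adnn.ChannelLayerNorm(channels)
        self.expand = adnn.Conv2d(channels, ce, 1, rng)
        self.dw3_a = adnn.DepthwiseConv2d(self.half, 3, rng)
        self.dw5_a = adnn.DepthwiseConv2d(ce - self.half, 5, rng)
        self.dw3_b = adnn.DepthwiseConv2d(self.half, 3, rng)
        self.dw5_b = adnn.DepthwiseConv2d(ce - self.half, 5, rng)
        self.proj = adnn.Conv2d(ce, channels, 1, rng)

    def _multiscale(self, x: Tensor, dw3, dw5) -> Tensor:
        from ._autodiff import gelu

        a = x[:, :self.half]
        b = x[:, self.half:]
        return concat([gelu(dw3(a)), gelu(dw5(b))], axis=1)

    def forward(self, x: Tensor) -> Tensor:
        h = self.expand(self.norm(x))
        h = self._multiscale(h, self.dw3_a, self.dw5_a)
        h = self._multiscale(h, self.dw3_b, self.dw5_b)
        return self.proj(h)


class DTB(adnn.Module):
    """Depthwise-convolution transformer block: pre-norm residual MDTA + MSFN."""

    def __init__(self, channels: int, num_heads: int, expansion: int,
                 rng: np.random.Generator):
        self.norm1 = adnn.ChannelLayerNorm(channels)
        self.mdta = MDTA(channels, num_heads, rng)
        self.msfn = MSFN(channels, expansion, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.mdta(self.norm1(x))
        x = x + self.msfn(x)  # MSFN carries its own entry LayerNorm
        return x


class _EncoderLevel(adnn.Module):
    def __init__(self, cin, cout, rng):
        self.conv = adnn.Conv2d(cin, cin, 3, rng)
        self.down = adnn.Conv2d(cin, cout, 3, rng, stride=2)

    def forward(self, x):
        feat = leaky_relu(self.conv(x), 0.2)
        return feat, leaky_relu(self.down(feat), 0.2)


class _DecoderLevel(adnn.Module):
    def __init__(self, cin, cout, rng):
        self.up_conv = adnn.Conv2d(cin, cout, 3, rng)
        self.fuse = adnn.Conv2d(2 * cout, cout, 3, rng)

    def forward(self, x, skip):
        N, C, H, W = x.shape
        x = adops.bilinear_resize(x, 2 * H, 2 * W)
        x = leaky_relu(self.up_conv(x), 0.2)
        x = concat([x, skip], axis=1)
        return leaky_relu(self.fuse(x), 0.2)


class Synthesizer(adnn.Module):
    """U-Net with a DTB bottleneck; single-channel in, single-channel out.

    The output adds a global residual connection from the input and clamps
    to [-1, 1], so the network learns a correction on top of the CBCT and
    starts near the identity mapping.  (A tanh bound composed with the
    residual was found to saturate over the air background - where the HU
    offset correction is largest - and made convergence seed-dependent;
    the clamp keeps full gradient flow inside the intensity domain.)
    """

    def __init__(self, config: SynthesizerConfig | None = None,
                 rng: np.random.Generator | int = 0):
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.config = config or SynthesizerConfig()
        cfg = self.config
        chans = cfg.channel_progression
        self.stem = adnn.Conv2d(1, chans[0], 1, rng)
        self.encoder = adnn.ModuleList(
            [_EncoderLevel(chans[d], chans[d + 1], rng)
             for d in range(cfg.encoder_depth)])
        cb = chans[-1]
        self.bottleneck = adnn.ModuleList(
            [DTB(cb, cfg.num_heads, cfg.msfn_expansion, rng)
             for _ in range(cfg.num_dtb)])
        self.decoder = adnn.ModuleList(
            [_DecoderLevel(chans[d + 1], chans[d], rng)
             for d in reversed(range(cfg.encoder_depth))])
        self.head = adnn.Conv2d(chans[0], 1, 1, rng)
        # small-scale head init: near-identity start (output ~ input), while
        # keeping gradient flow to every upstream parameter from step one
        self.head.weight.data *= 0.01

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        div = 2 ** self.config.encoder_depth
        if H % div or W % div:
            raise ValueError(
                f"spatial size {H}x{W} must be divisible by 2^depth = {div}")
        h = self.stem(x)
        skips = []
        for level in self.encoder:
            feat, h = level(h)
            skips.append(feat)
        for blk in self.bottleneck:
            h = blk(h)
        for level, skip in zip(self.decoder, reversed(skips)):
            h = level(h, skip)
        delta = self.head(h)
        from ._autodiff.tensor import clip_value

        return clip_value(x + delta, -1.0, 1.0)


def synthesize(cbct, config: SynthesizerConfig | None = None,
               model: Synthesizer | None = None):
    """Run a (possibly freshly initialized) synthesizer on one normalized slice.

    ``cbct`` may be a NormalizedImage, a 2-D array or an (N, 1, H, W) tensor;
    returns the same kind of object with pixels in [-1, 1].
    """
    from .io_preprocess import NormalizedImage

    if model is None:
        model = Synthesizer(config)
    if isinstance(cbct, NormalizedImage):
        arr = cbct.pixels
        out = model(Tensor(arr[None, None]))
        from dataclasses import replace

        return replace(cbct, pixels=out.data[0, 0])
    x = cbct if isinstance(cbct, Tensor) else Tensor(np.asarray(cbct))
    if x.ndim == 2:
        x = x.reshape((1, 1) + x.shape)
    return model(x)


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(model: Synthesizer, path: str | Path) -> None:
    """Weights to NPZ plus a JSON sidecar holding the configuration."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"synthesizer": asdict(model.config)}, indent=2))


def load_checkpoint(path: str | Path, rng: int = 0) -> Synthesizer:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = SynthesizerConfig(**json.loads(sidecar.read_text())["synthesizer"])
    model = Synthesizer(cfg, rng=rng)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
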