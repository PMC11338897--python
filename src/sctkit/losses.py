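"""Training losses: perceptual (texture+structure), Charbonnier intensity,
locally normalized cross-correlation, and deformation-field smoothness.

The total objective is

    L = L_perceptual(sCT, pCT) + lam1 * L_intensity(rsCT, pCT)
        + lam2 * L_structure(rsCT, pCT) + lam3 * L_smooth(DVF)

with default weights lam1, lam2, lam3 = 5, 1, 1.  The perceptual term is a
DISTS-style index: per-stage per-channel texture (mean) and structure
(covariance) similarities of deep feature maps, combined with non-negative
weights that sum to one so that D(x, x) = 0.  Because no pretrained VGG
weights can be bundled, the default feature backbone is a fixed-seed frozen
convolutional pyramid with uniform stage weights; it preserves the index's
self-similarity, symmetry and boundedness contracts.

All losses accept numpy arrays or autodiff tensors shaped (H, W), (N, H, W)
or (N, C, H, W) and return a scalar :class:`~sctkit._autodiff.Tensor`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, sqrt
from ._autodiff import ops as adops
from ._autodiff.tensor import DTYPE, _t, clip_value, leaky_relu


def _as4d(x) -> Tensor:
    x = _t(x)
    if x.ndim == 2:
        return x.reshape((1, 1) + x.shape)
    if x.ndim == 3:
        return x.reshape((x.shape[0], 1) + x.shape[1:])
    if x.ndim == 4:
        return x
    raise ValueError(f"expected 2-D..4-D input, got shape {x.shape}")


@dataclass
class LossWeights:
    """Weights of the composite objective (defaults: 5, 1, 1; e = 1e-3)."""

    lam_intensity: float = 5.0
    lam_structure: float = 1.0
    lam_smooth: float = 1.0
    charbonnier_e: float = 1e-3

    def __post_init__(self):
        if min(self.lam_intensity, self.lam_structure, self.lam_smooth) < 0:
            raise ValueError("loss weights must be non-negative")


# ----------------------------------------------------------------- intensity
def intensity_loss(rsct, pct, e: float = 1e-3) -> Tensor:
    """Charbonnier loss: mean over pixels of sqrt((y - x)^2 + e^2).

    A smooth surrogate of the L1 norm; equals ``e`` exactly for identical
    images and approaches the plain mean absolute difference as e -> 0.
    """
    x, y = _as4d(rsct), _as4d(pct)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    d = y - x
    return sqrt(d * d + e * e).mean()


# ----------------------------------------------------------------- structure
def _box_filter(x: Tensor, window: int) -> Tensor:
    from ._autodiff import pad2d

    w = np.full((1, 1, window, window), 1.0 / (window * window), dtype=DTYPE)
    xp = pad2d(x, window // 2, window // 2, mode="reflect")
    return adops.conv2d(xp, Tensor(w), padding=0)


def lncc(x, y, window: int = 9, eps: float = 1e-10) -> Tensor:
    """Mean locally normalized cross-correlation over ``window``-sized
    neighbourhoods (box window); in [-1, 1] up to the eps stabilizer."""
    x, y = _as4d(x), _as4d(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    N, C, H, W = x.shape
    xm = _box_filter(x.reshape((N * C, 1, H, W)), window)
    ym = _box_filter(y.reshape((N * C, 1, H, W)), window)
    x2m = _box_filter((x * x).reshape((N * C, 1, H, W)), window)
    y2m = _box_filter((y * y).reshape((N * C, 1, H, W)), window)
    xym = _box_filter((x * y).reshape((N * C, 1, H, W)), window)
    var_x = clip_value(x2m - xm * xm, 0.0, np.inf)
    var_y = clip_value(y2m - ym * ym, 0.0, np.inf)
    cov = xym - xm * ym
    r = cov * ((var_x * var_y + eps) ** -0.5)
    return r.mean()


def global_ncc(x, y) -> float:
    """Pearson correlation over all pixels (sample statistics, ddof=1).

    This is the printed global form of the structural-similarity measure;
    the windowed :func:`lncc` is the default used for training.
    """
    xa = np.asarray(x.data if isinstance(x, Tensor) else x, dtype=np.float64).ravel()
    ya = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=np.float64).ravel()
    n = xa.size
    sx = xa.std(ddof=1)
    sy = ya.std(ddof=1)
    return float(((xa - xa.mean()) * (ya - ya.mean())).sum() / ((n - 1) * sx * sy))


def structure_loss(rsct, pct, window: int = 9) -> Tensor:
    """1 - LNCC, so that minimization increases local correlation; in [0, 2]."""
    return 1.0 - lncc(rsct, pct, window=window)


# ----------------------------------------------------------------- smoothness
def smooth_loss(dvf) -> Tensor:
    """Mean squared forward-difference gradient of the displacement field.

    ``dvf`` is (N, 2, H, W) (or (2, H, W) / (H, W, 2) for a single field).
    The squared gradient norm sums over the two vector components; forward
    differences are taken over the valid region (no padding) and the
    horizontal- and vertical-derivative means are averaged, so a unit ramp
    in one component scores exactly 0.5.
    """
    d = _t(dvf)
    if d.ndim == 2:
        raise ValueError("a DVF needs a component axis")
    if d.ndim == 3:
        if d.shape[-1] == 2:  # (H, W, 2) -> (1, 2, H, W)
            d = d.transpose((2, 0, 1)).reshape((1, 2) + d.shape[:2])
        else:
            d = d.reshape((1,) + d.shape)
    dx = d[:, :, :, 1:] - d[:, :, :, :-1]
    dy = d[:, :, 1:, :] - d[:, :, :-1, :]
    return 0.5 * ((dx * dx).sum(axis=1).mean() + (dy * dy).sum(axis=1).mean())


# ----------------------------------------------------------------- perceptual
@dataclass
class DISTSConfig:
    """Configuration of the texture/structure perceptual index.

    ``stage_channels`` defines the frozen convolutional pyramid (each stage:
    3x3 conv, stride 2, leaky ReLU) seeded by ``backbone_seed``; stage 0 is
    the raw image.  Stage/channel weights are uniform and jointly normalized
    so their total is 1.
    """

    stage_channels: tuple[int, ...] = (8, 16, 32)
    backbone_seed: int = 1234
    c1: float = 1e-6
    c2: float = 1e-6


class PerceptualLoss:
    """DISTS-style perceptual distance D(x, y) with a frozen feature pyramid.

    D(x, y) = 1 - sum_ij [ alpha_ij * l(x_j^i, y_j^i) + beta_ij * k(x_j^i, y_j^i) ]

    where l compares per-channel global feature means (texture) and k
    per-channel global feature covariances (structure).  With the uniform
    normalized weights, D(x, x) = 0 and D is symmetric.
    """

    def __init__(self, config: DISTSConfig | None = None):
        self.config = config or DISTSConfig()
        rng = np.random.default_rng(self.config.backbone_seed)
        self.weights = []
        cin = 1
        for cout in self.config.stage_channels:
            w = rng.normal(0.0, np.sqrt(2.0 / (cin * 9)),
                           size=(cout, cin, 3, 3)).astype(DTYPE)
            self.weights.append(Tensor(w))  # frozen: requires_grad False
            cin = cout

    def features(self, x: Tensor) -> list[Tensor]:
        feats = [x]
        h = x
        for w in self.weights:
            h = leaky_relu(adops.conv2d(h, w, stride=2, padding=1), 0.2)
            feats.append(h)
        return feats

    def __call__(self, x, y) -> Tensor:
        x, y = _as4d(x), _as4d(y)
        if x.shape != y.shape:
            raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
        c1, c2 = self.config.c1, self.config.c2
        fx = self.features(x)
        fy = self.features(y)
        n_ch = sum(f.shape[1] for f in fx)
        alpha = beta = 1.0 / (2.0 * n_ch)  # sum(alpha) + sum(beta) = 1
        sim = None
        for a, b in zip(fx, fy):
            mx = a.mean(axis=(2, 3), keepdims=True)
            my = b.mean(axis=(2, 3), keepdims=True)
            xc = a - mx
            yc = b - my
            vx = (xc * xc).mean(axis=(2, 3), keepdims=True)
            vy = (yc * yc).mean(axis=(2, 3), keepdims=True)
            cxy = (xc * yc).mean(axis=(2, 3), keepdims=True)
            l_sim = (2.0 * mx * my + c1) / (mx * mx + my * my + c1)
            k_sim = (2.0 * cxy + c2) / (vx + vy + c2)
            contrib = (alpha * l_sim + beta * k_sim).sum(axis=1).mean(axis=(1, 2))
            sim = contrib if sim is None else sim + contrib
        return (1.0 - sim).mean()


def perceptual_loss(sct, pct, config: DISTSConfig | None = None) -> Tensor:
    """Convenience wrapper constructing a :class:`PerceptualLoss` on the fly.

    For training loops, instantiate :class:`PerceptualLoss` once and reuse it.
    """
    return PerceptualLoss(config)(sct, pct)


# ---------------------------------------------------------------------- total
def total_loss(sct, rsct, pct, dvf, weights: LossWeights | None = None,
               perceptual: PerceptualLoss | None = None,
               lncc_window: int = 9,
               perceptual_on_rsct: bool = False) -> tuple[Tensor, dict]:
    """Weighted composite objective plus the raw component values.

    The perceptual term compares sCT to pCT by default (the synthesizer's
    own output, before registration); intensity and structure compare the
    registered rsCT to pCT; smoothness regularizes the DVF.
    """
    weights = weights or LossWeights()
    perceptual = perceptual or PerceptualLoss()
    p_input = rsct if perceptual_on_rsct else sct
    lp = perceptual(p_input, pct)
    li = intensity_loss(rsct, pct, e=weights.charbonnier_e)
    ls = structure_loss(rsct, pct, window=lncc_window)
    lm = smooth_loss(dvf)
    total = lp + weights.lam_intensity * li + weights.lam_structure * ls \
        + weights.lam_smooth * lm
    components = {
        "perceptual": float(lp.data),
        "intensity": float(li.data),
        "structure": float(ls.data),
        "smooth": float(lm.data),
        "total": float(total.data),
    }
    return total, components
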