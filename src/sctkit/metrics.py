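"""HU-scale image-quality metrics, contour agreement, and paired statistics.

MAE, RMSE, PSNR and SSIM are computed on denormalized (HU-scale) images.
``P`` is the full HU window width (3200 HU for the default [-1000, 2200]
window) and enters PSNR directly and SSIM through the standard stabilizing
constants c1 = (0.01 P)^2 and c2 = (0.03 P)^2.  Contour agreement uses the
Dice similarity coefficient and the symmetric mean surface distance (MDA, in
mm).  The comparison harness picks a paired t test when the paired
differences look normal (Shapiro-Wilk) and the Wilcoxon signed-rank test
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .io_preprocess import HUImage

P_DEFAULT = 3200.0  # 2200 - (-1000)


def _as_array(img) -> np.ndarray:
    if isinstance(img, HUImage):
        return img.pixels.astype(np.float64)
    return np.asarray(img, dtype=np.float64)


def _check_pair(a: np.ndarray, b: np.ndarray, mask=None):
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match the images")
    return mask


def mae(img1, img2, mask=None) -> float:
    """Mean absolute HU difference over the mask (default: full image)."""
    a, b = _as_array(img1), _as_array(img2)
    mask = _check_pair(a, b, mask)
    d = np.abs(a - b)
    return float(d[mask].mean() if mask is not None else d.mean())


def rmse(img1, img2, mask=None) -> float:
    """Root-mean-square HU difference."""
    a, b = _as_array(img1), _as_array(img2)
    mask = _check_pair(a, b, mask)
    d = (a - b) ** 2
    return float(np.sqrt(d[mask].mean() if mask is not None else d.mean()))


def psnr(img1, img2, peak: float = P_DEFAULT, mask=None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    r = rmse(img1, img2, mask)
    if r == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak ** 2 / r ** 2))


def ssim(img1, img2, peak: float = P_DEFAULT, sigma: float = 1.5,
         truncate: float = 3.5) -> float:
    """Mean structural similarity over local Gaussian windows.

    Local means, variances and covariance are taken under a Gaussian window
    (sigma 1.5, truncated at 3.5 sigma, i.e. an 11x11 support) with reflect
    boundary handling; the per-window similarity statistic is averaged over
    the interior (the half-window border is cropped, following the original
    SSIM convention).  Symmetric in its arguments; 1 for identical images.
    """
    a, b = _as_array(img1), _as_array(img2)
    _check_pair(a, b)
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2

    def filt(x):
        return ndimage.gaussian_filter(x, sigma, truncate=truncate,
                                       mode="reflect")

    mu1, mu2 = filt(a), filt(b)
    mu1_sq, mu2_sq, mu12 = mu1 * mu1, mu2 * mu2, mu1 * mu2
    var1 = filt(a * a) - mu1_sq
    var2 = filt(b * b) - mu2_sq
    cov = filt(a * b) - mu12
    num = (2 * mu12 + c1) * (2 * cov + c2)
    den = (mu1_sq + mu2_sq + c1) * (var1 + var2 + c2)
    pad = int(truncate * sigma + 0.5)
    s = (num / den)[pad:-pad, pad:-pad] if min(a.shape) > 2 * pad else num / den
    return float(s.mean())


# ------------------------------------------------------------------- contours
@dataclass
class ContourMask:
    """Binary organ mask with pixel spacing in mm."""

    mask: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    label: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


def _mask_of(m) -> np.ndarray:
    return m.mask if isinstance(m, ContourMask) else np.asarray(m, dtype=bool)


def dsc(a, b) -> float:
    """Dice similarity coefficient; two empty masks count as identical."""
    ma, mb = _mask_of(a), _mask_of(b)
    if ma.shape != mb.shape:
        raise ValueError("masks must share a grid")
    sa, sb = int(ma.sum()), int(mb.sum())
    if sa == 0 and sb == 0:
        return 1.0
    return float(2.0 * np.logical_and(ma, mb).sum() / (sa + sb))


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return mask & ~eroded


def mda(a, b, spacing: tuple[float, float] | None = None,
        symmetric: bool = True) -> float:
    """Mean surface distance between two mask boundaries, in mm.

    Default is the symmetric (pooled) form: all boundary-of-A to nearest
    boundary-of-B distances and vice versa, averaged together.  With
    ``symmetric=False`` only the A-to-B direction is averaged.
    """
    ma, mb = _mask_of(a), _mask_of(b)
    if ma.shape != mb.shape:
        raise ValueError("masks must share a grid")
    if spacing is None:
        spacing = a.spacing if isinstance(a, ContourMask) else (1.0, 1.0)
    if not ma.any() or not mb.any():
        raise ValueError("MDA requires two non-empty masks")
    ba, bb = _boundary(ma), _boundary(mb)
    # distance maps to the nearest boundary pixel of the other contour
    dist_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    d_ab = dist_to_b[ba]
    if not symmetric:
        return float(d_ab.mean())
    dist_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
    d_ba = dist_to_a[bb]
    return float(np.concatenate([d_ab, d_ba]).mean())


# ------------------------------------------------------------------ reporting
@dataclass
class ComparisonResult:
    test: str  # "paired t" | "wilcoxon" | "degenerate"
    p_value: float | None
    significant: bool
    statistic: float | None = None


def paired_compare(x, y, alpha: float = 0.05) -> ComparisonResult:
    """Paired comparison with normality-based test selection.

    Shapiro-Wilk (at 0.05) decides whether the paired differences look
    normal; if so a paired t test is used, otherwise the Wilcoxon
    signed-rank test.  Significance is declared at p < ``alpha``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("paired_compare requires two equal 1-D samples, n >= 3")
    d = x - y
    if np.allclose(d, 0.0):
        return ComparisonResult("degenerate", None, False)
    _, p_norm = stats.shapiro(d)
    if p_norm > 0.05:
        t, p = stats.ttest_rel(x, y)
        return ComparisonResult("paired t", float(p), bool(p < alpha), float(t))
    w, p = stats.wilcoxon(x, y)
    return ComparisonResult("wilcoxon", float(p), bool(p < alpha), float(w))


def image_report(pred, ref, peak: float = P_DEFAULT, mask=None) -> dict:
    """MAE/RMSE/PSNR/SSIM for one slice pair, on the HU scale."""
    return {
        "mae": mae(pred, ref, mask),
        "rmse": rmse(pred, ref, mask),
        "psnr": psnr(pred, ref, peak, mask),
        "ssim": ssim(pred, ref, peak),
    }


def cohort_summary(per_patient: list[dict]) -> dict:
    """Cohort mean +/- SD over per-patient metric dicts."""
    keys = per_patient[0].keys()
    out = {}
    for k in keys:
        vals = np.array([p[k] for p in per_patient], dtype=np.float64)
        out[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
                  if len(vals) > 1 else 0.0}
    return out
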