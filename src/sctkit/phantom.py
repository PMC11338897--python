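"""Seeded generator of paired synthetic CT/CBCT data with known ground truth.

Each sample provides the three objects the training framework assumes:

* a clean planning-CT-like slice (``pct``): a body ellipse on an air
  background containing lung-like, fat, soft-tissue and bone components with
  mild smooth texture;
* a degraded CBCT-like slice (``cbct``): the clean slice plus a radial
  cupping bias field, a linear shading gradient, sparse streak lines,
  Gaussian noise and a global HU offset - the artifact families that
  scatter-heavy cone-beam acquisition produces;
* a misaligned training target: the clean slice warped by a smooth random
  deformation field, standing in for the residual error of deformable
  registration in clinical paired datasets.  The true field is returned, so
  registration accuracy can be scored exactly.

Everything is deterministic under (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_preprocess import (HU_MAX_DEFAULT, HU_MIN_DEFAULT, HUImage,
                            NormalizedImage, TrainingPair, clip_hu, normalize)


@dataclass
class TissueComponent:
    name: str
    hu_mean: float
    hu_jitter: float
    count: tuple[int, int]          # inclusive range of instances
    axes_frac: tuple[float, float]  # semi-axis range, fraction of body axes


@dataclass
class PhantomSpec:
    """Geometry and composition of the synthetic anatomy."""

    size: int = 64
    body_axes_frac: tuple[float, float] = (0.42, 0.34)  # (col, row) of size
    body_hu: float = 40.0
    body_hu_jitter: float = 10.0
    texture_sd: float = 20.0
    texture_smooth: float = 1.5
    components: list[TissueComponent] = field(default_factory=lambda: [
        TissueComponent("lung", -700.0, 40.0, (1, 2), (0.15, 0.30)),
        TissueComponent("fat", -100.0, 20.0, (2, 4), (0.10, 0.22)),
        TissueComponent("soft", 60.0, 20.0, (1, 3), (0.08, 0.18)),
        TissueComponent("bone", 700.0, 60.0, (2, 4), (0.06, 0.14)),
    ])

    def __post_init__(self):
        for c in self.components:
            if not HU_MIN_DEFAULT <= c.hu_mean <= HU_MAX_DEFAULT:
                raise ValueError(f"component {c.name} HU mean outside window")
            if c.axes_frac[1] >= 1.0:
                raise ValueError(f"component {c.name} larger than the body")


@dataclass
class DegradationSpec:
    """Amplitudes (HU) of the CBCT artifact families; all must be >= 0."""

    cupping_amplitude: float = 60.0
    shading_amplitude: float = 30.0
    streak_count: int = 6
    streak_amplitude: float = 50.0
    noise_sd: float = 25.0
    hu_offset: float = 20.0

    def __post_init__(self):
        vals = (self.cupping_amplitude, self.shading_amplitude,
                self.streak_amplitude, self.noise_sd)
        if min(vals) < 0 or self.streak_count < 0:
            raise ValueError("degradation amplitudes must be non-negative")


@dataclass
class MisalignmentSpec:
    """Residual-registration-error model: a smooth random field."""

    max_displacement: float = 3.0   # px
    smoothness: float = 8.0         # Gaussian filter scale, px
    cavity_change_prob: float = 0.0  # large local deformation events
    cavity_magnitude: float = 8.0   # px, when an event fires

    def __post_init__(self):
        if self.max_displacement < 0:
            raise ValueError("max displacement must be >= 0")


# ------------------------------------------------------------------ clean pCT
def _ellipse_mask(shape, center, axes, angle, yy, xx) -> np.ndarray:
    cy, cx = center
    ay, ax_ = axes
    ca, sa = np.cos(angle), np.sin(angle)
    yr = (yy - cy) * ca + (xx - cx) * sa
    xr = -(yy - cy) * sa + (xx - cx) * ca
    return (yr / ay) ** 2 + (xr / ax_) ** 2 <= 1.0


def generate_pct(spec: PhantomSpec | None = None,
                 seed: int | np.random.Generator = 0) -> HUImage:
    """One clean CT-like slice; deterministic under the seed."""
    spec = spec or PhantomSpec()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = cx = (n - 1) / 2.0
    ax_ = spec.body_axes_frac[0] * n * rng.uniform(0.92, 1.08)
    ay = spec.body_axes_frac[1] * n * rng.uniform(0.92, 1.08)
    body = _ellipse_mask((n, n), (cy, cx), (ay, ax_), 0.0, yy, xx)

    img = np.full((n, n), HU_MIN_DEFAULT, dtype=np.float64)
    img[body] = spec.body_hu + rng.normal(0.0, spec.body_hu_jitter)

    for comp in spec.components:
        k = int(rng.integers(comp.count[0], comp.count[1] + 1))
        for _ in range(k):
            f = rng.uniform(*comp.axes_frac)
            comp_ay = f * ay
            comp_ax = f * ax_ * rng.uniform(0.7, 1.3)
            # keep the component inside the body ellipse
            u = rng.uniform(0.0, 0.55)
            theta = rng.uniform(0.0, 2 * np.pi)
            ccy = cy + u * ay * np.sin(theta)
            ccx = cx + u * ax_ * np.cos(theta)
            angle = rng.uniform(0.0, np.pi)
            m = _ellipse_mask((n, n), (ccy, ccx), (comp_ay, comp_ax),
                              angle, yy, xx) & body
            img[m] = comp.hu_mean + rng.normal(0.0, comp.hu_jitter)

    texture = gaussian_filter(rng.normal(0.0, spec.texture_sd, size=(n, n)),
                              spec.texture_smooth)
    img[body] += texture[body]
    img = np.clip(img, HU_MIN_DEFAULT, HU_MAX_DEFAULT)
    return HUImage(img)


# --------------------------------------------------------------- degradation
def degrade_to_cbct(pct: HUImage, spec: DegradationSpec | None = None,
                    seed: int | np.random.Generator = 0) -> HUImage:
    """Apply the CBCT artifact model and re-clip to the HU window."""
    spec = spec or DegradationSpec()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    img = pct.pixels.astype(np.float64).copy()
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2

    if spec.cupping_amplitude > 0:
        # cupping: centre suppressed relative to the periphery, zero-mean-ish
        img += spec.cupping_amplitude * (r2 - 0.5)
    if spec.shading_amplitude > 0:
        phi = rng.uniform(0.0, 2 * np.pi)
        plane = ((xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)) / max(h, w)
        img += spec.shading_amplitude * plane
    for _ in range(spec.streak_count):
        angle = rng.uniform(0.0, np.pi)
        offset = rng.uniform(-0.45, 0.45) * max(h, w)
        amp = rng.uniform(0.3, 1.0) * spec.streak_amplitude * rng.choice([-1, 1])
        dist = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle) - offset
        img += amp * np.exp(-0.5 * (dist / 0.8) ** 2)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img += spec.hu_offset
    img = np.clip(img, HU_MIN_DEFAULT, HU_MAX_DEFAULT)
    return HUImage(img, spacing=pct.spacing, origin=pct.origin)


# -------------------------------------------------------------- misalignment
def _smooth_random_dvf(shape, spec: MisalignmentSpec,
                       rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    d = np.zeros((h, w, 2), dtype=np.float64)
    if spec.max_displacement > 0:
        for c in range(2):
            d[..., c] = gaussian_filter(rng.normal(size=(h, w)), spec.smoothness)
        mag = np.sqrt((d ** 2).sum(-1))
        peak = mag.max()
        if peak > 0:
            d *= spec.max_displacement / peak
    if spec.cavity_change_prob > 0 and rng.random() < spec.cavity_change_prob:
        # a localized radial expansion, emulating e.g. organ-fullness change
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        ccy = rng.uniform(0.3, 0.7) * h
        ccx = rng.uniform(0.3, 0.7) * w
        sigma = 0.08 * max(h, w)
        dy = yy - ccy
        dx = xx - ccx
        r = np.sqrt(dy ** 2 + dx ** 2) + 1e-9
        bump = spec.cavity_magnitude * np.exp(-0.5 * (r / sigma) ** 2)
        d[..., 0] += bump * dx / r
        d[..., 1] += bump * dy / r
    return d.astype(np.float32)


def make_misaligned_target(pct: HUImage, spec: MisalignmentSpec | None = None,
                           seed: int | np.random.Generator = 0
                           ) -> tuple[HUImage, np.ndarray]:
    """Warp the clean slice by a smooth random field; return both.

    The returned target satisfies target == warp(pct, dvf) exactly, so the
    misaligned image differs from the clean anatomy only by the known field.
    """
    from .regnet import warp

    spec = spec or MisalignmentSpec()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    dvf = _smooth_random_dvf(pct.shape, spec, rng)
    if not dvf.any():  # degenerate spec: the identity transform, exactly
        return HUImage(pct.pixels.copy(), spacing=pct.spacing,
                       origin=pct.origin), dvf
    warped = warp(pct.pixels, dvf)
    target = HUImage(np.asarray(warped),
                     spacing=pct.spacing, origin=pct.origin)
    return target, dvf


# ------------------------------------------------------------------- dataset
def make_dataset(n: int, phantom_spec: PhantomSpec | None = None,
                 degradation_spec: DegradationSpec | None = None,
                 misalignment_spec: MisalignmentSpec | None = None,
                 seed: int = 0,
                 hu_min: float = HU_MIN_DEFAULT, hu_max: float = HU_MAX_DEFAULT
                 ) -> tuple[list[TrainingPair], dict]:
    """Generate ``n`` fully characterized training pairs plus a manifest.

    Each pair carries: cbct (degraded clean anatomy), pct (misaligned
    training target), clean_pct (ground truth), true_dvf.  All images are
    clipped and normalized to (-1, 1) over the HU window.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    phantom_spec = phantom_spec or PhantomSpec()
    degradation_spec = degradation_spec or DegradationSpec()
    misalignment_spec = misalignment_spec or MisalignmentSpec()
    root = np.random.SeedSequence(seed)
    pairs = []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        pct_clean = generate_pct(phantom_spec, rng)
        cbct = degrade_to_cbct(pct_clean, degradation_spec, rng)
        target, dvf = make_misaligned_target(pct_clean, misalignment_spec, rng)

        def norm(img):
            return normalize(clip_hu(img, hu_min, hu_max), hu_min, hu_max)

        pairs.append(TrainingPair(
            cbct=norm(cbct), pct=norm(target), clean_pct=norm(pct_clean),
            true_dvf=dvf, patient_id=f"phantom-{i:04d}", slice_index=0))
    manifest = {
        "n": n,
        "seed": seed,
        "hu_window": [hu_min, hu_max],
        "phantom_spec": _spec_dict(phantom_spec),
        "degradation_spec": asdict(degradation_spec),
        "misalignment_spec": asdict(misalignment_spec),
    }
    return pairs, manifest


def _spec_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    return d


def save_dataset(path: str | Path, pairs: list[TrainingPair],
                 manifest: dict) -> None:
    """NPZ archive (images + fields) plus a JSON manifest sidecar."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(pairs):
        arrays[f"cbct_{i:04d}"] = p.cbct.pixels
        arrays[f"pct_{i:04d}"] = p.pct.pixels
        if p.clean_pct is not None:
            arrays[f"clean_{i:04d}"] = p.clean_pct.pixels
        if p.true_dvf is not None:
            arrays[f"dvf_{i:04d}"] = p.true_dvf
    np.savez_compressed(path, **arrays)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(manifest, indent=2))


def load_dataset(path: str | Path) -> tuple[list[TrainingPair], dict]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    hu_min, hu_max = manifest.get("hu_window", [HU_MIN_DEFAULT, HU_MAX_DEFAULT])
    window = (hu_min, hu_max)
    pairs = []
    with np.load(path) as data:
        ids = sorted({k.split("_")[1] for k in data.files if k.startswith("cbct_")})
        for i in ids:
            pairs.append(TrainingPair(
                cbct=NormalizedImage(data[f"cbct_{i}"], window=window),
                pct=NormalizedImage(data[f"pct_{i}"], window=window),
                clean_pct=NormalizedImage(data[f"clean_{i}"], window=window)
                if f"clean_{i}" in data.files else None,
                true_dvf=data[f"dvf_{i}"] if f"dvf_{i}" in data.files else None,
                patient_id=f"phantom-{i}"))
    return pairs, manifest
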