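"""Image containers, readers/writers, HU windowing and patch extraction.

The physical-domain representation is :class:`HUImage` (a 2-D axial slice of
Hounsfield-unit intensities with pixel spacing); the network-domain
representation is :class:`NormalizedImage`, linearly mapped to (-1, 1) over a
fixed HU window.  Training samples are :class:`TrainingPair` objects carrying
the degraded CBCT slice and its planning-CT target on a common grid, plus
(for synthetic data) the clean ground-truth CT and the true deformation field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

HU_MIN_DEFAULT = -1000.0
HU_MAX_DEFAULT = 2200.0


class FormatError(ValueError):
    """Unreadable or unrecognized image file."""


class DatasetError(ValueError):
    """Structurally inconsistent image series."""


@dataclass
class HUImage:
    """A 2-D slice of HU intensities with geometric metadata."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)  # (row, col) mm
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("HUImage requires a 2-D pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("HUImage requires finite pixel values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class NormalizedImage:
    """An HU slice mapped linearly to [-1, 1]; keeps the window used."""

    pixels: np.ndarray
    window: tuple[float, float] = (HU_MIN_DEFAULT, HU_MAX_DEFAULT)
    spacing: tuple[float, float] = (1.0, 1.0)
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TrainingPair:
    """(CBCT, target pCT) on a common grid, with optional ground truth."""

    cbct: NormalizedImage
    pct: NormalizedImage
    clean_pct: NormalizedImage | None = None
    true_dvf: np.ndarray | None = None  # (H, W, 2): (horizontal, vertical) px
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        if self.cbct.shape != self.pct.shape:
            raise ValueError("cbct and pct must share an identical grid")


# --------------------------------------------------------------------- window
def clip_hu(img: HUImage, hu_min: float = HU_MIN_DEFAULT,
            hu_max: float = HU_MAX_DEFAULT) -> HUImage:
    """Clamp intensities to [hu_min, hu_max]."""
    if not hu_min < hu_max:
        raise ValueError("hu_min must be < hu_max")
    return replace(img, pixels=np.clip(img.pixels, hu_min, hu_max))


def normalize(img: HUImage, hu_min: float = HU_MIN_DEFAULT,
              hu_max: float = HU_MAX_DEFAULT) -> NormalizedImage:
    """Map a clipped HU slice linearly onto [-1, 1]."""
    p = img.pixels
    if p.min() < hu_min or p.max() > hu_max:
        raise ValueError("image must be clipped to the window before normalize()")
    norm = 2.0 * (p.astype(np.float64) - hu_min) / (hu_max - hu_min) - 1.0
    return NormalizedImage(norm, window=(hu_min, hu_max),
                           spacing=img.spacing, origin=img.origin)


def denormalize(img: NormalizedImage) -> HUImage:
    """Exact linear inverse of :func:`normalize`."""
    if img.window is None:
        raise ValueError("NormalizedImage lacks its HU window provenance")
    hu_min, hu_max = img.window
    hu = (img.pixels.astype(np.float64) + 1.0) / 2.0 * (hu_max - hu_min) + hu_min
    return HUImage(hu, spacing=img.spacing, origin=img.origin)


# -------------------------------------------------------------------- readers
def read_slices(path: str | os.PathLike, fmt: str | None = None) -> list[HUImage]:
    """Read axial slices from an NPZ fixture, a NIfTI file, or a DICOM series.

    3-D volumes are decomposed slice-wise along the last axis (the framework
    is 2-D).  Slices are returned in ascending slice order.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.suffix == ".npz":
            fmt = "npz"
        elif path.name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        else:
            raise FormatError(f"cannot infer format of {path}")
    if fmt == "npz":
        return _read_npz(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom":
        return _read_dicom_series(path)
    raise FormatError(f"unknown format {fmt!r} for {path}")


def _read_npz(path: Path) -> list[HUImage]:
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable NPZ file {path}: {exc}") from exc
    spacing = tuple(np.asarray(arrays.pop("spacing", np.array([1.0, 1.0])))[:2].tolist())
    slices = []
    for key in sorted(k for k in arrays if k.startswith(("slice", "arr"))):
        arr = arrays[key]
        if arr.ndim == 2:
            slices.append(HUImage(arr, spacing=spacing))
        elif arr.ndim == 3:
            slices.extend(HUImage(arr[..., k], spacing=spacing)
                          for k in range(arr.shape[-1]))
        else:
            raise FormatError(f"array {key!r} in {path} is not 2-D or 3-D")
    if not slices:
        raise FormatError(f"no image arrays found in {path}")
    _check_consistent(slices, path)
    return slices


def _read_nifti(path: Path) -> list[HUImage]:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    vol = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[1]) if len(zooms) > 1 else 1.0,
               float(zooms[0]) if zooms else 1.0)
    if vol.ndim == 2:
        return [HUImage(vol, spacing=spacing)]
    if vol.ndim != 3:
        raise FormatError(f"{path}: expected a 2-D or 3-D volume")
    return [HUImage(vol[..., k], spacing=spacing) for k in range(vol.shape[-1])]


def _read_dicom_series(path: Path) -> list[HUImage]:
    import pydicom

    files = sorted(p for p in path.iterdir()
                   if p.is_file() and p.suffix.lower() in (".dcm", ""))
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"unreadable DICOM file {f}: {exc}") from exc
    if not datasets:
        raise FormatError(f"no DICOM files in {path}")
    datasets.sort(key=lambda ds: float(getattr(ds, "ImagePositionPatient",
                                               [0, 0, getattr(ds, "InstanceNumber", 0)])[2]))
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float32) * slope + intercept
        ps = getattr(ds, "PixelSpacing", [1.0, 1.0])
        slices.append(HUImage(hu, spacing=(float(ps[0]), float(ps[1]))))
    _check_consistent(slices, path)
    return slices


def _check_consistent(slices: list[HUImage], path) -> None:
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise DatasetError(f"inconsistent slice shapes {sorted(shapes)} in {path}")


# -------------------------------------------------------------------- writers
def write_npz(path: str | os.PathLike, slices: list[HUImage]) -> None:
    vol = np.stack([s.pixels for s in slices], axis=-1)
    np.savez(path, slices=vol, spacing=np.asarray(slices[0].spacing))


def write_nifti(path: str | os.PathLike, slices: list[HUImage]) -> None:
    import nibabel as nib

    vol = np.stack([s.pixels for s in slices], axis=-1)
    sp = slices[0].spacing
    affine = np.diag([sp[1], sp[0], 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))


# ----------------------------------------------------- patches & augmentation
def _pad_to(arr: np.ndarray, size: int) -> np.ndarray:
    """Reflect-pad the first two axes up to at least ``size``."""
    ph = max(0, size - arr.shape[0])
    pw = max(0, size - arr.shape[1])
    if ph == 0 and pw == 0:
        return arr
    width = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
    width += [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, width, mode="reflect")


def random_patch(pair: TrainingPair, size: int = 256,
                 seed: int | np.random.Generator = 0) -> TrainingPair:
    """Crop one identical random window from every image in the pair.

    Inputs smaller than ``size`` are reflect-padded first, so any pair can be
    cropped to any patch size.  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    arrays = {"cbct": pair.cbct.pixels, "pct": pair.pct.pixels}
    if pair.clean_pct is not None:
        arrays["clean_pct"] = pair.clean_pct.pixels
    if pair.true_dvf is not None:
        arrays["true_dvf"] = pair.true_dvf
    arrays = {k: _pad_to(v, size) for k, v in arrays.items()}
    H, W = arrays["cbct"].shape[:2]
    i = int(rng.integers(0, H - size + 1))
    j = int(rng.integers(0, W - size + 1))
    arrays = {k: np.ascontiguousarray(v[i:i + size, j:j + size])
              for k, v in arrays.items()}
    return TrainingPair(
        cbct=replace(pair.cbct, pixels=arrays["cbct"]),
        pct=replace(pair.pct, pixels=arrays["pct"]),
        clean_pct=replace(pair.clean_pct, pixels=arrays["clean_pct"])
        if pair.clean_pct is not None else None,
        true_dvf=arrays.get("true_dvf"),
        patient_id=pair.patient_id,
        slice_index=pair.slice_index,
    )


def _flip_dvf(d: np.ndarray, axis: int) -> np.ndarray:
    """Flip a (H, W, 2) field spatially and negate the mirrored component."""
    out = np.flip(d, axis=axis).copy()
    comp = 1 if axis == 0 else 0  # axis 0 flips rows -> vertical component
    out[..., comp] = -out[..., comp]
    return out


def _rot90_dvf(d: np.ndarray, k: int) -> np.ndarray:
    """Rotate a (H, W, 2) field by k*90 deg CCW, rotating the vectors too.

    With u = horizontal (col) and v = vertical (row) displacement and numpy's
    rot90 convention, one CCW step maps (u, v) -> (v, -u).
    """
    out = d
    for _ in range(k % 4):
        out = np.rot90(out, 1, axes=(0, 1))
        u, v = out[..., 0].copy(), out[..., 1].copy()
        out = np.stack([v, -u], axis=-1)
    return np.ascontiguousarray(out)


@dataclass
class AugmentOps:
    """One sampled augmentation: flips and a 90-degree rotation count."""

    flip_h: bool = False
    flip_v: bool = False
    rot_k: int = 0


def sample_augmentation(p: float = 0.3,
                        seed: int | np.random.Generator = 0) -> AugmentOps:
    """Draw the augmentation decisions: each op fires with probability p."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    do_h = rng.random() < p
    do_v = rng.random() < p
    do_r = rng.random() < p
    k = int(rng.integers(1, 4)) if do_r else 0
    return AugmentOps(do_h, do_v, k)


def augment(pair: TrainingPair, p: float = 0.3,
            seed: int | np.random.Generator = 0) -> TrainingPair:
    """Random flips and 90-degree rotations, applied jointly to the pair.

    With probability ``p`` each: a horizontal flip, a vertical flip, and a
    rotation by a uniformly drawn multiple of 90 degrees.  The true DVF, when
    present, is re-oriented consistently so that warping commutes with the
    augmentation.  Deterministic under a fixed seed.
    """
    ops = sample_augmentation(p, seed)
    return apply_augmentation(pair, ops)


def apply_augmentation(pair: TrainingPair, ops: AugmentOps) -> TrainingPair:
    """Apply a fixed set of augmentation decisions to every image in the pair."""
    do_h, do_v, k = ops.flip_h, ops.flip_v, ops.rot_k

    def tf_img(a):
        if do_h:
            a = np.flip(a, axis=1)
        if do_v:
            a = np.flip(a, axis=0)
        if k:
            a = np.rot90(a, k, axes=(0, 1))
        return np.ascontiguousarray(a)

    def tf_dvf(d):
        if do_h:
            d = _flip_dvf(d, axis=1)
        if do_v:
            d = _flip_dvf(d, axis=0)
        if k:
            d = _rot90_dvf(d, k)
        return d

    return TrainingPair(
        cbct=replace(pair.cbct, pixels=tf_img(pair.cbct.pixels)),
        pct=replace(pair.pct, pixels=tf_img(pair.pct.pixels)),
        clean_pct=replace(pair.clean_pct, pixels=tf_img(pair.clean_pct.pixels))
        if pair.clean_pct is not None else None,
        true_dvf=tf_dvf(pair.true_dvf) if pair.true_dvf is not None else None,
        patient_id=pair.patient_id,
        slice_index=pair.slice_index,
    )


def train_val_split(items: list, ratio: float = 0.9,
                    seed: int = 0) -> tuple[list, list]:
    """Seeded random split; ``ratio`` is the training fraction."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_train = int(round(len(items) * ratio))
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:]]
    return train, val
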