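"""Phantom generator: determinism, HU ranges, degradation and misalignment."""

import numpy as np
import pytest

from sctkit.metrics import mae, psnr, rmse, ssim
from sctkit.phantom import (DegradationSpec, MisalignmentSpec, PhantomSpec,
                            degrade_to_cbct, generate_pct, load_dataset,
                            make_dataset, make_misaligned_target, save_dataset)


def test_pct_values_within_hu_window():
    img = generate_pct(seed=0)
    assert img.pixels.min() >= -1000.0
    assert img.pixels.max() <= 2200.0


def test_pct_seeded_determinism():
    a = generate_pct(seed=3)
    b = generate_pct(seed=3)
    assert np.array_equal(a.pixels, b.pixels)
    c = generate_pct(seed=4)
    assert not np.array_equal(a.pixels, c.pixels)


def test_pct_contains_multiple_tissue_modes():
    """Across a generated batch, at least air, soft tissue and bone appear."""
    imgs = [generate_pct(seed=s) for s in range(8)]
    allpix = np.concatenate([i.pixels.ravel() for i in imgs])
    hist, edges = np.histogram(allpix, bins=64, range=(-1000, 2200))
    # count well-separated occupied intensity regions
    occupied = edges[:-1][hist > allpix.size * 1e-4]
    spread = np.split(occupied, np.where(np.diff(occupied) > 150)[0] + 1)
    assert len([s for s in spread if len(s)]) >= 3


def test_component_larger_than_body_rejected():
    from sctkit.phantom import TissueComponent

    with pytest.raises(ValueError):
        PhantomSpec(components=[TissueComponent("huge", 0, 0, (1, 1),
                                                (0.5, 1.5))])


def test_degradation_all_zero_spec_is_identity():
    pct = generate_pct(seed=1)
    spec = DegradationSpec(cupping_amplitude=0, shading_amplitude=0,
                           streak_count=0, streak_amplitude=0, noise_sd=0,
                           hu_offset=0)
    out = degrade_to_cbct(pct, spec, seed=2)
    assert np.array_equal(out.pixels, pct.pixels)


def test_degradation_pure_offset_shifts_mae_exactly():
    pct = generate_pct(seed=1)
    # keep away from the clip boundary: interior tissue moves by +30
    spec = DegradationSpec(cupping_amplitude=0, shading_amplitude=0,
                           streak_count=0, streak_amplitude=0, noise_sd=0,
                           hu_offset=30.0)
    out = degrade_to_cbct(pct, spec, seed=2)
    interior = pct.pixels > -900  # clipping only affects the air background
    diff = out.pixels[interior] - pct.pixels[interior]
    assert np.allclose(diff, 30.0, atol=1e-4)


def test_default_degradation_worsens_all_metrics():
    pct = generate_pct(seed=6)
    cbct = degrade_to_cbct(pct, seed=7)
    assert mae(cbct, pct) > 0
    assert rmse(cbct, pct) > 0
    assert ssim(cbct, pct) < 1.0
    assert psnr(cbct, pct) < float("inf")


def test_misalignment_zero_displacement_is_identity():
    pct = generate_pct(seed=2)
    target, dvf = make_misaligned_target(
        pct, MisalignmentSpec(max_displacement=0.0), seed=3)
    assert np.array_equal(target.pixels, pct.pixels)
    assert np.array_equal(dvf, np.zeros_like(dvf))


def test_misalignment_respects_max_magnitude():
    pct = generate_pct(seed=2)
    spec = MisalignmentSpec(max_displacement=4.0)
    _, dvf = make_misaligned_target(pct, spec, seed=9)
    mag = np.sqrt((dvf.astype(np.float64) ** 2).sum(-1))
    assert mag.max() <= 4.0 + 1e-6
    assert mag.max() > 3.9  # scaled so the peak reaches the budget


def test_misaligned_target_is_exact_warp_of_clean():
    from sctkit.regnet import warp

    pct = generate_pct(seed=8)
    target, dvf = make_misaligned_target(pct, seed=4)
    rewarped = np.asarray(warp(pct.pixels, dvf))
    assert np.array_equal(rewarped.astype(np.float32), target.pixels)


def test_make_dataset_counts_and_ground_truth(small_dataset):
    pairs, manifest = small_dataset
    assert len(pairs) == manifest["n"] == 16
    for p in pairs:
        assert p.clean_pct is not None and p.true_dvf is not None
        assert p.cbct.shape == p.pct.shape == p.clean_pct.shape
        assert p.true_dvf.shape == p.cbct.shape + (2,)
        assert np.all(np.abs(p.cbct.pixels) <= 1.0)


def test_make_dataset_determinism_and_manifest_roundtrip(tmp_path):
    a, ma = make_dataset(4, seed=11)
    b, mb = make_dataset(4, seed=11)
    assert ma == mb
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.cbct.pixels, pb.cbct.pixels)
        assert np.array_equal(pa.true_dvf, pb.true_dvf)
    save_dataset(tmp_path / "d.npz", a, ma)
    loaded, mload = load_dataset(tmp_path / "d.npz")
    assert mload["seed"] == 11
    for pa, pl in zip(a, loaded):
        assert np.array_equal(pa.cbct.pixels, pl.cbct.pixels)
        assert np.array_equal(pa.pct.pixels, pl.pct.pixels)


def test_default_degradation_cohort_mae_in_calibrated_band(small_dataset):
    """The frozen default degradation produces a CBCT-vs-clean error of
    clinical order: cohort MAE within [25, 75] HU (band registered once
    from the spec amplitudes: offset 20 + cupping 60 + shading 30 + noise 25
    acting on a mostly-air slice)."""
    pairs, _ = small_dataset
    from sctkit.io_preprocess import denormalize

    maes = [mae(denormalize(p.cbct), denormalize(p.clean_pct)) for p in pairs]
    assert 25.0 <= float(np.mean(maes)) <= 75.0


def test_cavity_change_event_creates_large_local_deformation():
    pct = generate_pct(seed=2)
    spec = MisalignmentSpec(max_displacement=2.0, cavity_change_prob=1.0,
                            cavity_magnitude=8.0)
    _, dvf = make_misaligned_target(pct, spec, seed=5)
    mag = np.sqrt((dvf.astype(np.float64) ** 2).sum(-1))
    assert mag.max() > 5.0  # far beyond the smooth-field budget
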