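"""Schedule, ablation modes, fit loop, validation and checkpointing."""

import numpy as np
import pytest

from sctkit.training import (JointModel, ScheduleConfig,
                             desk_profile, fit, learning_rate,
                             load_checkpoint, save_checkpoint, train_step,
                             validation_loss)
from sctkit._autodiff import nn as adnn

SCHED = ScheduleConfig()  # reference schedule: 1e-4 -> 0.1 @ 50 -> 0 @ 200


def _tiny_cfgs(mode="M1", seed=0, epochs=4):
    cfg, sched = desk_profile(mode=mode, seed=seed, total_epochs=epochs)
    cfg.synthesizer.base_channels = 8
    cfg.synthesizer.num_dtb = 1
    cfg.batch_size = 4
    cfg.val_period = 2
    return cfg, sched


def test_schedule_reference_endpoints():
    assert learning_rate(0, SCHED) == pytest.approx(1e-4)
    assert learning_rate(50, SCHED) == pytest.approx(0.1)
    assert learning_rate(200, SCHED) == pytest.approx(0.0, abs=1e-15)


def test_schedule_continuous_and_peaks_at_warmup_end():
    grid = np.linspace(0, 200, 2001)
    vals = np.array([learning_rate(t, SCHED) for t in grid])
    assert np.max(np.abs(np.diff(vals))) < 5e-3  # no jumps
    assert np.argmax(vals) == np.argmin(np.abs(grid - 50))
    assert np.all(vals <= 0.1 + 1e-12)


def test_schedule_rejects_out_of_range_epoch():
    with pytest.raises(ValueError):
        learning_rate(-1, SCHED)
    with pytest.raises(ValueError):
        learning_rate(201, SCHED)


def test_schedule_linear_warmup_option():
    sched = ScheduleConfig(warmup_shape="linear")
    assert learning_rate(25, sched) == pytest.approx(
        1e-4 + (0.1 - 1e-4) * 0.5)


def test_invalid_schedule_config_rejected():
    with pytest.raises(ValueError):
        ScheduleConfig(lr_init=0.2, lr_max=0.1)
    with pytest.raises(ValueError):
        ScheduleConfig(warmup_end_epoch=300)


def test_m1_does_not_instantiate_regnet():
    cfg, _ = _tiny_cfgs("M1")
    model = JointModel(cfg, rng=0)
    assert model.regnet is None
    cfg4, _ = _tiny_cfgs("M4")
    assert JointModel(cfg4, rng=0).regnet is not None


@pytest.mark.parametrize("mode", ["M1", "M2", "M3", "M4"])
def test_step_zero_losses_identical_across_reruns(small_dataset, mode):
    pairs, _ = small_dataset
    outs = []
    for _ in range(2):
        cfg, _ = _tiny_cfgs(mode)
        model = JointModel(cfg, rng=np.random.default_rng(cfg.seed))
        opt = adnn.Adam(model.parameters(), lr=1e-3,
                        beta1=cfg.beta1, beta2=cfg.beta2)
        outs.append(train_step(model, opt, pairs[:4], cfg))
    assert outs[0] == outs[1]


def test_loss_decreases_over_toy_optimization(small_dataset):
    """Repeated M1 steps on a fixed 8-pair toy set reduce the loss."""
    pairs, _ = small_dataset
    cfg, _ = _tiny_cfgs("M1")
    model = JointModel(cfg, rng=0)
    opt = adnn.Adam(model.parameters(), lr=1e-3,
                    beta1=cfg.beta1, beta2=cfg.beta2)
    batch = pairs[:8]
    first = train_step(model, opt, batch, cfg)["total"]
    last = None
    for _ in range(40):
        last = train_step(model, opt, batch, cfg)["total"]
    assert last < first


def test_fit_split_determinism_and_result(small_dataset):
    pairs, _ = small_dataset
    cfg, sched = _tiny_cfgs("M1", seed=3, epochs=2)
    r1 = fit(pairs, cfg, sched)
    r2 = fit(pairs, cfg, sched)
    assert len(r1.train_pairs) == 14 and len(r1.val_pairs) == 2
    assert [p.patient_id for p in r1.train_pairs] == \
        [p.patient_id for p in r2.train_pairs]
    assert r1.best_val == pytest.approx(r2.best_val, abs=0)
    sd1, sd2 = r1.model.state_dict(), r2.model.state_dict()
    assert all(np.array_equal(sd1[k], sd2[k]) for k in sd1)


def test_validation_requires_pairs(small_dataset):
    pairs, _ = small_dataset
    cfg, _ = _tiny_cfgs("M1")
    model = JointModel(cfg, rng=0)
    with pytest.raises(ValueError):
        validation_loss(model, [], cfg)


def test_checkpoint_only_overwrites_on_improvement(tmp_path, small_dataset):
    """fit() persists a checkpoint exactly when validation improves."""
    pairs, _ = small_dataset
    cfg, sched = _tiny_cfgs("M1", epochs=4)
    ckpt = tmp_path / "best.npz"
    result = fit(pairs, cfg, sched, checkpoint_path=ckpt)
    assert ckpt.exists()
    # the persisted best model reproduces its recorded validation loss
    model, opt, cfg2, sched2, meta = load_checkpoint(ckpt)
    val = validation_loss(model, result.val_pairs, cfg2)
    assert val["intensity"] == pytest.approx(meta["best_val"], abs=1e-6)
    assert val["intensity"] == pytest.approx(result.best_val, abs=1e-6)


def test_checkpoint_full_state_roundtrip(tmp_path, small_dataset):
    """Networks + optimizer state survive serialization bit-exactly."""
    pairs, _ = small_dataset
    cfg, sched = _tiny_cfgs("M4", epochs=2)
    model = JointModel(cfg, rng=0)
    opt = adnn.Adam(model.parameters(), lr=5e-4, beta1=cfg.beta1,
                    beta2=cfg.beta2)
    for _ in range(3):
        train_step(model, opt, pairs[:4], cfg)
    save_checkpoint(tmp_path / "s.npz", model, opt, cfg, sched, 1, 0.5)
    model2, opt2, *_ = load_checkpoint(tmp_path / "s.npz")
    sd1, sd2 = model.state_dict(), model2.state_dict()
    assert all(np.array_equal(sd1[k], sd2[k]) for k in sd1)
    assert opt2.t == opt.t
    assert all(np.array_equal(a, b) for a, b in zip(opt.m, opt2.m))
    # continued training diverges identically from the same state
    c1 = train_step(model, opt, pairs[:4], cfg)
    c2 = train_step(model2, opt2, pairs[:4], cfg)
    assert c1 == c2


def test_non_finite_loss_aborts(small_dataset):
    pairs, _ = small_dataset
    cfg, _ = _tiny_cfgs("M1")
    model = JointModel(cfg, rng=0)
    model.synthesizer.stem.weight.data[:] = np.nan
    opt = adnn.Adam(model.parameters(), lr=1e-3)
    with pytest.raises(FloatingPointError):
        train_step(model, opt, pairs[:2], cfg)
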