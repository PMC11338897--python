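"""Composite loss components: closed-form values, invariances, gradients."""

import numpy as np
import pytest

from sctkit._autodiff import Tensor
from sctkit.losses import (DISTSConfig, LossWeights, PerceptualLoss,
                           global_ncc, intensity_loss, lncc, smooth_loss,
                           structure_loss, total_loss)

from conftest import numerical_gradient


# ------------------------------------------------------------------ intensity
def test_charbonnier_on_identical_images_equals_e(rng):
    x = rng.uniform(-1, 1, (16, 16)).astype(np.float32)
    assert float(intensity_loss(x, x, e=1e-3).data) == pytest.approx(1e-3,
                                                                     rel=1e-6)


def test_charbonnier_constant_difference_closed_form():
    x = np.zeros((8, 8), dtype=np.float32)
    y = np.full((8, 8), 3e-3, dtype=np.float32)
    want = np.sqrt(9e-6 + 1e-6)  # 3.1623e-3
    assert float(intensity_loss(x, y, e=1e-3).data) == pytest.approx(want,
                                                                     rel=1e-5)


def test_charbonnier_lower_bound_and_l1_limit(rng):
    x = rng.uniform(-1, 1, (16, 16)).astype(np.float32)
    y = rng.uniform(-1, 1, (16, 16)).astype(np.float32)
    assert float(intensity_loss(x, y, e=1e-3).data) >= 1e-3
    l1 = float(np.mean(np.abs(x.astype(np.float64) - y)))
    assert float(intensity_loss(x, y, e=1e-8).data) == pytest.approx(l1,
                                                                     abs=1e-6)


def test_intensity_shape_mismatch_raises():
    with pytest.raises(ValueError):
        intensity_loss(np.zeros((4, 4)), np.zeros((5, 5)))


# ------------------------------------------------------------------ structure
def test_lncc_perfect_and_affine_correlation(rng):
    x = rng.normal(0, 1, (32, 32)).astype(np.float32)
    assert float(structure_loss(x, x).data) == pytest.approx(0.0, abs=1e-5)
    y = 2.5 * x + 0.7
    assert float(structure_loss(x, y).data) == pytest.approx(0.0, abs=1e-5)


def test_lncc_near_zero_for_independent_images():
    vals = []
    for seed in range(20):
        g = np.random.default_rng(seed)
        x = g.normal(0, 1, (32, 32)).astype(np.float32)
        y = g.normal(0, 1, (32, 32)).astype(np.float32)
        vals.append(float(lncc(x, y).data))
    assert abs(np.mean(vals)) < 0.05


def test_structure_loss_range(rng):
    x = rng.normal(0, 1, (24, 24)).astype(np.float32)
    y = -x  # perfectly anticorrelated
    v = float(structure_loss(x, y).data)
    assert 0.0 <= v <= 2.0
    assert v == pytest.approx(2.0, abs=1e-4)


def test_global_ncc_matches_printed_sample_form(rng):
    x = rng.normal(0, 1, (16, 16))
    y = 0.5 * x + rng.normal(0, 1, (16, 16))
    want = np.corrcoef(x.ravel(), y.ravel())[0, 1]
    # the (1/(N-1)) sum over standardized products is Pearson's r
    assert global_ncc(x, y) == pytest.approx(want, abs=1e-12)


# ----------------------------------------------------------------- smoothness
def test_smooth_constant_field_is_zero():
    assert float(smooth_loss(np.ones((8, 8, 2), dtype=np.float32)).data) == 0.0


def test_smooth_unit_ramp_scores_half():
    d = np.zeros((8, 8, 2), dtype=np.float32)
    d[..., 0] = np.arange(8, dtype=np.float32)[None, :]  # u = column index
    assert float(smooth_loss(d).data) == pytest.approx(0.5, abs=1e-7)


def test_smooth_non_negative(rng):
    d = rng.normal(0, 2, (2, 2, 12, 12)).astype(np.float32)
    assert float(smooth_loss(d).data) >= 0.0


# ----------------------------------------------------------------- perceptual
def test_perceptual_self_distance_is_zero(rng):
    loss = PerceptualLoss()
    x = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
    assert float(loss(x, x).data) == pytest.approx(0.0, abs=1e-6)


def test_perceptual_symmetry(rng):
    loss = PerceptualLoss()
    x = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
    y = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
    assert float(loss(x, y).data) == pytest.approx(float(loss(y, x).data),
                                                   abs=1e-6)


def test_perceptual_matches_formula_walk_oracle(rng):
    """Recompute D(x, y) straight from the per-stage texture/structure
    similarity formula using independently extracted features."""
    cfg = DISTSConfig(stage_channels=(4, 8), backbone_seed=77)
    loss = PerceptualLoss(cfg)
    x = rng.uniform(-1, 1, (16, 16)).astype(np.float32)
    y = rng.uniform(-1, 1, (16, 16)).astype(np.float32)

    fx = [f.data.astype(np.float64) for f in loss.features(Tensor(x[None, None]))]
    fy = [f.data.astype(np.float64) for f in loss.features(Tensor(y[None, None]))]
    n_ch = sum(f.shape[1] for f in fx)
    alpha = beta = 1.0 / (2 * n_ch)
    total_sim = 0.0
    for a, b in zip(fx, fy):
        for c in range(a.shape[1]):
            fa, fb = a[0, c].ravel(), b[0, c].ravel()
            mx, my = fa.mean(), fb.mean()
            vx, vy = fa.var(), fb.var()
            cxy = ((fa - mx) * (fb - my)).mean()
            l_sim = (2 * mx * my + cfg.c1) / (mx ** 2 + my ** 2 + cfg.c1)
            k_sim = (2 * cxy + cfg.c2) / (vx + vy + cfg.c2)
            total_sim += alpha * l_sim + beta * k_sim
    want = 1.0 - total_sim
    assert float(loss(x, y).data) == pytest.approx(want, abs=1e-5)


def test_perceptual_bounded_for_normalized_weights(rng):
    loss = PerceptualLoss()
    for seed in range(5):
        g = np.random.default_rng(seed)
        x = g.uniform(-1, 1, (32, 32)).astype(np.float32)
        y = g.uniform(-1, 1, (32, 32)).astype(np.float32)
        v = float(loss(x, y).data)
        assert -1e-6 <= v <= 2.0 + 1e-6  # similarities lie in [-1, 1]


# ---------------------------------------------------------------------- total
def test_total_loss_weighted_arithmetic(rng):
    """With weights (5, 1, 1) the total is p + 5*i + s + m."""
    x = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
    y = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
    dvf = rng.normal(0, 1, (32, 32, 2)).astype(np.float32)
    perc = PerceptualLoss()
    total, comps = total_loss(x, x, y, dvf, perceptual=perc)
    want = comps["perceptual"] + 5 * comps["intensity"] \
        + comps["structure"] + comps["smooth"]
    assert comps["total"] == pytest.approx(want, rel=1e-6)
    assert float(total.data) == pytest.approx(want, rel=1e-6)


def test_total_loss_zero_weights_reduces_to_perceptual(rng):
    x = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
    y = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
    dvf = rng.normal(0, 1, (32, 32, 2)).astype(np.float32)
    perc = PerceptualLoss()
    w = LossWeights(lam_intensity=0, lam_structure=0, lam_smooth=0)
    total, comps = total_loss(x, x, y, dvf, weights=w, perceptual=perc)
    assert float(total.data) == pytest.approx(comps["perceptual"], rel=1e-6)


def test_total_loss_gradient_matches_finite_differences(rng):
    """Autodiff gradient of the composite loss w.r.t. the synthesis."""
    y = rng.uniform(-0.5, 0.5, (8, 8)).astype(np.float32)
    dvf = rng.normal(0, 0.3, (8, 8, 2)).astype(np.float32)
    x0 = rng.uniform(-0.5, 0.5, (8, 8)).astype(np.float32)
    perc = PerceptualLoss(DISTSConfig(stage_channels=(4,)))

    xt = Tensor(x0, requires_grad=True)
    total, _ = total_loss(xt, xt, y, dvf, perceptual=perc)
    total.backward()
    ana = xt.grad.astype(np.float64)

    def f(xv):
        t, _ = total_loss(Tensor(xv), Tensor(xv), y, dvf, perceptual=perc)
        return float(t.data)

    num = numerical_gradient(f, x0, eps=1e-3)
    denom = np.maximum(np.abs(num), 1e-2)
    assert np.max(np.abs(ana - num) / denom) < 2.5e-2

    # and each component individually, at a tighter tolerance
    from sctkit.losses import intensity_loss, smooth_loss, structure_loss

    for fn in (lambda x: perc(x, y), lambda x: intensity_loss(x, y),
               lambda x: structure_loss(x, y)):
        xt = Tensor(x0, requires_grad=True)
        fn(xt).backward()
        ana_c = xt.grad.astype(np.float64)
        num_c = numerical_gradient(lambda v: float(fn(Tensor(v)).data), x0,
                                   eps=1e-3)
        err = np.abs(ana_c - num_c) / np.maximum(np.abs(num_c), 1e-2)
        assert np.max(err) < 5e-3


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        LossWeights(lam_intensity=-1.0)
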