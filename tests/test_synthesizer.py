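"""Channel-attention transformer blocks and the U-Net generator."""

import numpy as np
import pytest

from sctkit._autodiff import Tensor, softmax
from sctkit.synthesizer import (DTB, MDTA, MSFN, Synthesizer,
                                SynthesizerConfig, load_checkpoint,
                                save_checkpoint, synthesize)


def _np_pointwise(x, w, b):
    # x (N,C,H,W), w (Cout,Cin,1,1)
    y = np.einsum("oc,nchw->nohw", w[:, :, 0, 0], x)
    return y + b.reshape(1, -1, 1, 1)


def _np_depthwise3(x, w, b):
    # zero-padded 3x3 depthwise cross-correlation
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.zeros_like(x)
    for i in range(3):
        for j in range(3):
            y += w[None, :, i, j, None, None] * xp[:, :, i:i + H, j:j + W]
    return y + b.reshape(1, -1, 1, 1)


def mdta_oracle(module: MDTA, x: np.ndarray) -> np.ndarray:
    """Literal per-head channel attention: softmax(Q K^T / lambda) V."""
    qkv = _np_pointwise(x, module.qkv.weight.data, module.qkv.bias.data)
    qkv = _np_depthwise3(qkv, module.qkv_dw.weight.data, module.qkv_dw.bias.data)
    N, C3, H, W = qkv.shape
    C = C3 // 3
    h = module.num_heads
    ch = C // h
    out = np.zeros((N, C, H, W), dtype=np.float64)
    for n in range(N):
        flat = qkv[n].reshape(3, h, ch, H * W)
        for head in range(h):
            Q, K, V = flat[0, head], flat[1, head], flat[2, head]
            lam = float(module.lam.data[head].ravel()[0])
            A = Q @ K.T / lam  # (ch, ch) - independent of H*W
            A = np.exp(A - A.max(axis=1, keepdims=True))
            A /= A.sum(axis=1, keepdims=True)
            out[n, head * ch:(head + 1) * ch] = (A @ V).reshape(ch, H, W)
    return _np_pointwise(out, module.proj.weight.data, module.proj.bias.data)


def test_mdta_matches_per_head_bruteforce_oracle(rng):
    x = rng.normal(0, 1, (2, 8, 8, 8)).astype(np.float32)
    module = MDTA(8, 2, np.random.default_rng(0))
    got = module(Tensor(x)).data
    want = mdta_oracle(module, x)
    assert np.max(np.abs(got - want)) < 1e-5


def test_mdta_single_channel_single_head_returns_projected_v(rng):
    """With C=1 the attention matrix is the scalar 1, so attention out = V."""
    x = rng.normal(0, 1, (1, 1, 6, 6)).astype(np.float32)
    module = MDTA(1, 1, np.random.default_rng(1))
    got = module(Tensor(x)).data
    qkv = _np_pointwise(x, module.qkv.weight.data, module.qkv.bias.data)
    qkv = _np_depthwise3(qkv, module.qkv_dw.weight.data, module.qkv_dw.bias.data)
    v = qkv[:, 2:3]
    want = _np_pointwise(v, module.proj.weight.data, module.proj.bias.data)
    assert np.max(np.abs(got - want)) < 1e-5


def test_softmax_attention_rows_normalize(rng):
    a = Tensor(rng.normal(0, 3, (2, 4, 5, 5)).astype(np.float32))
    s = softmax(a, axis=-1).data
    assert np.max(np.abs(s.sum(axis=-1) - 1.0)) < 1e-6


def test_attention_matrix_is_channel_sized_not_pixel_sized(rng):
    """The (C/h)x(C/h) attention map is identical in shape for 32x32 and
    128x128 inputs: channel attention cost is linear in pixels."""
    shapes = []
    for size in (32, 128):
        module = MDTA(8, 2, np.random.default_rng(0))
        x = Tensor(rng.normal(0, 1, (1, 8, size, size)).astype(np.float32))
        N, C, H, W = x.shape
        h = module.num_heads
        ch = C // h
        qkv = module.qkv_dw(module.qkv(x)).reshape((N, 3, h, ch, H * W))
        att = qkv[:, 0] @ qkv[:, 1].transpose((0, 1, 3, 2))
        shapes.append(att.shape)
    assert shapes[0] == shapes[1] == (1, 2, 4, 4)


def test_mdta_rejects_indivisible_channels():
    with pytest.raises(ValueError):
        MDTA(6, 4, np.random.default_rng(0))


def test_msfn_preserves_shape_and_is_deterministic(rng):
    module = MSFN(8, expansion=2, rng=np.random.default_rng(2))
    x = Tensor(rng.normal(0, 1, (2, 8, 8, 8)).astype(np.float32))
    a = module(x).data
    b = module(x).data
    assert a.shape == x.shape
    assert np.array_equal(a, b)


def test_msfn_branch_channel_split(rng):
    """Expanded channels are split in half across the 3x3 and 5x5 branches."""
    module = MSFN(8, expansion=2, rng=np.random.default_rng(2))
    assert module.expand.weight.shape[0] == 16
    assert module.dw3_a.weight.shape == (8, 3, 3)
    assert module.dw5_a.weight.shape == (8, 5, 5)
    assert module.proj.weight.shape[:2] == (8, 16)


def test_dtb_residual_identity_with_zeroed_projections(rng):
    module = DTB(8, 2, 2, np.random.default_rng(3))
    module.mdta.proj.weight.data[:] = 0.0
    module.mdta.proj.bias.data[:] = 0.0
    module.msfn.proj.weight.data[:] = 0.0
    module.msfn.proj.bias.data[:] = 0.0
    x = Tensor(rng.normal(0, 1, (1, 8, 8, 8)).astype(np.float32))
    assert np.array_equal(module(x).data, x.data)


def test_stacked_dtbs_compose_sequentially(rng):
    blocks = [DTB(8, 2, 2, np.random.default_rng(i)) for i in range(3)]
    x = Tensor(rng.normal(0, 1, (1, 8, 16, 16)).astype(np.float32))
    h = x
    for blk in blocks:
        h = blk(h)
    stacked = h.data
    h2 = x
    for blk in blocks:
        h2 = blk(h2)
    assert stacked.shape == x.shape
    assert np.array_equal(stacked, h2.data)


@pytest.mark.parametrize("size", [64, 32])
def test_synthesizer_output_shape_and_bounds(rng, size):
    cfg = SynthesizerConfig(base_channels=8, encoder_depth=3, num_dtb=2,
                            num_heads=2)
    model = Synthesizer(cfg, rng=0)
    x = Tensor(rng.uniform(-1, 1, (1, 1, size, size)).astype(np.float32))
    y = model(x).data
    assert y.shape == x.shape
    assert np.all(y >= -1.0) and np.all(y <= 1.0)


def test_synthesizer_rejects_indivisible_spatial_size(rng):
    model = Synthesizer(SynthesizerConfig(base_channels=8, encoder_depth=3,
                                          num_dtb=1, num_heads=2), rng=0)
    with pytest.raises(ValueError):
        model(Tensor(rng.uniform(-1, 1, (1, 1, 36, 36)).astype(np.float32)))


def test_gradient_reaches_every_parameter(rng):
    cfg = SynthesizerConfig(base_channels=8, encoder_depth=2, num_dtb=1,
                            num_heads=2)
    model = Synthesizer(cfg, rng=1)
    x = Tensor(rng.uniform(-1, 1, (2, 1, 16, 16)).astype(np.float32))
    loss = (model(x) * model(x)).mean()
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, f"no gradient for {name}"
        assert np.all(np.isfinite(p.grad)), f"non-finite gradient for {name}"
        # zero-initialized output head weight legitimately gets gradient too
        if "head" not in name and "lam" not in name and "beta" not in name:
            assert np.any(p.grad != 0.0), f"all-zero gradient for {name}"


def test_checkpoint_roundtrip(tmp_path, rng):
    cfg = SynthesizerConfig(base_channels=8, encoder_depth=2, num_dtb=1,
                            num_heads=2)
    model = Synthesizer(cfg, rng=4)
    save_checkpoint(model, tmp_path / "syn.npz")
    loaded = load_checkpoint(tmp_path / "syn.npz")
    x = Tensor(rng.uniform(-1, 1, (1, 1, 16, 16)).astype(np.float32))
    assert np.array_equal(model(x).data, loaded(x).data)


def test_synthesize_accepts_normalized_image(rng):
    from sctkit.io_preprocess import NormalizedImage

    img = NormalizedImage(rng.uniform(-1, 1, (32, 32)).astype(np.float32))
    cfg = SynthesizerConfig(base_channels=8, encoder_depth=2, num_dtb=1,
                            num_heads=2)
    out = synthesize(img, model=Synthesizer(cfg, rng=0))
    assert isinstance(out, NormalizedImage)
    assert out.shape == (32, 32)
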