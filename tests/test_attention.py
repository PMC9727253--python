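"""Unit and property tests for the dual attention-fusion math."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eegfusion import (
    DAFMParams,
    apply_attention,
    attention_forward,
    compress_spatial,
    compress_temporal,
    fuse_attention,
    initial_conv,
    residual_combine,
    spatial_attention,
    temporal_attention,
)
from eegfusion._layers import AttentionFusion

from _oracles import naive_attention_forward


def _params(H, W, seed=0, gamma=0.0, **kw):
    return DAFMParams.init(H, W, seed=seed, gamma=gamma, **kw)


# ---------------------------------------------------------------------
# softmax attention maps


@pytest.mark.parametrize(
    "logits,expected",
    [
        (np.array([0.0, np.log(3.0)]), np.array([0.25, 0.75])),
        (np.array([0.0, 0.0, np.log(2.0), 0.0]), np.array([0.2, 0.2, 0.4, 0.2])),
        (np.zeros(5), np.full(5, 0.2)),
    ],
)
def test_softmax_attention_hand_computed(logits, expected):
    # feed logits through the attention op with v = 1 so logit_i = c_i
    a = spatial_attention(logits[:, None, None], np.ones_like(logits))
    np.testing.assert_allclose(a, expected, atol=1e-12)
    a = temporal_attention(logits[None, :, None], np.ones_like(logits))
    np.testing.assert_allclose(a, expected, atol=1e-12)


def test_softmax_saturation():
    logits = np.array([0.0, 500.0, 0.0])
    a = spatial_attention(logits[:, None, None], np.ones(3))
    assert a[1] > 1.0 - 1e-12 and np.isfinite(a).all()


@given(st.integers(0, 10_000), st.floats(-100.0, 100.0))
def test_softmax_shift_invariance(seed, shift):
    rng = np.random.default_rng(seed)
    c = rng.standard_normal(6)
    a = spatial_attention(c[:, None, None], np.ones(6))
    b = spatial_attention((c + shift)[:, None, None], np.ones(6))
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_attention_rejects_nonfinite_logits():
    c = np.array([0.0, np.inf, 0.0])
    with pytest.raises(FloatingPointError, match="index 1"):
        spatial_attention(c[:, None, None], np.ones(3))


# ---------------------------------------------------------------------
# initial convolution and compression


def test_initial_conv_identity_kernel(rng):
    A = rng.standard_normal((6, 9))
    p = _params(6, 9)
    B = initial_conv(A, p)
    assert B.shape == (6, 9, 1)
    np.testing.assert_array_equal(B[:, :, 0], A)


def test_initial_conv_scalar_kernel_matches_multiply(rng):
    A = rng.standard_normal((4, 7))
    p = _params(4, 7)
    p.initial_conv_weights = np.array([[-2.5]])
    np.testing.assert_allclose(initial_conv(A, p)[:, :, 0], -2.5 * A, rtol=1e-12)


def test_initial_conv_preserves_mi_shape(rng):
    A = rng.standard_normal((22, 1000))
    assert initial_conv(A, _params(22, 1000)).shape == (22, 1000, 1)


def test_initial_conv_rejects_nonfinite():
    A = np.zeros((2, 3))
    A[1, 2] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        initial_conv(A, _params(2, 3))


def test_compress_shapes_speller_geometry(rng):
    B = rng.standard_normal((10, 144, 1))
    assert compress_spatial(B, rng.standard_normal(144)).shape == (10, 1, 1)
    assert compress_temporal(B, rng.standard_normal(10)).shape == (1, 144, 1)


def test_compress_averaging_kernel_is_mean(rng):
    B = rng.standard_normal((5, 8, 1))
    c = compress_spatial(B, np.full(8, 1.0 / 8.0))
    np.testing.assert_allclose(c[:, 0, 0], B[:, :, 0].mean(axis=1), rtol=1e-12)


def test_compress_matches_explicit_loops(rng):
    B = rng.standard_normal((4, 6, 1))
    wc, wd = rng.standard_normal(6), rng.standard_normal(4)
    c = compress_spatial(B, wc, 0.3)
    d = compress_temporal(B, wd, -0.2)
    for h in range(4):
        assert c[h, 0, 0] == pytest.approx(
            sum(B[h, w, 0] * wc[w] for w in range(6)) + 0.3, rel=1e-12
        )
    for w in range(6):
        assert d[0, w, 0] == pytest.approx(
            sum(B[h, w, 0] * wd[h] for h in range(4)) - 0.2, rel=1e-12
        )


# ---------------------------------------------------------------------
# fusion, weighting, residual


def test_fuse_one_hot_outer_product():
    a = fuse_attention(np.array([1.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    np.testing.assert_array_equal(a, [[0.0, 1.0, 0.0], [0.0, 0.0, 0.0]])


def test_fuse_uniform_is_constant():
    a = fuse_attention(np.full(4, 0.25), np.full(5, 0.2))
    np.testing.assert_allclose(a, 1.0 / 20.0)


def test_fuse_matches_double_loop(rng):
    a1 = rng.dirichlet(np.ones(5))
    a2 = rng.dirichlet(np.ones(7))
    a = fuse_attention(a1, a2)
    for h in range(5):
        for w in range(7):
            assert abs(a[h, w] - a1[h] * a2[w]) < 1e-12
    assert a.sum() == pytest.approx(1.0, abs=1e-12)


def test_apply_attention_identity_and_mask(rng):
    B = rng.standard_normal((3, 4, 1))
    np.testing.assert_array_equal(apply_attention(np.ones((3, 4)), B), B)
    mask = np.zeros((3, 4))
    mask[1, 2] = 1.0
    E = apply_attention(mask, B)
    assert E[1, 2, 0] == B[1, 2, 0]
    assert np.count_nonzero(E) <= 1


def test_apply_attention_matches_triple_loop(rng):
    B = rng.standard_normal((3, 5, 1))
    a = rng.random((3, 5))
    E = apply_attention(a, B)
    for h in range(3):
        for w in range(5):
            assert E[h, w, 0] == pytest.approx(a[h, w] * B[h, w, 0], rel=1e-12)


def test_residual_identity_and_linearity(rng):
    B = rng.standard_normal((4, 6, 1))
    E = rng.standard_normal((4, 6, 1))
    np.testing.assert_array_equal(residual_combine(E, B, 0.0), B)
    np.testing.assert_allclose(residual_combine(B, B, 1.0), 2.0 * B, rtol=1e-12)
    np.testing.assert_allclose(residual_combine(E, B, 0.5), 0.5 * E + B, rtol=1e-12)


# ---------------------------------------------------------------------
# full forward pass


@pytest.mark.parametrize("H,W", [(3, 5), (5, 8)])
def test_forward_matches_naive_oracle(H, W, rng):
    for trial in range(10):
        A = 5.0 * rng.standard_normal((H, W))
        p = _params(H, W, seed=trial, gamma=rng.uniform(-1, 1))
        Z, maps = attention_forward(A, p)
        Zn, a1n, a2n, fn = naive_attention_forward(A.tolist(), p)
        np.testing.assert_allclose(Z[:, :, 0], Zn, atol=1e-6)
        np.testing.assert_allclose(maps.a1, a1n, atol=1e-9)
        np.testing.assert_allclose(maps.a2, a2n, atol=1e-9)
        np.testing.assert_allclose(maps.fused, fn, atol=1e-9)


def test_forward_gamma_zero_is_identity_on_B(rng):
    A = rng.standard_normal((6, 10))
    Z, _ = attention_forward(A, _params(6, 10, gamma=0.0))
    np.testing.assert_array_equal(Z[:, :, 0], A)  # identity initial conv, gamma 0


def test_forward_speller_shape(rng):
    Z, maps = attention_forward(rng.standard_normal((10, 144)), _params(10, 144))
    assert Z.shape == (10, 144, 1)
    assert maps.fused.shape == (10, 144)


@given(st.integers(0, 10_000))
def test_attention_map_invariants(seed):
    rng = np.random.default_rng(seed)
    H = int(rng.integers(1, 8))
    W = int(rng.integers(1, 12))
    A = 50.0 * rng.standard_normal((H, W))
    p = _params(H, W, seed=seed, gamma=rng.normal(), attention_scale=rng.uniform(0.01, 10))
    _, maps = attention_forward(A, p)
    assert maps.a1.sum() == pytest.approx(1.0, abs=1e-6)
    assert maps.a2.sum() == pytest.approx(1.0, abs=1e-6)
    assert maps.fused.sum() == pytest.approx(1.0, abs=1e-6)
    assert (maps.a1 >= 0).all() and (maps.a2 >= 0).all() and (maps.fused >= 0).all()
    s = np.linalg.svd(maps.fused, compute_uv=False)
    if len(s) > 1:
        assert s[1] < 1e-6 * s[0]


# ---------------------------------------------------------------------
# batched trainable layer


def test_layer_matches_functional_reference(rng):
    H, W = 4, 7
    layer = AttentionFusion(H, W, np.random.default_rng(3), gamma_init=0.6)
    p = _params(H, W)
    p.spatial_compress_weights = layer.params["wc"].copy()
    p.temporal_compress_weights = layer.params["wd"].copy()
    p.v, p.w = layer.params["v"].copy(), layer.params["w"].copy()
    p.gamma = 0.6
    X = rng.standard_normal((5, H, W))
    out = layer.forward(X[..., None])
    for i in range(5):
        Z, _ = attention_forward(X[i], p)
        np.testing.assert_allclose(out[i], Z, atol=1e-12)


def test_attention_gradients_match_finite_differences(rng):
    """Central finite differences on every attention parameter."""
    H, W = 3, 5
    layer = AttentionFusion(H, W, np.random.default_rng(7), gamma_init=0.4)
    X = rng.standard_normal((2, H, W, 1))
    G = rng.standard_normal((2, H, W, 1))  # fixed weights for a scalar loss

    def loss():
        return float(np.sum(layer.forward(X) * G))

    base = loss()
    layer.zero_grads()
    layer.backward(G)
    eps = 1e-6
    for name, p in layer.params.items():
        flat = p.reshape(-1) if p.ndim else p.reshape(1)
        grad = layer.grads[name].reshape(-1) if p.ndim else layer.grads[name].reshape(1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - grad[i]) <= 1e-4 * max(abs(fd), abs(grad[i]), 1e-8), (
                f"gradient mismatch for {name}[{i}]: fd={fd}, analytic={grad[i]}"
            )
    assert np.isfinite(base)
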