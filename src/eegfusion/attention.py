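"""Dual spatial-temporal attention fusion for EEG epochs.

Given an epoch ``A`` with ``H`` electrodes and ``W`` time points, the module
recodes it in five steps:

1. an initial convolution produces a feature map ``B`` (one map, ``C = 1``);
2. ``B`` is compressed along time to a per-channel summary ``c`` (shape
   ``H x 1 x C``) and along channels to a per-timepoint summary ``d``
   (``1 x W x C``) by convolutions whose kernels span the collapsed axis;
3. each summary is combined with a trainable attention vector (``v`` over
   channels, ``w`` over time) and passed through a softmax, yielding a
   spatial attention map ``a1`` (sums to 1 over electrodes) and a temporal
   attention map ``a2`` (sums to 1 over time points);
4. the outer product ``a = a1 a2^T`` gives a rank-1, normalised
   spatial-temporal weight matrix which multiplies ``B`` elementwise into an
   attentive recoding ``E``;
5. a residual blend ``Z = gamma * E + B`` with a single learnable scalar
   ``gamma`` returns the final representation.  With ``gamma = 0`` the module
   is an exact identity on ``B``, which makes ablation trivially fair.

The functions here are the single-epoch reference API; the trainable,
batched layer used inside the network lives in ``_layers.AttentionFusion``
and matches these functions exactly (a property the test-suite enforces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate2d

__all__ = [
    "DAFMParams",
    "AttentionMaps",
    "initial_conv",
    "compress_spatial",
    "compress_temporal",
    "spatial_attention",
    "temporal_attention",
    "fuse_attention",
    "apply_attention",
    "residual_combine",
    "attention_forward",
]


@dataclass
class DAFMParams:
    """Parameters of the attention-fusion module for a fixed ``(H, W)``.

    All arrays are float; shapes are validated on use.  ``gamma`` is the
    scalar residual weight; at 0 the module reduces to the initial
    convolution alone.
    """

    initial_conv_weights: np.ndarray  # (kh, kw) kernel, default 1x1
    initial_conv_bias: float
    spatial_compress_weights: np.ndarray  # (W,) kernel collapsing time
    spatial_compress_bias: float
    temporal_compress_weights: np.ndarray  # (H,) kernel collapsing channels
    temporal_compress_bias: float
    v: np.ndarray  # (H,) spatial attention vector
    w: np.ndarray  # (W,) temporal attention vector
    gamma: float

    @classmethod
    def init(
        cls,
        H: int,
        W: int,
        *,
        seed: int | np.random.Generator = 0,
        attention_scale: float = 0.1,
        gamma: float = 0.0,
    ) -> "DAFMParams":
        """Random initialisation.

        The initial 1x1 convolution starts as the identity (weight 1, bias
        0); compression kernels use Glorot-style scaling; the attention
        vectors are small zero-mean Gaussians; ``gamma`` starts at 0 so the
        untrained module is an identity map on ``B``.
        """
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        return cls(
            initial_conv_weights=np.ones((1, 1)),
            initial_conv_bias=0.0,
            spatial_compress_weights=rng.normal(0.0, 1.0 / np.sqrt(W), size=W),
            spatial_compress_bias=0.0,
            temporal_compress_weights=rng.normal(0.0, 1.0 / np.sqrt(H), size=H),
            temporal_compress_bias=0.0,
            v=rng.normal(0.0, attention_scale, size=H),
            w=rng.normal(0.0, attention_scale, size=W),
            gamma=float(gamma),
        )


@dataclass
class AttentionMaps:
    """Per-epoch attention maps: spatial ``a1`` (H,), temporal ``a2`` (W,),
    and their rank-1 outer-product fusion (H, W).  Each sums to one."""

    a1: np.ndarray
    a2: np.ndarray
    fused: np.ndarray


def _softmax(logits: np.ndarray) -> np.ndarray:
    # max-subtraction keeps exp() finite on unnormalised EEG amplitudes
    z = logits - np.max(logits)
    e = np.exp(z)
    return e / e.sum()


def initial_conv(epoch: np.ndarray, params: DAFMParams) -> np.ndarray:
    """Initial convolution producing the feature map ``B`` of shape (H, W, 1).

    The default kernel is 1x1 so B is a scaled copy of the input; larger
    odd kernels are applied with 'same' zero padding.
    """
    A = np.asarray(epoch, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"epoch must be 2-D (H, W), got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("epoch contains non-finite values")
    k = np.asarray(params.initial_conv_weights, dtype=float)
    if k.ndim != 2:
        raise ValueError(f"initial conv kernel must be 2-D, got shape {k.shape}")
    if k.shape == (1, 1):
        B2 = k[0, 0] * A + params.initial_conv_bias
    else:
        B2 = correlate2d(A, k, mode="same") + params.initial_conv_bias
    return B2[:, :, None]


def compress_spatial(B: np.ndarray, weights: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Collapse the time axis: (H, W, 1) -> (H, 1, 1) via a (1, W) kernel."""
    B = np.asarray(B, dtype=float)
    H, W, C = _check_feature_map(B)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (W,):
        raise ValueError(f"spatial compression kernel must have length W={W}, got {weights.shape}")
    c = B[:, :, 0] @ weights + bias
    return c[:, None, None]


def compress_temporal(B: np.ndarray, weights: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Collapse the channel axis: (H, W, 1) -> (1, W, 1) via an (H, 1) kernel."""
    B = np.asarray(B, dtype=float)
    H, W, C = _check_feature_map(B)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (H,):
        raise ValueError(f"temporal compression kernel must have length H={H}, got {weights.shape}")
    d = weights @ B[:, :, 0] + bias
    return d[None, :, None]


def _check_feature_map(B: np.ndarray) -> tuple[int, int, int]:
    if B.ndim != 3 or B.shape[2] != 1:
        raise ValueError(f"feature map must have shape (H, W, 1), got {B.shape}")
    return B.shape


def spatial_attention(C_map: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Softmax over electrodes of the compressed map paired with ``v``.

    logit_i = c_i * v_i; returns a1 with a1 >= 0 and sum(a1) == 1.
    """
    c = np.asarray(C_map, dtype=float).reshape(-1)
    v = np.asarray(v, dtype=float)
    if c.shape != v.shape:
        raise ValueError(f"compressed map length {c.shape[0]} != attention vector length {v.shape[0]}")
    logits = c * v
    bad = np.flatnonzero(~np.isfinite(logits))
    if bad.size:
        raise FloatingPointError(f"non-finite spatial attention logit at channel index {bad[0]}")
    return _softmax(logits)


def temporal_attention(D_map: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Softmax over time points; logit_i = d_i * w_i."""
    d = np.asarray(D_map, dtype=float).reshape(-1)
    w = np.asarray(w, dtype=float)
    if d.shape != w.shape:
        raise ValueError(f"compressed map length {d.shape[0]} != attention vector length {w.shape[0]}")
    logits = d * w
    bad = np.flatnonzero(~np.isfinite(logits))
    if bad.size:
        raise FloatingPointError(f"non-finite temporal attention logit at time index {bad[0]}")
    return _softmax(logits)


def fuse_attention(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Outer product of the two attention maps: a[h, t] = a1[h] * a2[t].

    Because a1 and a2 each sum to one, the fused map sums to one and has
    matrix rank one.
    """
    a1 = np.asarray(a1, dtype=float).reshape(-1)
    a2 = np.asarray(a2, dtype=float).reshape(-1)
    return np.outer(a1, a2)


def apply_attention(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Elementwise weighting of the feature map by the fused attention map."""
    B = np.asarray(B, dtype=float)
    H, W, C = _check_feature_map(B)
    a = np.asarray(a, dtype=float)
    if a.shape != (H, W):
        raise ValueError(f"attention map shape {a.shape} != feature map spatial shape {(H, W)}")
    return a[:, :, None] * B


def residual_combine(E: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """Residual blend Z = gamma * E + B (identity on B when gamma == 0)."""
    E = np.asarray(E, dtype=float)
    B = np.asarray(B, dtype=float)
    if E.shape != B.shape:
        raise ValueError(f"E shape {E.shape} != B shape {B.shape}")
    return gamma * E + B


def attention_forward(
    epoch: np.ndarray, params: DAFMParams
) -> tuple[np.ndarray, AttentionMaps]:
    """Full forward pass of the attention-fusion module on one epoch.

    Returns the recoded representation ``Z`` of shape (H, W, 1) together
    with the :class:`AttentionMaps` (useful for heatmap export).
    """
    B = initial_conv(epoch, params)
    c = compress_spatial(B, params.spatial_compress_weights, params.spatial_compress_bias)
    d = compress_temporal(B, params.temporal_compress_weights, params.temporal_compress_bias)
    a1 = spatial_attention(c, params.v)
    a2 = temporal_attention(d, params.w)
    fused = fuse_attention(a1, a2)
    E = apply_attention(fused, B)
    Z = residual_combine(E, B, params.gamma)
    return Z, AttentionMaps(a1=a1, a2=a2, fused=fused)


def save_attention_maps(path, maps: "AttentionMaps | list[AttentionMaps]") -> None:
    """Write attention maps to an .npz container (arrays a1, a2, fused)."""
    if isinstance(maps, AttentionMaps):
        maps = [maps]
    np.savez(
        path,
        a1=np.stack([m.a1 for m in maps]),
        a2=np.stack([m.a2 for m in maps]),
        fused=np.stack([m.fused for m in maps]),
    )
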