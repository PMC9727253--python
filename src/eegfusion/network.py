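"""Construction of the depthwise-separable CNN classification head.

The head is an EEGNet-style compact network consuming the recoded epoch
``Z`` of shape (H, W, 1):

    Conv2D (1, K1) x F1, same padding      -> (H, W, F1)
    BatchNorm
    DepthwiseConv2D (H, 1), multiplier D   -> (1, W, F1*D)
    BatchNorm, ELU
    AveragePooling2D (1, P1) [, Dropout]   -> (1, W/P1, F1*D)
    SeparableConv2D (1, K2) x F2           -> (1, W/P1, F2)
    BatchNorm, ELU
    AveragePooling2D (1, P2) [, Dropout]   -> (1, W/(P1*P2), F2)
    Flatten, Dense(N), softmax

Width-wise convolutions use 'same' padding so only the pooling layers
change the width; the depthwise stage collapses the electrode axis to 1.
Pooling uses floor ('valid') semantics, so when W/P1 is not divisible by
P2 the trailing remainder is dropped and the flattened length is
``floor(W/P1/P2) * F2`` rather than the idealised ``W*F2/(P1*P2)``.
Dropout follows each pooling stage with the rate from the config.
"""

from __future__ import annotations

import numpy as np

from ._layers import (
    AttentionFusion,
    AvgPoolWidth,
    BatchNorm,
    Dense,
    DepthwiseSpatialConv,
    Dropout,
    ELU,
    Flatten,
    Network,
    SeparableTemporalConv,
    TemporalConv,
)
from .config import ModelConfig

__all__ = [
    "build_classifier",
    "build_model",
    "count_parameters",
    "expected_shapes",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_classifier(config: ModelConfig, *, seed=0, dtype=np.float64) -> Network:
    """Build the classification head alone (input shape (H, W, 1))."""
    cfg = config
    if cfg.width_after_pool1 < cfg.P2:
        raise ValueError(
            f"pooled width W/P1={cfg.width_after_pool1} is smaller than P2={cfg.P2}"
        )
    rng = _as_rng(seed)
    layers = [
        TemporalConv(cfg.K1, 1, cfg.F1, rng, dtype=dtype),
        BatchNorm(cfg.F1, dtype=dtype),
        DepthwiseSpatialConv(cfg.H, cfg.F1, cfg.D, rng, dtype=dtype),
        BatchNorm(cfg.F1 * cfg.D, dtype=dtype),
        ELU(),
        AvgPoolWidth(cfg.P1),
        Dropout(cfg.dropout_rate, rng),
        SeparableTemporalConv(cfg.K2, cfg.F1 * cfg.D, cfg.F2, rng, dtype=dtype),
        BatchNorm(cfg.F2, dtype=dtype),
        ELU(),
        AvgPoolWidth(cfg.P2),
        Dropout(cfg.dropout_rate, rng),
        Flatten(),
        Dense(cfg.flatten_length, cfg.N, rng, dtype=dtype),
    ]
    return Network(layers)


def build_model(
    config: ModelConfig,
    *,
    seed=0,
    use_attention: bool = True,
    gamma_init: float = 0.0,
    dtype=np.float64,
) -> Network:
    """Attention-fusion front-end followed by the classification head.

    With ``use_attention=False`` the attention layer is still constructed
    (so random initialisation consumes the generator stream identically in
    both ablation arms) but its residual scalar gamma is frozen at 0,
    making the layer an exact identity on the initial-conv output.
    """
    rng = _as_rng(seed)
    front = AttentionFusion(
        config.H,
        config.W,
        rng,
        gamma_init=gamma_init if use_attention else 0.0,
        trainable_gamma=use_attention,
        dtype=dtype,
    )
    head = build_classifier(config, seed=rng, dtype=dtype)
    return Network([front] + head.layers)


def count_parameters(model: Network) -> int:
    """Exact trainable parameter count (excludes normalisation buffers)."""
    return model.n_parameters


def expected_shapes(config: ModelConfig) -> dict[str, tuple[int, ...]]:
    """The architecture's intermediate output shapes for one epoch.

    Widths follow 'same' convolutions and floor pooling; the electrode
    axis collapses at the depthwise stage.
    """
    cfg = config
    w1 = cfg.width_after_pool1
    w2 = cfg.width_after_pool2
    return {
        "input": (cfg.H, cfg.W, 1),
        "conv_temporal": (cfg.H, cfg.W, cfg.F1),
        "depthwise_spatial": (1, cfg.W, cfg.F1 * cfg.D),
        "pool1": (1, w1, cfg.F1 * cfg.D),
        "separable": (1, w1, cfg.F2),
        "pool2": (1, w2, cfg.F2),
        "flatten": (w2 * cfg.F2,),
        "dense": (cfg.N,),
    }
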