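"""Minimal NumPy neural-network layers with hand-derived gradients.

Everything operates on batched maps of shape ``(n, H, W, C)`` (channels
last).  Each layer caches what its backward pass needs; ``backward``
accumulates parameter gradients into ``layer.grads`` and returns the
gradient with respect to the layer input.  Gradients are verified against
central finite differences in the test-suite.

Convolutions along the time axis are implemented as FFT correlations
(exact to rounding; the kernels are long relative to the epochs, so the
frequency domain beats im2col by a wide margin), which is what keeps
training on a single CPU tractable for the epoch sizes used here (up to
22 x 1000).
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

__all__ = [
    "Layer",
    "AttentionFusion",
    "TemporalConv",
    "DepthwiseSpatialConv",
    "SeparableTemporalConv",
    "BatchNorm",
    "ELU",
    "AvgPoolWidth",
    "Dropout",
    "Flatten",
    "Dense",
    "Network",
    "Adam",
    "softmax_cross_entropy",
]


class Layer:
    """Base class: parameter dicts plus forward/backward contract."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.frozen: set[str] = set()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def trainable_items(self):
        for k, p in self.params.items():
            if k not in self.frozen:
                yield k, p

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All arrays needed to reproduce inference (params + buffers)."""
        return dict(self.params)

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(state[k])


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class AttentionFusion(Layer):
    """Batched dual spatial-temporal attention fusion (see ``attention``).

    Input and output shape ``(n, H, W, 1)``.  Parameters: the 1x1 initial
    conv (k0, b0), the two compression kernels (wc over time, wd over
    channels, each with a bias), the attention vectors v (H,) and w (W,),
    and the residual scalar gamma.  With ``trainable_gamma=False`` and
    ``gamma_init=0`` the layer is a frozen identity on the initial-conv
    output, which is the "without attention" ablation arm.
    """

    def __init__(
        self,
        H: int,
        W: int,
        rng: np.random.Generator,
        *,
        gamma_init: float = 0.0,
        trainable_gamma: bool = True,
        attention_scale: float = 0.1,
        dtype=np.float64,
    ) -> None:
        super().__init__()
        self.H, self.W = H, W
        self.params = {
            "k0": np.array(1.0, dtype=dtype),
            "b0": np.array(0.0, dtype=dtype),
            "wc": rng.normal(0.0, 1.0 / np.sqrt(W), size=W).astype(dtype),
            "bc": np.array(0.0, dtype=dtype),
            "wd": rng.normal(0.0, 1.0 / np.sqrt(H), size=H).astype(dtype),
            "bd": np.array(0.0, dtype=dtype),
            "v": rng.normal(0.0, attention_scale, size=H).astype(dtype),
            "w": rng.normal(0.0, attention_scale, size=W).astype(dtype),
            "gamma": np.array(gamma_init, dtype=dtype),
        }
        if not trainable_gamma:
            self.frozen.add("gamma")
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, H, W, C = x.shape
        if (H, W, C) != (self.H, self.W, 1):
            raise ValueError(
                f"attention layer built for (H, W, 1)=({self.H}, {self.W}, 1), got {(H, W, C)}"
            )
        p = self.params
        A = x[..., 0]
        B = p["k0"] * A + p["b0"]
        c = B @ p["wc"] + p["bc"]  # (n, H)
        d = np.einsum("nhw,h->nw", B, p["wd"]) + p["bd"]  # (n, W)
        a1 = _softmax_rows(c * p["v"])
        a2 = _softmax_rows(d * p["w"])
        a = a1[:, :, None] * a2[:, None, :]
        E = a * B
        Z = p["gamma"] * E + B
        self._cache = (A, B, c, d, a1, a2, a, E)
        return Z[..., None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p, g = self.params, self.grads
        A, B, c, d, a1, a2, a, E = self._cache
        dZ = dout[..., 0]
        g["gamma"] += np.sum(dZ * E)
        dE = p["gamma"] * dZ
        dB = dZ.copy()
        da = dE * B
        dB += a * dE
        da1 = np.einsum("nhw,nw->nh", da, a2)
        da2 = np.einsum("nhw,nh->nw", da, a1)
        dl1 = a1 * (da1 - np.sum(da1 * a1, axis=1, keepdims=True))
        dl2 = a2 * (da2 - np.sum(da2 * a2, axis=1, keepdims=True))
        dc = dl1 * p["v"]
        g["v"] += np.sum(dl1 * c, axis=0)
        dd = dl2 * p["w"]
        g["w"] += np.sum(dl2 * d, axis=0)
        dB += dc[:, :, None] * p["wc"][None, None, :]
        g["wc"] += np.einsum("nhw,nh->w", B, dc)
        g["bc"] += dc.sum()
        dB += p["wd"][None, :, None] * dd[:, None, :]
        g["wd"] += np.einsum("nhw,nw->h", B, dd)
        g["bd"] += dd.sum()
        g["k0"] += np.sum(dB * A)
        g["b0"] += dB.sum()
        dA = p["k0"] * dB
        return np.ascontiguousarray(dA[..., None])

    def attention_maps(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Inference-mode (a1, a2, fused) for a batch; no caching side-effects."""
        p = self.params
        A = x[..., 0]
        B = p["k0"] * A + p["b0"]
        c = B @ p["wc"] + p["bc"]
        d = np.einsum("nhw,h->nw", B, p["wd"]) + p["bd"]
        a1 = _softmax_rows(c * p["v"])
        a2 = _softmax_rows(d * p["w"])
        return a1, a2, a1[:, :, None] * a2[:, None, :]


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class _WidthFFT:
    """Shared FFT bookkeeping for 'same'-padded correlations along width.

    Correlation out[w] = sum_k xp[w+k] k[k] is computed circularly at
    length L >= W+K-1, which makes the first W lags exact.  The two
    gradients are the mirrored correlation (for the kernel) and the full
    convolution (for the input), both also done in the frequency domain.
    """

    def __init__(self, K: int):
        self.K = K
        self.pl = (K - 1) // 2

    def pad_and_fft(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        """x (n, H, W, C) -> (rfft of padded signal with width last, W, L)."""
        W = x.shape[2]
        Wp = W + self.K - 1
        L = next_fast_len(Wp)
        xt = np.moveaxis(x, 2, -1)  # (n, H, C, W)
        xp = np.zeros(xt.shape[:-1] + (L,), dtype=x.dtype)
        xp[..., self.pl : self.pl + W] = xt
        return rfft(xp, axis=-1), W, L


class TemporalConv(Layer):
    """2-D convolution with kernel (1, K): a per-electrode temporal filter.

    'same' zero padding preserves the width; no bias (a BatchNorm follows).
    Kernel shape (K, C_in, F).  Implemented via FFT correlation along the
    width axis, exact to rounding.
    """

    def __init__(self, K: int, C_in: int, F: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.K = K
        self._fft = _WidthFFT(K)
        self.params = {"kernel": _glorot(rng, (K, C_in, F), K * C_in, K * F, dtype)}
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        Fx, W, L = self._fft.pad_and_fft(x)  # (n, H, C, Lf)
        kern = self.params["kernel"]  # (K, C, F)
        Fk = rfft(kern.transpose(1, 2, 0), n=L, axis=-1)  # (C, F, Lf)
        prod = np.einsum("nhcl,cfl->nhfl", Fx, Fk.conj())
        out = irfft(prod, n=L, axis=-1)[..., :W]  # (n, H, F, W)
        self._cache = (Fx, x.shape, L)
        return np.ascontiguousarray(np.moveaxis(out, -1, 2)).astype(x.dtype, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        Fx, x_shape, L = self._cache
        n, H, W, C = x_shape
        kern = self.params["kernel"]
        Fd = rfft(np.moveaxis(dout, 2, -1), n=L, axis=-1)  # (n, H, F, Lf)
        # kernel gradient: correlate input with upstream gradient
        Fdk = np.einsum("nhcl,nhfl->cfl", Fx, Fd.conj())
        dk = irfft(Fdk, n=L, axis=-1)[..., : self.K]  # (C, F, K)
        self.grads["kernel"] += dk.transpose(2, 0, 1).astype(kern.dtype, copy=False)
        # input gradient: convolve upstream gradient with the kernel
        Fk = rfft(kern.transpose(1, 2, 0), n=L, axis=-1)  # (C, F, Lf)
        Fdx = np.einsum("nhfl,cfl->nhcl", Fd, Fk)
        pl = self._fft.pl
        dxp = irfft(Fdx, n=L, axis=-1)[..., pl : pl + W]  # (n, H, C, W)
        return np.ascontiguousarray(np.moveaxis(dxp, -1, 2)).astype(dout.dtype, copy=False)


class DepthwiseSpatialConv(Layer):
    """Depthwise convolution with kernel (H, 1) and depth multiplier D.

    Collapses the electrode axis: (n, H, W, F) -> (n, 1, W, F*D).  Each of
    the F input maps gets D learned spatial filters across all electrodes.
    """

    def __init__(self, H: int, C_in: int, D: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.H, self.C_in, self.D = H, C_in, D
        self.params = {"kernel": _glorot(rng, (H, C_in, D), H, H * D, dtype)}
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.H:
            raise ValueError(f"depthwise spatial kernel spans H={self.H}, input has H={x.shape[1]}")
        out = np.einsum("nhwf,hfd->nwfd", x, self.params["kernel"])
        self._cache = x
        n, W = x.shape[0], x.shape[2]
        return out.reshape(n, 1, W, self.C_in * self.D)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        n, H, W, F = x.shape
        d4 = dout.reshape(n, W, F, self.D)
        self.grads["kernel"] += np.einsum("nhwf,nwfd->hfd", x, d4)
        return np.einsum("nwfd,hfd->nhwf", d4, self.params["kernel"])


class SeparableTemporalConv(Layer):
    """Separable convolution with kernel (1, K): depthwise temporal filter
    per channel followed by a 1x1 pointwise mix to F_out maps.  'same'
    padding, no biases."""

    def __init__(self, K: int, C_in: int, F_out: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.K = K
        self._fft = _WidthFFT(K)
        self.params = {
            "depthwise": _glorot(rng, (K, C_in), K, K, dtype),
            "pointwise": _glorot(rng, (C_in, F_out), C_in, F_out, dtype),
        }
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        Fx, W, L = self._fft.pad_and_fft(x)  # (n, H, C, Lf)
        Fkd = rfft(self.params["depthwise"].T, n=L, axis=-1)  # (C, Lf)
        mid_t = irfft(Fx * Fkd.conj(), n=L, axis=-1)[..., :W]  # (n, H, C, W)
        mid = np.moveaxis(mid_t, -1, 2)  # (n, H, W, C)
        out = mid @ self.params["pointwise"]
        self._cache = (Fx, mid, x.shape, L)
        return out.astype(x.dtype, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        Fx, mid, x_shape, L = self._cache
        W = x_shape[2]
        self.grads["pointwise"] += np.einsum("nhwc,nhwf->cf", mid, dout)
        dmid = dout @ self.params["pointwise"].T  # (n, H, W, C)
        Fdm = rfft(np.moveaxis(dmid, 2, -1), n=L, axis=-1)  # (n, H, C, Lf)
        dkd = irfft((Fx * Fdm.conj()).sum(axis=(0, 1)), n=L, axis=-1)[..., : self.K]  # (C, K)
        self.grads["depthwise"] += dkd.T.astype(self.params["depthwise"].dtype, copy=False)
        Fkd = rfft(self.params["depthwise"].T, n=L, axis=-1)  # (C, Lf)
        pl = self._fft.pl
        dxp = irfft(Fdm * Fkd, n=L, axis=-1)[..., pl : pl + W]
        return np.ascontiguousarray(np.moveaxis(dxp, -1, 2)).astype(dout.dtype, copy=False)


class BatchNorm(Layer):
    """Per-channel batch normalisation over (batch, H, W).

    Training uses batch statistics and updates exponential running
    statistics (momentum 0.99, eps 1e-3); inference uses the running
    statistics only, so evaluation is deterministic.
    """

    def __init__(self, C: int, dtype=np.float64, eps: float = 1e-3, momentum: float = 0.99):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"scale": np.ones(C, dtype=dtype), "shift": np.zeros(C, dtype=dtype)}
        self.running_mean = np.zeros(C, dtype=dtype)
        self.running_var = np.ones(C, dtype=dtype)
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, training, x.shape)
        return xhat * self.params["scale"] + self.params["shift"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, shape = self._cache
        self.grads["scale"] += np.sum(dout * xhat, axis=(0, 1, 2))
        self.grads["shift"] += np.sum(dout, axis=(0, 1, 2))
        dxhat = dout * self.params["scale"]
        if not training:
            return dxhat * inv_std
        m = shape[0] * shape[1] * shape[2]
        return (inv_std / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 1, 2))
            - xhat * np.sum(dxhat * xhat, axis=(0, 1, 2))
        )

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = dict(self.params)
        state["running_mean"] = self.running_mean
        state["running_var"] = self.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        super().load_state_arrays(state)
        self.running_mean = np.array(state["running_mean"])
        self.running_var = np.array(state["running_var"])


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pos = x > 0
        out = np.where(pos, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._cache = (pos, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        pos, out = self._cache
        return dout * np.where(pos, 1.0, out + self.alpha)


class AvgPoolWidth(Layer):
    """Average pooling (1, P) along the width; 'valid' (floor) semantics:
    a trailing remainder that does not fill a window is dropped."""

    def __init__(self, P: int):
        super().__init__()
        self.P = P

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, H, W, C = x.shape
        Wo = W // self.P
        if Wo < 1:
            raise ValueError(f"pooling length {self.P} exceeds width {W}")
        self._in_shape = x.shape
        return x[:, :, : Wo * self.P, :].reshape(n, H, Wo, self.P, C).mean(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, H, W, C = self._in_shape
        Wo = dout.shape[2]
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : Wo * self.P, :] = np.repeat(dout / self.P, self.P, axis=2)
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training mode; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.params = {
            "weight": _glorot(rng, (n_in, n_out), n_in, n_out, dtype),
            "bias": np.zeros(n_out, dtype=dtype),
        }
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["weight"] += x.T @ dout
        self.grads["bias"] += dout.sum(axis=0)
        return dout @ self.params["weight"].T


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted softmax cross-entropy.

    Returns (mean loss, gradient wrt logits, class probabilities).  For two
    classes this equals binary cross-entropy on a 2-unit softmax head.
    """
    n, N = logits.shape
    probs = _softmax_rows(logits)
    idx = (np.arange(n), y)
    logp = np.log(np.clip(probs[idx], 1e-12, None))
    if sample_weight is None:
        sample_weight = np.ones(n, dtype=logits.dtype)
    wsum = sample_weight.sum()
    loss = float(-(sample_weight * logp).sum() / wsum)
    dlogits = probs * (sample_weight / wsum)[:, None]
    dlogits[idx] -= sample_weight / wsum
    return loss, dlogits, probs


class Network:
    """A plain sequential stack of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def activation_shapes(self, input_shape: tuple[int, ...]) -> list[tuple[int, ...]]:
        """Per-layer output shapes (without the batch axis) for one dummy epoch."""
        x = np.zeros((1,) + tuple(input_shape))
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, training=False)
            shapes.append(tuple(x.shape[1:]))
        return shapes

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_parameters for layer in self.layers)

    def trainable_params(self):
        """Yield (layer, name) pairs for every unfrozen parameter, in order."""
        for layer in self.layers:
            for name, _ in layer.trainable_items():
                yield layer, name

    def get_weights(self) -> list[np.ndarray]:
        """All inference state (parameters plus normalisation buffers)."""
        return [p.copy() for layer in self.layers for p in layer.state_arrays().values()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            state = {}
            for k in layer.state_arrays():
                state[k] = weights[i]
                i += 1
            layer.load_state_arrays(state)

    def state_dict(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping suitable for np.savez."""
        out = {}
        for i, layer in enumerate(self.layers):
            for k, arr in layer.state_arrays().items():
                out[f"layer{i:02d}.{type(layer).__name__}.{k}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            prefix = f"layer{i:02d}.{type(layer).__name__}."
            sub = {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)}
            if sub:
                layer.load_state_arrays(sub)


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-7, Keras-style)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, network: Network) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for layer, name in network.trainable_params():
            g = layer.grads[name]
            key = (id(layer), name)
            m = self._m.get(key)
            if m is None:
                m = np.zeros_like(g)
                self._v[key] = np.zeros_like(g)
            v = self._v[key]
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self._m[key], self._v[key] = m, v
            update = self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            layer.params[name] = layer.params[name] - update
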