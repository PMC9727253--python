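"""Scikit-learn style estimator wrapping the attention-fusion network.

``EEGAttentionClassifier`` takes epochs as a 3-D array ``(n_trials, H, W)``
and class labels, trains the dual-attention front-end jointly with the
depthwise-separable CNN head by Adam on (weighted) cross-entropy, and
predicts class probabilities.  It follows the scikit-learn estimator
contract (``get_params``/``set_params``, ``fit``/``predict``/
``predict_proba``, fitted attributes with trailing underscores) so it
composes with pipelines and model selection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.utils.class_weight import compute_class_weight

from ._layers import Adam, AttentionFusion, Network, softmax_cross_entropy
from .attention import AttentionMaps
from .config import ModelConfig, get_config
from .network import build_model

__all__ = ["EEGAttentionClassifier"]


class EEGAttentionClassifier(ClassifierMixin, BaseEstimator):
    """EEG epoch classifier with a dual spatial-temporal attention front-end.

    Parameters
    ----------
    config : ModelConfig, str or None
        Network hyperparameters.  A string selects a named preset; ``None``
        infers ``H``, ``W`` and ``N`` from the training data and keeps the
        standard filter settings (F1=8, F2=16, K2=16, P1=4, P2=8, D=2,
        K1 capped at W).
    use_attention : bool
        If False, the residual attention scalar gamma is frozen at zero so
        the front-end reduces to its initial 1x1 convolution — the
        "without attention" ablation arm.  Both arms draw identical
        initial weights for a given seed.
    gamma_init : float
        Initial value of the residual scalar (default 0: the attention
        branch starts silent and is turned on by training).
    learning_rate, batch_size, max_epochs : Adam step size and schedule.
    class_weight : None or 'balanced'
        'balanced' applies inverse-frequency sample weights in the loss —
        the default protocol for the 1:5 target/non-target imbalance of
        oddball data should be set explicitly by the caller.
    shuffle : bool
        Reshuffle the training order every epoch (seeded).
    seed : int
        Seeds weight initialisation, shuffling and dropout; two fits with
        the same seed and data are bitwise identical.
    dtype : numpy dtype for all parameters and activations.

    Attributes
    ----------
    network_ : the trained layer stack.
    config_ : the resolved ModelConfig.
    classes_ : original class labels.
    history_ : dict of per-epoch curves ('loss', 'accuracy', plus
        'val_loss'/'val_accuracy' when an eval set is given to fit).
    n_parameters_ : trainable parameter count.
    """

    def __init__(
        self,
        config: ModelConfig | str | None = None,
        *,
        use_attention: bool = True,
        gamma_init: float = 0.0,
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        max_epochs: int = 100,
        class_weight: str | None = None,
        shuffle: bool = True,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        self.config = config
        self.use_attention = use_attention
        self.gamma_init = gamma_init
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.class_weight = class_weight
        self.shuffle = shuffle
        self.seed = seed
        self.dtype = dtype

    # ------------------------------------------------------------------

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3:
            raise ValueError(f"X must be 3-D (n_trials, H, W), got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _resolve_config(self, H: int, W: int, n_classes: int) -> ModelConfig:
        cfg = self.config
        if cfg is None:
            cfg = ModelConfig(H=H, W=W, K1=min(64, W), N=n_classes)
        elif isinstance(cfg, str):
            cfg = get_config(cfg)
        if (cfg.H, cfg.W) != (H, W):
            raise ValueError(
                f"config expects epochs of shape ({cfg.H}, {cfg.W}), data has ({H}, {W})"
            )
        if cfg.N != n_classes:
            raise ValueError(f"config has N={cfg.N} classes, data has {n_classes}")
        return cfg

    # ------------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, eval_set=None) -> "EEGAttentionClassifier":
        """Train on epochs X (n, H, W) with labels y.

        ``eval_set=(X_val, y_val)`` additionally records validation loss
        and accuracy once per epoch (inference mode; does not influence
        training).
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError(f"X has {X.shape[0]} trials but y has {y.shape[0]} labels")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n, H, W = X.shape
        cfg = self._resolve_config(H, W, len(self.classes_))
        self.config_ = cfg

        rng = np.random.default_rng(self.seed)
        self.network_ = build_model(
            cfg,
            seed=rng,
            use_attention=self.use_attention,
            gamma_init=self.gamma_init,
            dtype=self.dtype,
        )
        self.n_parameters_ = self.network_.n_parameters
        optimizer = Adam(lr=self.learning_rate)

        if self.class_weight == "balanced":
            cw = compute_class_weight("balanced", classes=np.arange(len(self.classes_)), y=y_enc)
        elif self.class_weight is None:
            cw = np.ones(len(self.classes_))
        else:
            raise ValueError(f"class_weight must be None or 'balanced', got {self.class_weight!r}")
        sample_weight_all = cw[y_enc].astype(self.dtype)

        Xb = X[..., None]  # (n, H, W, 1)
        history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        if eval_set is not None:
            history["val_loss"] = []
            history["val_accuracy"] = []

        for epoch in range(self.max_epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            epoch_loss = 0.0
            n_correct = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb, wb = Xb[idx], y_enc[idx], sample_weight_all[idx]
                logits = self.network_.forward(xb, training=True)
                loss, dlogits, probs = softmax_cross_entropy(logits, yb, wb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch {start // self.batch_size}"
                    )
                self.network_.zero_grads()
                self.network_.backward(dlogits)
                optimizer.step(self.network_)
                epoch_loss += loss * len(idx)
                n_correct += int(np.sum(probs.argmax(axis=1) == yb))
            history["loss"].append(epoch_loss / n)
            history["accuracy"].append(n_correct / n)
            if eval_set is not None:
                Xv, yv = eval_set
                probs = self._forward_proba(np.asarray(Xv, dtype=self.dtype))
                yv_enc = np.searchsorted(self.classes_, np.asarray(yv))
                vloss, _, _ = softmax_cross_entropy(
                    np.log(np.clip(probs, 1e-12, None)), yv_enc
                )
                history["val_loss"].append(vloss)
                history["val_accuracy"].append(float(np.mean(probs.argmax(axis=1) == yv_enc)))

        self.history_ = history
        return self

    # ------------------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise NotFittedError("this EEGAttentionClassifier instance is not fitted yet")

    def _forward_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        Xb = X[..., None]
        out = []
        for start in range(0, len(Xb), batch_size):
            logits = self.network_.forward(Xb[start : start + batch_size], training=False)
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities per trial (rows on the simplex)."""
        self._check_fitted()
        return self._forward_proba(self._validate_X(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = self._validate_X(X)
        Xb = X[..., None]
        return self.network_.forward(Xb, training=False)

    def attention_maps(self, X: np.ndarray) -> AttentionMaps:
        """Spatial (n, H), temporal (n, W) and fused (n, H, W) attention
        maps for each trial, in inference mode."""
        self._check_fitted()
        X = self._validate_X(X)
        front = self.network_.layers[0]
        assert isinstance(front, AttentionFusion)
        a1, a2, fused = front.attention_maps(X[..., None])
        return AttentionMaps(a1=a1, a2=a2, fused=fused)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) and config (.json) next to each other."""
        self._check_fitted()
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.network_.state_dict())
        meta = {
            "config": self.config_.to_dict(),
            "classes": np.asarray(self.classes_).tolist(),
            "use_attention": self.use_attention,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EEGAttentionClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig.from_dict(meta["config"])
        clf = cls(config=cfg, use_attention=meta["use_attention"])
        clf.config_ = cfg
        clf.classes_ = np.asarray(meta["classes"])
        clf.network_ = build_model(cfg, seed=0, use_attention=meta["use_attention"])
        with np.load(path.with_suffix(".npz")) as data:
            clf.network_.load_state_dict(dict(data))
        clf.n_parameters_ = clf.network_.n_parameters
        clf.history_ = {}
        return clf
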