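"""Model hyperparameter configuration.

A :class:`ModelConfig` fixes the epoch geometry (``H`` electrodes by ``W``
time points) and the hyperparameters of the depthwise-separable CNN head:
temporal filter count ``F1``, separable filter count ``F2``, temporal kernel
length ``K1``, separable kernel length ``K2``, pooling lengths ``P1``/``P2``,
depth multiplier ``D`` and the number of output classes ``N``.

Named presets cover the four benchmark geometries this model family is
normally run on: two P300 speller setups (10 channels x 144 samples at
240 Hz) and two motor-imagery setups (22x1000 and 3x1000 at 250 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path


@dataclass(frozen=True)
class ModelConfig:
    H: int
    W: int
    F1: int = 8
    F2: int = 16
    K1: int = 64
    K2: int = 16
    P1: int = 4
    P2: int = 8
    D: int = 2
    N: int = 2
    dropout_rate: float = 0.25

    def __post_init__(self) -> None:
        for name in ("H", "W", "F1", "F2", "K1", "K2", "P1", "P2", "D", "N"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.N < 2:
            raise ValueError(f"N must be at least 2, got {self.N}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.W % self.P1 != 0:
            raise ValueError(
                f"W={self.W} is not divisible by P1={self.P1} "
                "(pooled width would be fractional)"
            )

    # -- derived sizes -------------------------------------------------

    @property
    def width_after_pool1(self) -> int:
        return self.W // self.P1

    @property
    def width_after_pool2(self) -> int:
        # floor ('valid') pooling: trailing samples that do not fill a
        # window are dropped, matching Keras AveragePooling2D defaults.
        return self.width_after_pool1 // self.P2

    @property
    def flatten_length(self) -> int:
        """Actual flattened feature length of the built network."""
        return self.width_after_pool2 * self.F2

    @property
    def flatten_length_formula(self) -> int:
        """The idealised flattened length (W*F2)/(P1*P2).

        Equals :attr:`flatten_length` whenever ``W`` divides evenly by
        ``P1*P2``; otherwise it overstates the true length because floor
        pooling drops the remainder.
        """
        return (self.W * self.F2) // (self.P1 * self.P2)

    # -- (de)serialisation --------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        import json

        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


#: Benchmark presets. P300 speller epochs are 10 channels x 144 samples
#: (600 ms at 240 Hz); motor imagery epochs are 4 s at 250 Hz.
PRESETS: dict[str, ModelConfig] = {
    "speller-ii": ModelConfig(H=10, W=144, K1=72, N=2, dropout_rate=0.5),
    "speller-iii": ModelConfig(H=10, W=144, K1=72, N=2, dropout_rate=0.5),
    "mi-2a": ModelConfig(H=22, W=1000, K1=64, N=4, dropout_rate=0.2),
    "mi-2b": ModelConfig(H=3, W=1000, K1=64, N=2, dropout_rate=0.2),
}


def get_config(name: str) -> ModelConfig:
    """Look up a named preset (see :data:`PRESETS`)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown config {name!r}; available: {sorted(PRESETS)}"
        ) from None
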