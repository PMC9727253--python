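import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A small but structurally complete architecture for fast training."""
    from eegfusion import ModelConfig

    return ModelConfig(H=4, W=64, F1=4, F2=8, K1=16, K2=8, P1=4, P2=4, D=2, N=2,
                       dropout_rate=0.0)


# ---------------------------------------------------------------------
# trained models on the synthetic study conditions (shared across the
# acceptance and property tests; each trains once per session)

SEED = 42


def train_p300(snr):
    from eegfusion import TrainConfig, simulate_p300_epochs, train

    train_set = simulate_p300_epochs(600, snr=snr, seed=SEED)
    test_set = simulate_p300_epochs(180, snr=snr, seed=SEED + 1)
    clf = train(
        train_set,
        TrainConfig(batch_size=150, max_epochs=100, class_weight="balanced", seed=SEED),
        model_config="speller-ii",
    )
    return clf, test_set


def train_mi(snr):
    from eegfusion import SimulationSpec, TrainConfig, simulate_mi_epochs, train

    def epochs(n, seed):
        return simulate_mi_epochs(
            SimulationSpec(task="MI", H=3, W=1000, sfreq=250.0, snr=snr,
                           n_trials=n, n_classes=2, seed=seed)
        )

    clf = train(
        epochs(400, SEED),
        TrainConfig(batch_size=16, max_epochs=100, seed=SEED),
        model_config="mi-2b",
    )
    return clf, epochs(100, SEED + 1)


@pytest.fixture(scope="session")
def p300_snr2():
    return train_p300(2.0)


@pytest.fixture(scope="session")
def p300_snr0():
    return train_p300(0.0)


@pytest.fixture(scope="session")
def mi_snr2():
    return train_mi(2.0)


@pytest.fixture(scope="session")
def mi_snr0():
    return train_mi(0.0)
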