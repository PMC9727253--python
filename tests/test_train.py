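"""Training-harness tests: optimisation sanity, evaluation contracts,
ablation mechanics and reproducibility."""

import numpy as np
import pytest

from eegfusion import (
    SimulationSpec,
    TrainConfig,
    ablation,
    evaluate,
    mi_train_defaults,
    p300_train_defaults,
    simulate_mi_epochs,
    train,
)
from eegfusion.io import EpochSet


def test_protocol_defaults():
    mi = mi_train_defaults()
    assert (mi.learning_rate, mi.batch_size, mi.max_epochs) == (1e-3, 16, 1000)
    p3 = p300_train_defaults()
    assert (p3.learning_rate, p3.batch_size, p3.max_epochs) == (1e-3, 150, 300)
    assert p3.class_weight == "balanced"


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)


def _tiny_separable(rng, n=64, H=4, W=64):
    """Two classes separated by a strong constant offset on one channel."""
    X = rng.standard_normal((n, H, W))
    y = np.resize([0, 1], n)
    X[y == 1, 0] += 2.0
    return EpochSet(epochs=X, labels=y, sfreq=64.0, channel_names=[f"c{i}" for i in range(H)])


def test_training_reduces_loss(tiny_config, rng):
    es = _tiny_separable(rng)
    clf = train(es, TrainConfig(max_epochs=20, batch_size=16, seed=0),
                model_config=tiny_config)
    assert clf.history_["loss"][-1] < clf.history_["loss"][0]


def test_evaluate_report_invariants(tiny_config, rng):
    es = _tiny_separable(rng)
    clf = train(es, TrainConfig(max_epochs=15, batch_size=16, seed=0),
                model_config=tiny_config)
    rep = evaluate(clf, es)
    assert rep.confusion.sum() == len(es)
    assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / rep.confusion.sum())
    assert rep.n_test == len(es)


def test_perfect_and_constant_predictors():
    class Stub:
        classes_ = np.array([0, 1])

        def __init__(self, fn):
            self.predict = fn

    X = np.zeros((10, 2, 4))
    y = np.resize([0, 1], 10)
    perfect = evaluate(Stub(lambda X_: y), (X, y))
    assert perfect.accuracy == 1.0
    assert np.all(perfect.confusion == np.diag([5, 5]))
    constant = evaluate(Stub(lambda X_: np.zeros(len(X_), dtype=int)), (X, y))
    assert constant.accuracy == 0.5


def test_nonfinite_input_rejected(tiny_config, rng):
    es = _tiny_separable(rng)
    es.epochs[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        train(es, TrainConfig(max_epochs=1), model_config=tiny_config)


# ---------------------------------------------------------------------
# ablation mechanics


def test_frozen_gamma_arms_are_identical(tiny_config, rng):
    """With gamma pinned at 0 the attention branch contributes nothing:
    the with-attention and without-attention networks produce bitwise
    identical outputs on the same inputs (residual identity Z = B)."""
    from eegfusion import build_model

    arm_with = build_model(tiny_config, seed=5, use_attention=True, gamma_init=0.0)
    arm_without = build_model(tiny_config, seed=5, use_attention=False)
    x = rng.standard_normal((6, tiny_config.H, tiny_config.W, 1))
    np.testing.assert_array_equal(
        arm_with.forward(x, training=False), arm_without.forward(x, training=False)
    )


def test_trainable_gamma_moves_but_frozen_stays(tiny_config, rng):
    es = _tiny_separable(rng)
    cfg = TrainConfig(max_epochs=5, batch_size=16, seed=3)
    arm_with = train(es, cfg, model_config=tiny_config, use_attention=True)
    arm_without = train(es, cfg, model_config=tiny_config, use_attention=False)
    assert float(arm_with.network_.layers[0].params["gamma"]) != 0.0
    assert float(arm_without.network_.layers[0].params["gamma"]) == 0.0


def test_ablation_reports_share_test_hash(tiny_config, rng):
    es = _tiny_separable(rng, n=48)
    test = _tiny_separable(np.random.default_rng(9), n=24)
    rep_with, rep_without = ablation(
        es, test, TrainConfig(max_epochs=5, batch_size=16, seed=1), model_config=tiny_config
    )
    assert rep_with.test_set_hash == rep_without.test_set_hash
    assert rep_with.n_test == rep_without.n_test == 24


# ---------------------------------------------------------------------
# reproducibility


def test_identical_seeds_give_identical_weights(tiny_config, rng):
    es = _tiny_separable(rng)
    cfg = TrainConfig(max_epochs=4, batch_size=16, seed=11)
    a = train(es, cfg, model_config=tiny_config)
    b = train(es, cfg, model_config=tiny_config)
    for wa, wb in zip(a.network_.get_weights(), b.network_.get_weights()):
        np.testing.assert_array_equal(wa, wb)


def test_different_seeds_differ(tiny_config, rng):
    es = _tiny_separable(rng)
    a = train(es, TrainConfig(max_epochs=2, seed=1), model_config=tiny_config)
    b = train(es, TrainConfig(max_epochs=2, seed=2), model_config=tiny_config)
    assert any(
        not np.array_equal(wa, wb)
        for wa, wb in zip(a.network_.get_weights(), b.network_.get_weights())
    )


def test_accuracy_monotone_in_snr(p300_snr0, p300_snr2):
    """Test accuracy is non-decreasing in the signal-to-noise ratio
    (checked at snr 0, 0.5 and 2 with fixed seeds; ties within 3%)."""
    from conftest import train_p300

    acc = {0.0: evaluate(*p300_snr0).accuracy,
           2.0: evaluate(*p300_snr2).accuracy}
    clf_mid, test_mid = train_p300(0.5)
    acc[0.5] = evaluate(clf_mid, test_mid).accuracy
    assert acc[0.0] <= acc[0.5] + 0.03
    assert acc[0.5] <= acc[2.0] + 0.03


def test_loss_curve_smoothed_nonincreasing_on_separable_task(tiny_config, rng):
    """Smoothed training loss should not rise over the final half of a run
    on an easy task (stable convergence)."""
    es = _tiny_separable(rng, n=96)
    clf = train(es, TrainConfig(max_epochs=40, batch_size=16, seed=0),
                model_config=tiny_config)
    loss = np.array(clf.history_["loss"])
    smooth = np.convolve(loss, np.ones(10) / 10.0, mode="valid")
    second_half = smooth[len(smooth) // 2 :]
    assert second_half[-1] <= second_half[0] + 1e-3
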