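"""Statistical checks on the synthetic-EEG generators."""

import numpy as np
import pytest

from eegfusion.simulate import (
    SimulationSpec,
    pink_noise,
    p300_template,
    simulate_mi_epochs,
    simulate_p300_epochs,
    simulate_p300_session,
)

from _oracles import bandpower, loglog_psd_slope


# ---------------------------------------------------------------------
# pink noise


def test_pink_noise_spectral_slope_near_minus_one():
    x = pink_noise(4, 4096, seed=0)
    slopes = [loglog_psd_slope(ch) for ch in x]
    for s in slopes:
        assert -1.4 <= s <= -0.6


def test_pink_noise_zero_mean_and_seeding():
    x = pink_noise(8, 1024, seed=5)
    np.testing.assert_allclose(x.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_array_equal(x, pink_noise(8, 1024, seed=5))
    assert not np.array_equal(x, pink_noise(8, 1024, seed=6))


def test_pink_noise_channels_uncorrelated():
    # correlate first differences: differencing whitens the 1/f spectrum,
    # so cross-channel sample correlations concentrate tightly around 0
    # (raw 1/f series have too few effective samples for a sharp test)
    x = np.diff(pink_noise(6, 4096, seed=1), axis=1)
    corr = np.corrcoef(x)
    off = np.abs(corr[np.triu_indices(6, k=1)])
    assert off.mean() < 0.1


def test_pink_noise_validates_shape():
    with pytest.raises(ValueError):
        pink_noise(0, 100)


# ---------------------------------------------------------------------
# P300 session


def test_p300_template_peaks_at_latency():
    tmpl = p300_template(144, 240.0, peak_latency=0.3)
    assert np.argmax(tmpl) == 72  # 0.3 s at 240 Hz
    assert tmpl.max() == pytest.approx(1.0)
    assert tmpl.min() >= 0.0


def _p300_spec(**kw):
    base = dict(task="P300", H=10, W=144, sfreq=240.0, snr=1.0, n_characters=3, seed=42)
    base.update(kw)
    return SimulationSpec(**base)


def test_session_paradigm_combinatorics():
    es, session = simulate_p300_session(_p300_spec())
    assert len(es) == 3 * 15 * 12
    assert es.labels.sum() == 3 * 15 * 2  # 2 target flashes per repetition
    assert es.labels.mean() == pytest.approx(1.0 / 6.0)
    # every repetition flashes each code exactly once
    for ci in range(3):
        for rep in range(15):
            assert sorted(session.flash_codes[ci, rep]) == list(range(1, 13))
    assert len(session.truth) == 3


def test_session_seeding_reproducible():
    es1, s1 = simulate_p300_session(_p300_spec())
    es2, s2 = simulate_p300_session(_p300_spec())
    np.testing.assert_array_equal(es1.epochs, es2.epochs)
    assert s1.truth == s2.truth
    es3, _ = simulate_p300_session(_p300_spec(seed=43))
    assert not np.array_equal(es1.epochs, es3.epochs)


def test_target_deflection_scales_with_snr():
    strong, _ = simulate_p300_session(_p300_spec(snr=2.0, n_characters=5))
    null, _ = simulate_p300_session(_p300_spec(snr=0.0, n_characters=5))

    def difference_wave(es):
        pz = es.channel_names.index("Pz")
        return (
            es.epochs[es.labels == 1, pz].mean(axis=0)
            - es.epochs[es.labels == 0, pz].mean(axis=0)
        )

    dw_strong = difference_wave(strong)
    dw_null = difference_wave(null)
    assert dw_strong[72] > 1.0  # peak of the injected deflection
    assert abs(dw_null).max() < 0.5  # null limit: no systematic difference


def test_epoch_convenience_keeps_target_fraction():
    es = simulate_p300_epochs(600, snr=1.0, seed=42)
    assert len(es) == 600
    assert es.labels.mean() == pytest.approx(1.0 / 6.0)


def test_invalid_character_count_rejected():
    with pytest.raises(ValueError):
        simulate_p300_session(_p300_spec(n_characters=0))


# ---------------------------------------------------------------------
# motor imagery


def _mi_spec(**kw):
    base = dict(task="MI", H=3, W=1000, sfreq=250.0, snr=1.0, n_trials=200,
                n_classes=2, seed=42)
    base.update(kw)
    return SimulationSpec(**base)


def test_mi_band_power_lateralisation():
    es = simulate_mi_epochs(_mi_spec())
    contrast = []
    for x, lab in zip(es.epochs, es.labels):
        left = bandpower(x[0], 250.0, 8.0, 13.0)
        right = bandpower(x[2], 250.0, 8.0, 13.0)
        contrast.append((lab, left - right))
    c0 = np.mean([c for lab, c in contrast if lab == 0])
    c1 = np.mean([c for lab, c in contrast if lab == 1])
    assert c0 > 0 > c1  # opposite-sign asymmetry by class


def test_mi_null_limit_equal_band_power():
    es = simulate_mi_epochs(_mi_spec(snr=0.0))
    power = np.array([bandpower(x[0], 250.0, 8.0, 13.0) for x in es.epochs])
    p0, p1 = power[es.labels == 0].mean(), power[es.labels == 1].mean()
    pooled_se = power.std() * np.sqrt(2.0 / 100.0)
    assert abs(p0 - p1) < 3 * pooled_se


def test_mi_classes_balanced_and_seeded():
    es = simulate_mi_epochs(_mi_spec(n_trials=200, n_classes=2))
    assert np.bincount(es.labels).tolist() == [100, 100]
    es2 = simulate_mi_epochs(_mi_spec(n_trials=200, n_classes=2))
    np.testing.assert_array_equal(es.epochs, es2.epochs)


def test_mi_four_class_geometry():
    es = simulate_mi_epochs(_mi_spec(H=22, n_trials=8, n_classes=4))
    assert es.epochs.shape == (8, 22, 1000)
    assert sorted(np.unique(es.labels)) == [0, 1, 2, 3]


def test_mi_too_few_channels_rejected():
    with pytest.raises(ValueError, match="channel"):
        simulate_mi_epochs(_mi_spec(H=2, n_classes=4))
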