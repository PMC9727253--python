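"""Synthetic EEG generators for the oddball-speller and motor-imagery tasks.

These generators produce labelled epochs with exactly the statistical
structure the model is designed to exploit, so the whole stack can be
trained and evaluated without any external recordings:

* **P300 / oddball speller** — per character, 15 repetitions of 12
  row/column flashes (6 columns coded 1-6, 6 rows coded 7-12) in random
  order; the two flashes per repetition that contain the attended
  character carry an additive positive half-sine deflection (300 ms wide,
  peaking ``peak_latency`` seconds after flash onset, default 0.3 s) on
  parieto-central channels, superposed on 1/f pink noise.  Target
  fraction is exactly 1/6.
* **Motor imagery** — each class adds a 10-12 Hz oscillation of random
  phase on a class-specific channel group (lateralised for two classes),
  on pink noise; a stylised sensorimotor-rhythm modulation.

``snr`` is the amplitude of the class-dependent signal relative to the
unit-standard-deviation noise; at ``snr=0`` classes are indistinguishable
by construction.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ContinuousRecording, EpochSet
from .speller import DEFAULT_LAYOUT, SpellerSession, codes_for_character

__all__ = [
    "SimulationSpec",
    "pink_noise",
    "p300_template",
    "simulate_p300_session",
    "simulate_p300_epochs",
    "simulate_p300_recording",
    "simulate_mi_epochs",
]

#: The 10 electrodes over which the P300 is strongest, in montage order.
P300_CHANNELS = ["Fz", "Cz", "Pz", "Oz", "C3", "C4", "P3", "P4", "PO7", "PO8"]

#: Relative P300 amplitude per electrode (parieto-central topography).
P300_TOPOGRAPHY = {
    "Fz": 0.4, "Cz": 0.9, "Pz": 1.0, "Oz": 0.7, "C3": 0.5,
    "C4": 0.5, "P3": 0.8, "P4": 0.8, "PO7": 0.6, "PO8": 0.6,
}

MI_CHANNELS_3 = ["C3", "Cz", "C4"]


@dataclass
class SimulationSpec:
    """Conditions for one synthetic dataset."""

    task: str  # "P300" | "MI"
    H: int
    W: int
    sfreq: float
    snr: float = 1.0
    n_trials: int = 0
    n_characters: int = 0
    n_classes: int = 2
    peak_latency: float = 0.3
    seed: int = 42
    truth: str | None = None

    def __post_init__(self) -> None:
        if self.task not in ("P300", "MI"):
            raise ValueError(f"task must be 'P300' or 'MI', got {self.task!r}")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")


def pink_noise(H: int, W: int, seed: int | np.random.Generator = 0, exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent noise, H uncorrelated channels of W samples.

    Generated by spectrally shaping white Gaussian noise; each channel is
    standardised to zero mean and unit variance.
    """
    if H < 1 or W < 1:
        raise ValueError("H and W must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal((H, W))
    freqs = np.fft.rfftfreq(W)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * scale, n=W, axis=1)
    shaped -= shaped.mean(axis=1, keepdims=True)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def p300_template(W: int, sfreq: float, peak_latency: float = 0.3, duration: float = 0.3) -> np.ndarray:
    """Positive half-sine deflection of given duration centred on the peak.

    Returns a length-W waveform that is zero outside
    [peak - duration/2, peak + duration/2] and peaks (value 1) at
    ``peak_latency`` seconds.
    """
    t = np.arange(W) / sfreq
    t0 = peak_latency - duration / 2.0
    phase = (t - t0) / duration
    tmpl = np.where((phase >= 0) & (phase <= 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    return tmpl


def _p300_channel_gains(channel_names: list[str]) -> np.ndarray:
    return np.array([P300_TOPOGRAPHY.get(name, 0.0) for name in channel_names])


def simulate_p300_session(spec: SimulationSpec) -> tuple[EpochSet, SpellerSession]:
    """Simulate a full speller session of ``spec.n_characters`` characters.

    Epochs are ordered character-major, then repetition, then flash
    position; labels are 1 for target flashes (the row and the column
    containing the attended character), 0 otherwise.  Returns the epochs
    together with the aligned flash codes and ground-truth string.
    """
    if spec.task != "P300":
        raise ValueError("spec.task must be 'P300'")
    if spec.n_characters < 1:
        raise ValueError("n_characters must be at least 1")
    rng = np.random.default_rng(spec.seed)
    n_reps = 15
    layout = DEFAULT_LAYOUT
    symbols = [s for row in layout for s in row]
    if spec.truth is None:
        truth = "".join(rng.choice(symbols) for _ in range(spec.n_characters))
    else:
        truth = spec.truth
        if len(truth) != spec.n_characters:
            raise ValueError("truth length does not match n_characters")

    channel_names = P300_CHANNELS[: spec.H] if spec.H <= 10 else P300_CHANNELS + [
        f"EEG{i}" for i in range(spec.H - 10)
    ]
    gains = _p300_channel_gains(channel_names)
    tmpl = p300_template(spec.W, spec.sfreq, spec.peak_latency)
    deflection = spec.snr * gains[:, None] * tmpl[None, :]

    epochs, labels = [], []
    flash_codes = np.zeros((spec.n_characters, n_reps, 12), dtype=int)
    for ci, char in enumerate(truth):
        row_code, col_code = codes_for_character(char, layout)
        for rep in range(n_reps):
            codes = rng.permutation(12) + 1
            flash_codes[ci, rep] = codes
            for code in codes:
                x = pink_noise(spec.H, spec.W, rng)
                is_target = code in (row_code, col_code)
                if is_target:
                    x = x + deflection
                epochs.append(x)
                labels.append(int(is_target))

    epoch_set = EpochSet(
        epochs=np.array(epochs),
        labels=np.array(labels),
        sfreq=spec.sfreq,
        channel_names=channel_names,
        task="P300",
        label_names=["non-target", "target"],
    )
    session = SpellerSession(
        flash_codes=flash_codes, scores=None, truth=truth, matrix_layout=layout
    )
    return epoch_set, session


def simulate_p300_epochs(
    n_trials: int,
    *,
    snr: float = 1.0,
    H: int = 10,
    W: int = 144,
    sfreq: float = 240.0,
    peak_latency: float = 0.3,
    seed: int = 42,
) -> EpochSet:
    """Oddball epochs without the session bookkeeping.

    Simulates whole speller characters and keeps the first ``n_trials``
    epochs; when ``n_trials`` is a multiple of 12 the cut falls on a
    repetition boundary, so the target fraction stays exactly 1/6.
    """
    n_chars = max(1, math.ceil(n_trials / 180))
    spec = SimulationSpec(
        task="P300", H=H, W=W, sfreq=sfreq, snr=snr,
        n_characters=n_chars, peak_latency=peak_latency, seed=seed,
    )
    epoch_set, _ = simulate_p300_session(spec)
    return EpochSet(
        epochs=epoch_set.epochs[:n_trials],
        labels=epoch_set.labels[:n_trials],
        sfreq=epoch_set.sfreq,
        channel_names=epoch_set.channel_names,
        task="P300",
        label_names=epoch_set.label_names,
    )


def simulate_p300_recording(
    n_characters: int,
    *,
    snr: float = 1.0,
    sfreq: float = 240.0,
    soa: float = 0.175,
    peak_latency: float = 0.3,
    seed: int = 42,
    channel_names: list[str] | None = None,
) -> tuple[ContinuousRecording, str]:
    """Continuous speller recording with flash events, for the epoching path.

    Flashes follow each other every ``soa`` seconds (the speller's ~5.7 Hz
    stimulus rate), so successive 600 ms analysis windows overlap, as in
    real sessions.  Events carry the flash code (1-12) and a target flag.
    Returns the recording and the ground-truth character string.
    """
    rng = np.random.default_rng(seed)
    if channel_names is None:
        channel_names = list(P300_CHANNELS)
    H = len(channel_names)
    layout = DEFAULT_LAYOUT
    symbols = [s for row in layout for s in row]
    truth = "".join(rng.choice(symbols) for _ in range(n_characters))

    n_reps = 15
    soa_samples = int(round(soa * sfreq))
    pause_samples = int(round(1.0 * sfreq))  # inter-character pause
    n_flashes = n_characters * n_reps * 12
    total = n_flashes * soa_samples + n_characters * pause_samples + int(2 * sfreq)

    signals = pink_noise(H, total, rng)
    gains = _p300_channel_gains(channel_names)
    win = int(round(0.6 * sfreq))
    tmpl = p300_template(win, sfreq, peak_latency)

    events, targets = [], []
    cursor = int(0.5 * sfreq)
    for char in truth:
        row_code, col_code = codes_for_character(char, layout)
        for _rep in range(n_reps):
            for code in rng.permutation(12) + 1:
                events.append((cursor, int(code)))
                is_target = code in (row_code, col_code)
                targets.append(int(is_target))
                if is_target:
                    stop = min(cursor + win, total)
                    signals[:, cursor:stop] += snr * gains[:, None] * tmpl[None, : stop - cursor]
                cursor += soa_samples
        cursor += pause_samples

    rec = ContinuousRecording(
        signals=signals,
        sfreq=sfreq,
        events=np.array(events, dtype=int),
        channel_names=channel_names,
        event_targets=np.array(targets, dtype=int),
    )
    return rec, truth


def simulate_mi_epochs(spec: SimulationSpec) -> EpochSet:
    """Motor-imagery style epochs: class-dependent oscillatory power.

    Class ``c`` adds a band-limited (10-12 Hz) oscillation with amplitude
    ``snr`` and random phase on its own channel group; for two classes the
    groups are the outermost channels (lateralised, e.g. C3 vs C4 in a
    three-channel montage).  Classes are balanced.
    """
    if spec.task != "MI":
        raise ValueError("spec.task must be 'MI'")
    N = spec.n_classes
    if N < 2:
        raise ValueError("n_classes must be at least 2")
    if spec.H < N:
        raise ValueError(
            f"H={spec.H} channels cannot host {N} disjoint class channel groups"
        )
    rng = np.random.default_rng(spec.seed)

    if N == 2:
        groups = [[0], [spec.H - 1]]  # lateralised: first vs last channel
    else:
        bounds = np.linspace(0, spec.H, N + 1).astype(int)
        groups = [list(range(bounds[i], bounds[i + 1])) for i in range(N)]

    labels = np.resize(np.arange(N), spec.n_trials)
    rng.shuffle(labels)
    t = np.arange(spec.W) / spec.sfreq
    epochs = np.empty((spec.n_trials, spec.H, spec.W))
    for i, lab in enumerate(labels):
        x = pink_noise(spec.H, spec.W, rng)
        freq = rng.uniform(10.0, 12.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        osc = spec.snr * np.sin(2.0 * np.pi * freq * t + phase)
        x[groups[lab]] += osc
        epochs[i] = x

    names = MI_CHANNELS_3 if spec.H == 3 else [f"EEG{i}" for i in range(spec.H)]
    return EpochSet(
        epochs=epochs,
        labels=labels.astype(int),
        sfreq=spec.sfreq,
        channel_names=names,
        task="MI",
        label_names=[f"class{c}" for c in range(N)],
    )
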