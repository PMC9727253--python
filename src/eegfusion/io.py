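"""Reading, filtering and epoching of continuous EEG.

Continuous recordings come from EDF/GDF files (read through MNE) or from a
plain ``.npz`` array container with keys ``signals`` (channels x samples),
``sfreq``, ``channel_names``, and optionally ``events`` (n x 2 array of
``(sample_index, code)``) and ``event_targets`` (per-event 0/1 flags used
to label oddball flashes).  Signals are in microvolts by convention.

Filtering is a zero-phase 4th-order Butterworth band-pass applied
forward-backward (phase-preserving, so ERP latencies are untouched).
Epoching slices the filtered signal without resampling: every epoch is an
exact sample-for-sample window of the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "bandpass_filter",
    "competition_split",
    "extract_mi_epochs",
    "extract_p300_epochs",
    "read_recording",
    "write_recording",
    "write_edf",
    "DEFAULT_P300_ELECTRODES",
]

#: Electrodes over which the P300 is strongest; the default analysis montage.
DEFAULT_P300_ELECTRODES = ["Fz", "Cz", "Pz", "Oz", "C3", "C4", "P3", "P4", "PO7", "PO8"]


@dataclass
class ContinuousRecording:
    """Multi-channel continuous EEG with event markers.

    ``events`` is an (n_events, 2) integer array of (sample_index, code),
    kept sorted by sample index; ``event_targets`` optionally flags each
    event as target (1) or not (0) for oddball labelling.
    """

    signals: np.ndarray
    sfreq: float
    events: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    channel_names: list[str] = field(default_factory=list)
    event_targets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError(f"signals must be 2-D (channels, samples), got {self.signals.shape}")
        if not self.channel_names:
            self.channel_names = [f"EEG{i}" for i in range(self.signals.shape[0])]
        if len(self.channel_names) != self.signals.shape[0]:
            raise ValueError("channel_names length does not match signal channel count")
        self.events = np.asarray(self.events, dtype=int).reshape(-1, 2)
        if len(self.events):
            if self.events[:, 0].min() < 0 or self.events[:, 0].max() >= self.signals.shape[1]:
                raise ValueError("event sample indices fall outside the recording")
            order = np.argsort(self.events[:, 0], kind="stable")
            self.events = self.events[order]
            if self.event_targets is not None:
                self.event_targets = np.asarray(self.event_targets, dtype=int)[order]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass
class EpochSet:
    """Labelled epochs of one common shape: (n_trials, H, W)."""

    epochs: np.ndarray
    labels: np.ndarray
    sfreq: float
    channel_names: list[str]
    task: str = ""  # "MI" | "P300"
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError(f"epochs must be 3-D (n, H, W), got {self.epochs.shape}")
        if len(self.labels) != len(self.epochs):
            raise ValueError(
                f"{len(self.epochs)} epochs but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.epochs)

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            epochs=self.epochs,
            labels=self.labels,
            sfreq=self.sfreq,
            channel_names=np.array(self.channel_names),
            task=self.task,
            label_names=np.array(self.label_names),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                epochs=data["epochs"],
                labels=data["labels"],
                sfreq=float(data["sfreq"]),
                channel_names=[str(c) for c in data["channel_names"]],
                task=str(data["task"]),
                label_names=[str(c) for c in data["label_names"]],
            )


def bandpass_filter(rec: ContinuousRecording, low: float, high: float) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (4th order, forward-backward).

    The effective magnitude response is the squared 4th-order response,
    giving steep (>40 dB/octave) attenuation outside the band with no
    phase distortion.
    """
    nyq = rec.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); got ({low}, {high})"
        )
    sos = butter(4, [low, high], btype="bandpass", fs=rec.sfreq, output="sos")
    filtered = sosfiltfilt(sos, rec.signals, axis=1)
    return replace(rec, signals=filtered)


def extract_mi_epochs(
    rec: ContinuousRecording,
    window_seconds: float = 4.0,
    *,
    offset_seconds: float = 0.0,
    event_labels: dict[int, int] | None = None,
) -> EpochSet:
    """Cut cue-locked motor-imagery epochs.

    Each event opens a half-open window ``[cue + offset, cue + offset + T)``
    of ``T = round(window_seconds * sfreq)`` samples (1000 samples for 4 s
    at 250 Hz).  ``event_labels`` maps event codes to class labels; by
    default codes are ranked and mapped to 0..N-1.  Trials whose window
    leaves the recording are dropped with a warning.
    """
    W = int(round(window_seconds * rec.sfreq))
    if event_labels is None:
        codes = sorted(set(rec.events[:, 1].tolist()))
        event_labels = {c: i for i, c in enumerate(codes)}
    epochs, labels = [], []
    for sample, code in rec.events:
        if code not in event_labels:
            continue
        start = sample + int(round(offset_seconds * rec.sfreq))
        if start < 0 or start + W > rec.n_samples:
            warnings.warn(
                f"dropping trial at sample {sample}: window [{start}, {start + W}) "
                f"exceeds recording of {rec.n_samples} samples"
            )
            continue
        epochs.append(rec.signals[:, start : start + W])
        labels.append(event_labels[code])
    if not epochs:
        epochs_arr = np.zeros((0, rec.n_channels, W))
    else:
        epochs_arr = np.array(epochs)
    return EpochSet(
        epochs=epochs_arr,
        labels=np.array(labels, dtype=int),
        sfreq=rec.sfreq,
        channel_names=list(rec.channel_names),
        task="MI",
        label_names=[str(k) for k in sorted(event_labels, key=event_labels.get)],
    )


def extract_p300_epochs(
    rec: ContinuousRecording,
    electrodes: list[str] | None = None,
    window_seconds: float = 0.6,
) -> EpochSet:
    """Cut flash-locked oddball epochs on a named electrode subset.

    Windows of ``round(window_seconds * sfreq)`` samples (144 at 240 Hz)
    start at each flash event.  Labels come from ``rec.event_targets``
    (1 when the flashed row/column contains the attended character).
    """
    if electrodes is None:
        electrodes = DEFAULT_P300_ELECTRODES
    missing = [e for e in electrodes if e not in rec.channel_names]
    if missing:
        raise ValueError(
            f"electrodes {missing} not in recording; available: {rec.channel_names}"
        )
    if rec.event_targets is None:
        raise ValueError("recording has no event_targets; cannot label oddball epochs")
    picks = [rec.channel_names.index(e) for e in electrodes]
    W = int(round(window_seconds * rec.sfreq))
    epochs, labels = [], []
    for (sample, _code), target in zip(rec.events, rec.event_targets):
        if sample + W > rec.n_samples:
            warnings.warn(f"dropping flash at sample {sample}: window exceeds recording end")
            continue
        epochs.append(rec.signals[picks, sample : sample + W])
        labels.append(int(target))
    epochs_arr = np.array(epochs) if epochs else np.zeros((0, len(picks), W))
    return EpochSet(
        epochs=epochs_arr,
        labels=np.array(labels, dtype=int),
        sfreq=rec.sfreq,
        channel_names=list(electrodes),
        task="P300",
        label_names=["non-target", "target"],
    )


def competition_split(sessions: list[EpochSet], n_train_sessions: int = 1) -> tuple[EpochSet, EpochSet]:
    """Concatenate per-session epoch sets into the competition train/test
    division.

    The standard protocols assign whole sessions: the first session trains
    and the second tests for the 22-channel four-class setup
    (``n_train_sessions=1``); the first three sessions train and the
    remaining two test for the three-channel binary setup
    (``n_train_sessions=3``).
    """
    if not 1 <= n_train_sessions < len(sessions):
        raise ValueError(
            f"n_train_sessions must leave at least one test session; "
            f"got {n_train_sessions} of {len(sessions)} sessions"
        )
    ref = sessions[0]
    for s in sessions[1:]:
        if s.epochs.shape[1:] != ref.epochs.shape[1:]:
            raise ValueError("sessions have inconsistent epoch shapes")

    def concat(parts: list[EpochSet]) -> EpochSet:
        return EpochSet(
            epochs=np.concatenate([p.epochs for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            sfreq=ref.sfreq,
            channel_names=ref.channel_names,
            task=ref.task,
            label_names=ref.label_names,
        )

    return concat(sessions[:n_train_sessions]), concat(sessions[n_train_sessions:])


# ---------------------------------------------------------------------
# file formats


def write_recording(path: str | Path, rec: ContinuousRecording) -> None:
    """Write the array container (.npz)."""
    payload = dict(
        signals=rec.signals,
        sfreq=rec.sfreq,
        events=rec.events,
        channel_names=np.array(rec.channel_names),
    )
    if rec.event_targets is not None:
        payload["event_targets"] = rec.event_targets
    np.savez(path, **payload)


def _read_npz(path: Path) -> ContinuousRecording:
    with np.load(path, allow_pickle=False) as data:
        return ContinuousRecording(
            signals=data["signals"],
            sfreq=float(data["sfreq"]),
            events=data["events"] if "events" in data else np.zeros((0, 2), dtype=int),
            channel_names=[str(c) for c in data["channel_names"]],
            event_targets=data["event_targets"] if "event_targets" in data else None,
        )


def _read_mne(path: Path, fmt: str) -> ContinuousRecording:
    import mne

    reader = {"edf": mne.io.read_raw_edf, "gdf": mne.io.read_raw_gdf}[fmt]
    raw = reader(str(path), preload=True, verbose="error")
    signals = raw.get_data() * 1e6  # volts -> microvolts
    events = np.zeros((0, 2), dtype=int)
    if raw.annotations is not None and len(raw.annotations):
        ev = []
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
            try:
                code = int(float(desc))
            except ValueError:
                continue
            ev.append((int(round(onset * raw.info["sfreq"])), code))
        if ev:
            events = np.array(ev, dtype=int)
    return ContinuousRecording(
        signals=signals,
        sfreq=float(raw.info["sfreq"]),
        events=events,
        channel_names=list(raw.ch_names),
    )


def read_recording(path: str | Path, format: str | None = None) -> ContinuousRecording:
    """Read EDF, GDF or the .npz array container; format inferred from suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "npz":
        return _read_npz(path)
    if fmt in ("edf", "gdf"):
        try:
            return _read_mne(path, fmt)
        except Exception as exc:  # unreadable/corrupt file
            raise IOError(f"failed to read {path} as {fmt.upper()}: {exc}") from exc
    raise IOError(f"unrecognised recording format {fmt!r} for {path} (expected edf, gdf or npz)")


def write_edf(path: str | Path, rec: ContinuousRecording, physical_range: float = 1000.0) -> None:
    """Write a minimal EDF file (16-bit, 1 s data records, microvolt units).

    Covers the plain-EDF subset needed to round-trip synthetic recordings;
    signals are clipped to +-``physical_range`` microvolts.  Events are not
    stored (EDF+ annotations are out of scope); keep them in the .npz
    container if needed.
    """
    path = Path(path)
    sfreq = rec.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1 s record
    n_ch = rec.n_channels
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one 1 s EDF data record")

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X", 80),  # patient id
            pad("X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        [pad(name, 16) for name in rec.channel_names],  # label
        [pad("", 80)] * n_ch,  # transducer
        [pad("uV", 8)] * n_ch,  # physical dimension
        [pad(f"{-physical_range:g}", 8)] * n_ch,
        [pad(f"{physical_range:g}", 8)] * n_ch,
        [pad("-32768", 8)] * n_ch,
        [pad("32767", 8)] * n_ch,
        [pad("", 80)] * n_ch,  # prefiltering
        [pad(str(spr), 8)] * n_ch,
        [pad("", 32)] * n_ch,  # reserved
    ]
    signal_header = b"".join(b"".join(col) for col in fields)

    clipped = np.clip(rec.signals, -physical_range, physical_range)
    digital = np.round(clipped / physical_range * 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + signal_header)
        for r in range(n_records):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())  # channel-major within the record
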