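"""Band-pass filtering, epoching and EDF I/O.

Motor-imagery pipelines band-limit the EEG to the sensorimotor rhythms
(mu/alpha and beta, together roughly 8-30 Hz) before feature extraction.
Filtering is zero-phase: a Butterworth IIR filter applied forward and
backward, which doubles the effective attenuation and cancels phase
distortion. When a continuous recording and an event table are available,
the recording is filtered first and epochs are cut afterwards, which keeps
filter edge transients out of the analysis windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from .containers import EpochedEEG
from .exceptions import ConfigurationError, EpochingError, SignalLengthError

__all__ = [
    "PreprocessConfig",
    "bandpass_filter",
    "extract_epochs",
    "read_edf",
    "write_edf",
    "read_events",
]


@dataclass
class PreprocessConfig:
    """Band-pass and epoching parameters.

    band : (low_hz, high_hz), default (8, 30)
    filter_order : Butterworth order before the forward-backward pass, default 5
    epoch_window : (start_s, end_s) relative to the cue, default (0.5, 3.5)
    """

    band: tuple[float, float] = (8.0, 30.0)
    filter_order: int = 5
    epoch_window: tuple[float, float] = (0.5, 3.5)

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not (0.0 < low < high):
            raise ConfigurationError(f"band edges must satisfy 0 < low < high, got {self.band}")
        if high >= fs / 2.0:
            raise ConfigurationError(
                f"upper band edge {high} Hz reaches the Nyquist frequency {fs / 2.0} Hz"
            )
        if self.filter_order < 1:
            raise ConfigurationError(f"filter order must be >= 1, got {self.filter_order}")
        if self.epoch_window[1] <= self.epoch_window[0]:
            raise ConfigurationError(f"empty epoch window {self.epoch_window}")


def _design(fs: float, cfg: PreprocessConfig) -> tuple[np.ndarray, np.ndarray]:
    return butter(cfg.filter_order, cfg.band, btype="bandpass", fs=fs)


def bandpass_filter(signal: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Accepts a 1-D signal, a (channels, samples) recording or a
    (trials, channels, samples) tensor; output shape equals input shape.
    Forward-backward application with odd-reflection padding of length
    ``3 * max(len(a), len(b))``.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(fs)
    signal = np.asarray(signal, dtype=float)
    b, a = _design(fs, cfg)
    padlen = 3 * max(len(a), len(b))
    if signal.shape[-1] <= padlen:
        raise SignalLengthError(
            f"signal length {signal.shape[-1]} must exceed padding length {padlen} "
            f"for an order-{cfg.filter_order} zero-phase filter"
        )
    return filtfilt(b, a, signal, axis=-1, padtype="odd", padlen=padlen)


def extract_epochs(
    continuous: np.ndarray,
    fs: float,
    events: list[tuple[int, int]],
    cfg: PreprocessConfig | None = None,
    channel_names: list[str] | None = None,
) -> EpochedEEG:
    """Cut epochs from a (channels, samples) recording.

    Trial ``t`` holds the half-open sample range
    ``[onset + round(start_s * fs), onset + round(end_s * fs))`` with 0-based
    indexing. Events whose window does not fit inside the recording raise an
    :class:`EpochingError` listing the offenders.
    """
    cfg = cfg or PreprocessConfig()
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    start_s, end_s = cfg.epoch_window
    off_start = int(round(start_s * fs))
    off_stop = int(round(end_s * fs))
    n_total = continuous.shape[1]

    bad = [
        (onset, label)
        for onset, label in events
        if onset + off_start < 0 or onset + off_stop > n_total
    ]
    if bad:
        raise EpochingError(
            f"{len(bad)} event(s) exceed the recording bounds "
            f"(length {n_total} samples): {bad[:5]}"
        )
    trials = np.stack(
        [continuous[:, onset + off_start : onset + off_stop] for onset, _ in events]
    )
    labels = np.asarray([label for _, label in events], dtype=int)
    return EpochedEEG(trials, labels, fs, channel_names or [], window=(start_s, end_s))


def read_events(path: str | Path) -> list[tuple[int, int]]:
    """Read a 2-column delimited event table: onset_sample, label."""
    raw = np.loadtxt(path, delimiter=None if str(path).endswith(".txt") else ",", ndmin=2)
    if raw.shape[1] < 2:
        raise ConfigurationError(f"event table must have 2 columns, got {raw.shape[1]}")
    return [(int(onset), int(label)) for onset, label in raw[:, :2]]


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read a continuous EDF recording; returns (channels x samples in uV, fs, names)."""
    import mne  # heavy import kept local

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    fs: float,
    channel_names: list[str] | None = None,
) -> None:
    """Write a minimal continuous EDF file (16-bit, 1-s data records, uV).

    Small purpose-built writer used for synthetic-data export and round-trip
    tests; signals are quantized to the 16-bit digital range per channel.
    Trailing samples that do not fill a whole 1-s record are dropped with a
    warning.
    """
    data = np.atleast_2d(np.asarray(data_uv, dtype=float))
    n_ch, n_samp = data.shape
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ConfigurationError("EDF export requires an integer sampling rate")
    n_rec = n_samp // spr
    if n_rec == 0:
        raise SignalLengthError("recording shorter than one 1-s EDF data record")
    if n_rec * spr != n_samp:
        warnings.warn(f"dropping {n_samp - n_rec * spr} trailing samples for whole EDF records")
        data = data[:, : n_rec * spr]
    names = channel_names or [f"ch{i:02d}" for i in range(n_ch)]

    def pad(text: str, width: int) -> bytes:
        return f"{text:<{width}}"[:width].encode("ascii")

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    same = phys_max - phys_min < 1e-12
    phys_min[same] -= 1.0
    phys_max[same] += 1.0
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("synthetic EEG", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        b"".join(pad(nm, 16) for nm in names),
        b"".join(pad("EEG", 80) for _ in names),
        b"".join(pad("uV", 8) for _ in names),
        b"".join(pad(f"{v:.6g}", 8) for v in phys_min),
        b"".join(pad(f"{v:.6g}", 8) for v in phys_max),
        b"".join(pad(str(dig_min), 8) for _ in names),
        b"".join(pad(str(dig_max), 8) for _ in names),
        b"".join(pad("", 80) for _ in names),
        b"".join(pad(str(spr), 8) for _ in names),
        b"".join(pad("", 32) for _ in names),
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(block)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
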