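"""Core data containers: epoched EEG tensors and per-domain feature tables.

Epoched EEG is held as a dense ``(n_trials, n_channels, n_samples)`` float
tensor in microvolts, together with per-trial class labels, the sampling
rate and the epoch window relative to the cue. Feature tables carry a
``(n_trials, n_features)`` matrix tagged with the domain the features were
extracted from (time, frequency, time-frequency or spatial).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = ["Domain", "EpochedEEG", "DomainFeatureTable", "CompositeFeatureTable"]


class Domain(str, Enum):
    """Feature domain tag: time (td), frequency (fd), time-frequency (tfd), spatial (sd)."""

    TIME = "td"
    FREQUENCY = "fd"
    TIME_FREQUENCY = "tfd"
    SPATIAL = "sd"

    @classmethod
    def coerce(cls, value: "Domain | str") -> "Domain":
        return value if isinstance(value, cls) else cls(str(value))


#: Fixed domain order used when domain blocks are concatenated.
DOMAIN_ORDER = (Domain.TIME, Domain.FREQUENCY, Domain.TIME_FREQUENCY, Domain.SPATIAL)


@dataclass
class EpochedEEG:
    """Labeled trial tensor with channel names and sampling rate.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial tensor in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Class label per trial (binary 0/1 for spatial filtering).
    fs : float
        Sampling rate in Hz.
    channel_names : list of str, optional
        Defaults to ``ch00, ch01, ...``.
    window : (float, float), optional
        Epoch window (start_s, end_s) relative to the cue.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ConfigurationError(
                f"epoched data must be (n_trials, n_channels, n_samples), got {self.data.shape}"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise ConfigurationError(
                f"labels length {self.labels.shape} does not match {self.data.shape[0]} trials"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("epoched data contains non-finite values")
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        elif len(self.channel_names) != self.data.shape[1]:
            raise ConfigurationError("channel_names length does not match channel count")
        if self.window is not None:
            start, end = self.window
            expected = int(round((end - start) * self.fs))
            if expected != self.n_samples:
                raise ConfigurationError(
                    f"window {self.window} at fs={self.fs} implies {expected} samples, "
                    f"data has {self.n_samples}"
                )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def select(self, indices) -> "EpochedEEG":
        """Return a trial subset (copy) preserving metadata."""
        idx = np.asarray(indices)
        return EpochedEEG(
            self.data[idx].copy(),
            self.labels[idx].copy(),
            self.fs,
            list(self.channel_names),
            self.window,
        )

    def with_data(self, data: np.ndarray) -> "EpochedEEG":
        """Return a copy with a replaced (same-shape) data tensor."""
        return EpochedEEG(data, self.labels.copy(), self.fs, list(self.channel_names), self.window)

    # -- round-trip through a compressed array container + JSON sidecar -----
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savez_compressed(prefix.with_suffix(".npz"), data=self.data, labels=self.labels)
        sidecar = {
            "fs": self.fs,
            "channel_names": self.channel_names,
            "window": list(self.window) if self.window is not None else None,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "EpochedEEG":
        prefix = Path(prefix)
        with np.load(prefix.with_suffix(".npz")) as npz:
            data, labels = npz["data"], npz["labels"]
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        window = tuple(sidecar["window"]) if sidecar["window"] is not None else None
        return cls(data, labels, sidecar["fs"], sidecar["channel_names"], window)


@dataclass
class DomainFeatureTable:
    """Per-trial feature matrix tagged with its extraction domain."""

    values: np.ndarray
    domain: Domain
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.domain = Domain.coerce(self.domain)
        self.feature_names = list(self.feature_names)
        if self.values.shape[1] != len(self.feature_names):
            raise ConfigurationError(
                f"{self.values.shape[1]} columns but {len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ConfigurationError("feature names must be unique within a table")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("feature table contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_rows(self, indices) -> "DomainFeatureTable":
        return DomainFeatureTable(self.values[np.asarray(indices)], self.domain, self.feature_names)

    def select_columns(self, indices) -> "DomainFeatureTable":
        idx = np.asarray(indices)
        return DomainFeatureTable(
            self.values[:, idx], self.domain, [self.feature_names[i] for i in idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)

    # -- delimited text + JSON sidecar --------------------------------------
    def save(self, path: str | Path, labels: np.ndarray | None = None) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {"domain": self.domain.value}
        if labels is not None:
            sidecar["labels"] = np.asarray(labels).astype(int).tolist()
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> tuple["DomainFeatureTable", np.ndarray | None]:
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        labels = np.asarray(sidecar["labels"]) if "labels" in sidecar else None
        table = cls(frame.to_numpy(), Domain(sidecar["domain"]), list(frame.columns))
        return table, labels


@dataclass
class CompositeFeatureTable:
    """Concatenation [rotated | significant] of a domain's selected features."""

    values: np.ndarray
    origin: list[str]
    domain: Domain | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.origin = list(self.origin)
        if self.values.shape[1] != len(self.origin):
            raise ConfigurationError("origin tags must match column count")
        allowed = {"rotated", "significant"}
        if not set(self.origin) <= allowed:
            raise ConfigurationError(f"origin tags must be in {allowed}")
        n_rot = self.origin.count("rotated")
        if n_rot * 2 != len(self.origin):
            raise ConfigurationError("composite table needs equal rotated and significant blocks")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]
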