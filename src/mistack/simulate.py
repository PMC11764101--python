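"""Synthetic motor-imagery EEG with controllable ERD/ERS structure.

Trials are sums of band-limited oscillations (mu/alpha and beta), a pink
(1/f) background and white noise. Class membership modulates the
oscillation amplitudes: channels listed for a class undergo event-related
desynchronization (amplitude scaled by ``1 - erd_depth``, so band power
scales by its square), while the other class's channels may undergo
synchronization (``1 + ers_gain``). Oscillations are narrow-band filtered
Gaussian noise rather than pure sinusoids so spectral, wavelet and
fractal-dimension features are all non-degenerate. A ground-truth manifest
records which channels, bands and mechanisms carry class signal.

Feature-level fixtures (Gaussian blocks with planted class-mean shifts per
domain) are also provided for unit-testing selection, rotation and
stacking without the signal-processing front end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Domain, DomainFeatureTable, EpochedEEG
from .exceptions import ConfigurationError
from .preprocessing import PreprocessConfig, bandpass_filter

__all__ = ["SyntheticConfig", "generate_mi_eeg", "generate_continuous_eeg", "generate_feature_tables"]


@dataclass
class SyntheticConfig:
    """Generator settings for two-class ERD/ERS-structured EEG.

    ``erd_channels`` maps each class to the channel indices whose alpha and
    beta oscillations are attenuated (contralateral desynchronization) when
    that class is imagined; the opposite class's channels receive the
    ``ers_gain`` power increase (ipsilateral synchronization).
    ``domain_signal_toggles`` switches independent class-signal mechanisms:
    "sd" is the lateralized ERD/ERS pattern itself, "fd"/"tfd" add global
    (non-lateralized) alpha/beta power shifts, and "td" adds a
    class-dependent broadband noise-variance shift.
    """

    n_trials_per_class: int = 100
    n_channels: int = 8
    fs: float = 100.0
    duration_s: float = 3.0
    alpha_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (16.0, 24.0)
    erd_channels: dict[int, tuple[int, ...]] | None = None
    erd_depth: float = 0.6
    ers_gain: float = 0.2
    alpha_amplitude: float = 1.0
    beta_amplitude: float = 0.7
    pink_amplitude: float = 0.6
    noise_sd: float = 0.4
    domain_signal_toggles: dict[str, bool] = field(
        default_factory=lambda: {"td": False, "fd": False, "tfd": False, "sd": True}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.erd_channels is None:
            # laterally symmetric defaults: a small group on each hemisphere,
            # mirrored about the channel axis ({0: (1, 2), 1: (5, 6)} at 8 ch)
            k = max(1, self.n_channels // 4)
            left = tuple(range(1, min(1 + k, self.n_channels)))
            right = tuple(sorted(self.n_channels - 1 - c for c in left))
            if set(left) & set(right):
                left, right = (0,), (self.n_channels - 1,)
            self.erd_channels = {0: left, 1: right}

    def validate(self) -> None:
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ConfigurationError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        if self.ers_gain < 0:
            raise ConfigurationError(f"ers_gain must be >= 0, got {self.ers_gain}")
        top = max(self.alpha_band[1], self.beta_band[1])
        if self.fs <= 2 * top:
            raise ConfigurationError(f"fs={self.fs} must exceed twice the top band edge {top}")
        for cls, chans in self.erd_channels.items():
            if any(not (0 <= c < self.n_channels) for c in chans):
                raise ConfigurationError(
                    f"erd channel indices {chans} for class {cls} outside 0..{self.n_channels - 1}"
                )
        if self.n_trials_per_class < 1 or self.n_channels < 1:
            raise ConfigurationError("need at least one trial and one channel")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _narrowband(rng: np.random.Generator, shape, fs: float, band) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (order-4 zero-phase Butterworth)."""
    pad = 200  # generate extra samples so filter transients can be trimmed
    white = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    filt = bandpass_filter(white, fs, PreprocessConfig(band=band, filter_order=4))
    return _unit_rms(filt[..., pad:-pad])


def _pink(rng: np.random.Generator, shape) -> np.ndarray:
    """Unit-RMS 1/f-power noise via spectral shaping of white noise."""
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** -0.5
    return _unit_rms(np.fft.irfft(spectrum * gain, n=shape[-1], axis=-1))


def _amplitude_multipliers(cfg: SyntheticConfig) -> np.ndarray:
    """(n_classes, n_channels) oscillation amplitude multiplier (ERD/ERS)."""
    mult = np.ones((2, cfg.n_channels))
    if not cfg.domain_signal_toggles.get("sd", True):
        return mult
    for cls, chans in cfg.erd_channels.items():
        for other in (0, 1):
            if other == cls:
                mult[cls, list(chans)] *= 1.0 - cfg.erd_depth
            else:
                mult[other, list(chans)] *= 1.0 + cfg.ers_gain
    return mult


def generate_mi_eeg(cfg: SyntheticConfig | None = None) -> tuple[EpochedEEG, dict]:
    """Generate epoched two-class EEG plus a ground-truth manifest."""
    cfg = cfg or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_trials_per_class
    T = cfg.n_samples
    labels = np.repeat([0, 1], cfg.n_trials_per_class)
    rng.shuffle(labels)

    mult = _amplitude_multipliers(cfg)
    toggles = cfg.domain_signal_toggles
    # global (non-lateralized) per-class scale factors for the optional mechanisms
    alpha_global = np.ones(2)
    beta_global = np.ones(2)
    noise_scale = np.full(2, cfg.noise_sd)
    if toggles.get("fd", False):
        alpha_global[0] = 1.0 - cfg.erd_depth / 2.0
    if toggles.get("tfd", False):
        beta_global[0] = 1.0 - cfg.erd_depth / 2.0
    if toggles.get("td", False):
        noise_scale[1] = cfg.noise_sd * (1.0 + cfg.erd_depth / 2.0)

    shape = (n, cfg.n_channels, T)
    alpha = _narrowband(rng, shape, cfg.fs, cfg.alpha_band)
    beta = _narrowband(rng, shape, cfg.fs, cfg.beta_band)
    pink = _pink(rng, shape)
    white = rng.standard_normal(shape)

    amp_a = cfg.alpha_amplitude * mult[labels][:, :, None] * alpha_global[labels][:, None, None]
    amp_b = cfg.beta_amplitude * mult[labels][:, :, None] * beta_global[labels][:, None, None]
    data = (
        amp_a * alpha
        + amp_b * beta
        + cfg.pink_amplitude * pink
        + noise_scale[labels][:, None, None] * white
    )

    epochs = EpochedEEG(data, labels, cfg.fs, window=(0.0, cfg.duration_s))
    manifest = {
        "erd_channels": {int(k): list(v) for k, v in cfg.erd_channels.items()},
        "informative_channels": sorted({c for v in cfg.erd_channels.values() for c in v}),
        "alpha_band": list(cfg.alpha_band),
        "beta_band": list(cfg.beta_band),
        "erd_depth": cfg.erd_depth,
        "ers_gain": cfg.ers_gain,
        "domain_signal_toggles": dict(toggles),
        "seed": cfg.seed,
    }
    return epochs, manifest


def generate_continuous_eeg(
    cfg: SyntheticConfig | None = None,
    cue_offset_s: float = 0.5,
    gap_s: float = 1.0,
) -> tuple[np.ndarray, list[tuple[int, int]], dict]:
    """Continuous recording with cue events, for epoching and EDF round trips.

    Each trial's oscillatory segment is placed ``cue_offset_s`` after its cue
    onset; background between trials is pink plus white noise. Returns the
    (channels, samples) array, the (onset_sample, label) event list and the
    ground-truth manifest.
    """
    cfg = cfg or SyntheticConfig()
    epochs, manifest = generate_mi_eeg(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    fs = cfg.fs
    off = int(round(cue_offset_s * fs))
    gap = int(round(gap_s * fs))
    T = epochs.n_samples
    step = off + T + gap
    total = epochs.n_trials * step + gap
    background = (
        cfg.pink_amplitude * _pink(rng, (cfg.n_channels, total))
        + cfg.noise_sd * rng.standard_normal((cfg.n_channels, total))
    )
    events = []
    for t in range(epochs.n_trials):
        onset = gap + t * step
        background[:, onset + off : onset + off + T] = epochs.data[t]
        events.append((onset, int(epochs.labels[t])))
    manifest = dict(manifest, cue_offset_s=cue_offset_s, gap_s=gap_s)
    return background, events, manifest


def generate_feature_tables(
    n: int = 200,
    per_domain_effect: dict[Domain | str, float] | None = None,
    seed: int = 0,
    n_features: int = 20,
    n_informative: int = 5,
) -> tuple[dict[Domain, DomainFeatureTable], np.ndarray, dict]:
    """Gaussian per-domain feature blocks with planted class-mean shifts.

    ``per_domain_effect`` gives the standardized mean shift planted in the
    first ``n_informative`` columns of each domain (0 = pure noise). Used as
    a direct fixture for selection, rotation and stacking tests.
    """
    effects = {Domain.coerce(k): float(v) for k, v in (per_domain_effect or {}).items()}
    for effect in effects.values():
        if effect < 0:
            raise ConfigurationError("effect sizes must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n - n // 2)[:n]
    rng.shuffle(labels)
    tables: dict[Domain, DomainFeatureTable] = {}
    informative: dict[str, list[int]] = {}
    for domain in Domain:
        effect = effects.get(domain, 0.0)
        X = rng.standard_normal((n, n_features))
        X[labels == 1, :n_informative] += effect
        names = [f"{domain.value}_f{j:02d}" for j in range(n_features)]
        tables[domain] = DomainFeatureTable(X, domain, names)
        informative[domain.value] = list(range(n_informative)) if effect > 0 else []
    manifest = {
        "informative_columns": informative,
        "effects": {d.value: effects.get(d, 0.0) for d in Domain},
        "seed": seed,
    }
    return tables, labels, manifest
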