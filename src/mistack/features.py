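"""Time, frequency and time-frequency domain feature extraction.

Per channel the time domain contributes mean, population variance, RMS and
Higuchi's fractal dimension; the frequency domain contributes alpha- and
beta-band PSD and energy from the unnormalized DFT; the time-frequency
domain contributes discrete-wavelet detail energies at the decomposition
levels mapped to the alpha and beta rhythms (db4, 4 levels, with detail
level D4 read as alpha and D3 as beta). All extractors are deterministic,
channel-separable functions of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pywt
from scipy.signal import resample_poly

from .containers import Domain, DomainFeatureTable, EpochedEEG
from .exceptions import ConfigurationError, DecompositionError

__all__ = [
    "HiguchiConfig",
    "BandDefinition",
    "higuchi_fd",
    "time_domain_features",
    "frequency_domain_features",
    "timefrequency_features",
    "dwt_energy_decomposition",
]


@dataclass
class HiguchiConfig:
    """Maximum time interval for the Higuchi curve-length fit (default 10)."""

    l_max: int = 10

    def validate(self, n_samples: int) -> None:
        if self.l_max < 2:
            raise ConfigurationError(f"l_max must be >= 2, got {self.l_max}")
        if n_samples < 2 * self.l_max:
            raise ConfigurationError(
                f"need at least 2*l_max={2 * self.l_max} samples, got {n_samples}"
            )


@dataclass
class BandDefinition:
    """Alpha and beta band edges in Hz (defaults 8-13 and 13-30)."""

    alpha: tuple[float, float] = (8.0, 13.0)
    beta: tuple[float, float] = (13.0, 30.0)

    def validate(self, fs: float) -> None:
        for name, (low, high) in (("alpha", self.alpha), ("beta", self.beta)):
            if not (0.0 <= low < high):
                raise ConfigurationError(f"{name} band {low, high} is empty or negative")
            if high > fs / 2.0:
                raise ConfigurationError(
                    f"{name} band edge {high} Hz outside [0, fs/2)={fs / 2.0}"
                )
        a, b = sorted([self.alpha, self.beta])
        if b[0] < a[1]:
            raise ConfigurationError("alpha and beta bands must not overlap")


def higuchi_fd(x: np.ndarray, l_max: int = 10) -> float:
    """Higuchi fractal dimension of a 1-D signal.

    Builds, for each time interval ``l = 1..l_max``, the ``l`` decimated
    sub-series starting at offsets ``m = 1..l``, computes their normalized
    curve lengths, and returns the least-squares slope of
    ``ln <L(l)>`` against ``ln(1/l)``. A line has dimension 1, white noise
    approaches 2. A constant signal is degenerate (zero curve length) and
    returns 1.0 with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    HiguchiConfig(l_max).validate(x.size)
    T = x.size
    if np.ptp(x) == 0.0:
        warnings.warn("constant signal: Higuchi fractal dimension is degenerate, returning 1.0")
        return 1.0

    mean_lengths = np.empty(l_max)
    for l in range(1, l_max + 1):
        lengths = []
        for m in range(l):
            sub = x[m::l]
            q = sub.size - 1  # number of increments, Q = floor((T-1-m)/l)
            if q < 1:
                continue
            curve = np.abs(np.diff(sub)).sum() * (T - 1) / (q * l)
            lengths.append(curve / l)
        mean_lengths[l - 1] = np.mean(lengths)

    ln_inv_l = -np.log(np.arange(1, l_max + 1))
    ln_len = np.log(mean_lengths)
    slope = np.polyfit(ln_inv_l, ln_len, 1)[0]
    return float(slope)


def _channel_table(
    epochs: EpochedEEG, per_channel: dict[str, np.ndarray], domain: Domain
) -> DomainFeatureTable:
    # per_channel maps feature suffix -> (n_trials, n_channels); column order is
    # channel-major so permuting channels permutes feature blocks identically.
    names, columns = [], []
    for ch_i, ch in enumerate(epochs.channel_names):
        for suffix, mat in per_channel.items():
            names.append(f"{ch}:{suffix}")
            columns.append(mat[:, ch_i])
    return DomainFeatureTable(np.column_stack(columns), domain, names)


def time_domain_features(
    epochs: EpochedEEG, cfg: HiguchiConfig | None = None
) -> DomainFeatureTable:
    """Mean, population variance, RMS and Higuchi FD per channel (4 x Nch features)."""
    cfg = cfg or HiguchiConfig()
    cfg.validate(epochs.n_samples)
    data = epochs.data
    hfd = np.empty(data.shape[:2])
    for t in range(data.shape[0]):
        for c in range(data.shape[1]):
            hfd[t, c] = higuchi_fd(data[t, c], cfg.l_max)
    per_channel = {
        "mean": data.mean(axis=-1),
        "var": data.var(axis=-1),  # population variance (divide by T)
        "rms": np.sqrt(np.mean(data**2, axis=-1)),
        "hfd": hfd,
    }
    return _channel_table(epochs, per_channel, Domain.TIME)


def frequency_domain_features(
    epochs: EpochedEEG, bands: BandDefinition | None = None
) -> DomainFeatureTable:
    """Alpha/beta PSD and band energy per channel (4 x Nch features).

    Uses the unnormalized forward DFT; band features sum ``|X(k)|^2`` over
    positive-frequency bins whose frequency lies in the half-open band
    ``[low, high)``, with PSD carrying an extra ``1/T``. No one-sided
    doubling is applied.
    """
    bands = bands or BandDefinition()
    bands.validate(epochs.fs)
    T = epochs.n_samples
    spectrum = np.fft.rfft(epochs.data, axis=-1)
    power = np.abs(spectrum) ** 2
    freqs = np.fft.rfftfreq(T, d=1.0 / epochs.fs)

    def band_power(band: tuple[float, float]) -> np.ndarray:
        mask = (freqs >= band[0]) & (freqs < band[1])
        return power[..., mask].sum(axis=-1)

    e_alpha = band_power(bands.alpha)
    e_beta = band_power(bands.beta)
    per_channel = {
        "psd_alpha": e_alpha / T,
        "psd_beta": e_beta / T,
        "energy_alpha": e_alpha,
        "energy_beta": e_beta,
    }
    return _channel_table(epochs, per_channel, Domain.FREQUENCY)


def dwt_energy_decomposition(
    x: np.ndarray, wavelet: str = "db4", n_levels: int = 4
) -> dict[str, float]:
    """Coefficient energies of the full dyadic decomposition of a 1-D signal.

    Returns ``{"A{L}": energy, "D{L}": ..., ..., "D1": ...}`` using the same
    periodic-extension convention as :func:`timefrequency_features`; with an
    orthogonal wavelet these energies sum to the time-domain energy.
    """
    x = np.asarray(x, dtype=float).ravel()
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    if max_level < n_levels:
        raise DecompositionError(
            f"{x.size} samples support at most {max_level} {wavelet} levels"
        )
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=n_levels)
    out = {f"A{n_levels}": float((coeffs[0] ** 2).sum())}
    for j in range(n_levels, 0, -1):
        out[f"D{j}"] = float((coeffs[n_levels - j + 1] ** 2).sum())
    return out


def timefrequency_features(
    epochs: EpochedEEG,
    wavelet: str = "db4",
    n_levels: int = 4,
    level_map: dict[str, int] | None = None,
    analysis_fs: float = 100.0,
) -> DomainFeatureTable:
    """Discrete-wavelet detail energies for the alpha and beta rhythms (2 x Nch).

    ``level_map`` assigns a detail level to each rhythm (default alpha->D4,
    beta->D3). Decomposition uses periodic signal extension so that, with an
    orthogonal wavelet, sub-band energies sum to the time-domain energy.
    Signals sampled at a rate other than ``analysis_fs`` are resampled first
    so the level-to-rhythm mapping keeps its meaning across datasets.
    """
    level_map = level_map or {"alpha": 4, "beta": 3}
    for rhythm, level in level_map.items():
        if not (1 <= level <= n_levels):
            raise ConfigurationError(f"{rhythm} mapped to level {level} outside 1..{n_levels}")

    data = epochs.data
    if abs(epochs.fs - analysis_fs) > 1e-9:
        ratio = Fraction(analysis_fs / epochs.fs).limit_denominator(1000)
        data = resample_poly(data, ratio.numerator, ratio.denominator, axis=-1)

    max_level = pywt.dwt_max_level(data.shape[-1], pywt.Wavelet(wavelet).dec_len)
    if max_level < n_levels:
        raise DecompositionError(
            f"{data.shape[-1]} samples support at most {max_level} {wavelet} levels, "
            f"requested {n_levels}"
        )
    coeffs = pywt.wavedec(data, wavelet, mode="periodization", level=n_levels, axis=-1)
    # coeffs = [A_L, D_L, D_{L-1}, ..., D_1]; detail level j sits at index L - j + 1
    detail_energy = {
        rhythm: (coeffs[n_levels - level + 1] ** 2).sum(axis=-1)
        for rhythm, level in level_map.items()
    }
    per_channel = {
        "dwt_energy_alpha": detail_energy["alpha"],
        "dwt_energy_beta": detail_energy["beta"],
    }
    return _channel_table(epochs, per_channel, Domain.TIME_FREQUENCY)
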