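"""Common spatial patterns and the 8-32 Hz filter-bank variant.

CSP finds spatial filters that jointly diagonalize the two class-average
covariance matrices: per-trial covariances are trace-normalized and
averaged per class, the composite covariance is whitened, and the
eigenvectors of the whitened class-1 covariance (whose eigenvalues pair
with the class-2 ones as lambda_1 + lambda_2 = I) give the projection
matrix W. Log-variance shares of the first and last m projected rows are
the spatial features. The filter-bank variant repeats this on six 4-Hz
sub-bands spanning 8-32 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import Domain, DomainFeatureTable, EpochedEEG
from .exceptions import ChannelMismatchError, ConfigurationError
from .preprocessing import PreprocessConfig, bandpass_filter

__all__ = [
    "CSPModel",
    "fit_csp",
    "apply_csp",
    "filterbank_csp",
    "apply_filterbank_csp",
    "default_filter_bank",
]


def default_filter_bank() -> list[tuple[float, float]]:
    """Six contiguous 4-Hz sub-bands from 8 to 32 Hz."""
    return [(float(lo), float(lo + 4)) for lo in range(8, 32, 4)]


@dataclass
class CSPModel:
    """Fitted spatial projection.

    W : (Nch, Nch) projection matrix, rows = spatial filters ordered by
        descending eigenvalue of the whitened class-1 covariance.
    m : retained filter pairs; features use the first and last m rows.
    band : sub-band this model was fitted on (None = broadband input).
    """

    W: np.ndarray
    m: int
    band: tuple[float, float] | None = None
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    filter_order: int = 5

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def retained_rows(self) -> np.ndarray:
        n = self.n_channels
        return np.r_[np.arange(self.m), np.arange(n - self.m, n)]


def _class_mean_covariance(data: np.ndarray) -> np.ndarray:
    covs = []
    for trial in data:
        c = trial @ trial.T
        tr = np.trace(c)
        if tr <= 0:
            raise ConfigurationError("trial covariance has non-positive trace (all-zero trial?)")
        covs.append(c / tr)
    return np.mean(covs, axis=0)


def fit_csp(
    epochs: EpochedEEG,
    m: int = 2,
    band: tuple[float, float] | None = None,
    filter_order: int = 5,
    reg: float = 1e-10,
) -> CSPModel:
    """Fit CSP on two-class epochs (optionally band-passing them first)."""
    classes = epochs.classes
    if classes.size != 2:
        raise ConfigurationError(f"CSP requires exactly 2 classes, got {classes.tolist()}")
    nch = epochs.n_channels
    if not (1 <= m and 2 * m <= nch):
        raise ConfigurationError(f"need 1 <= m and 2m <= {nch} channels, got m={m}")

    data = epochs.data
    if band is not None:
        data = bandpass_filter(data, epochs.fs, PreprocessConfig(band=band, filter_order=filter_order))

    c1 = _class_mean_covariance(data[epochs.labels == classes[0]])
    c2 = _class_mean_covariance(data[epochs.labels == classes[1]])
    cc = c1 + c2

    eigvals, eigvecs = np.linalg.eigh((cc + cc.T) / 2.0)
    order = np.argsort(-eigvals, kind="stable")
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    floor = reg * np.trace(cc) / nch
    if eigvals[-1] < floor:
        warnings.warn("rank-deficient composite covariance; regularizing eigenvalues")
        eigvals = eigvals + floor
    whitening = np.diag(eigvals**-0.5) @ eigvecs.T

    s1 = whitening @ c1 @ whitening.T
    lam, b_vecs = np.linalg.eigh((s1 + s1.T) / 2.0)
    order = np.argsort(-lam, kind="stable")  # stable sort: ties keep original index order
    lam, b_vecs = lam[order], b_vecs[:, order]
    w = b_vecs.T @ whitening
    return CSPModel(W=w, m=m, band=band, eigenvalues=lam, filter_order=filter_order)


def apply_csp(model: CSPModel, epochs: EpochedEEG, prefilter: bool = False) -> DomainFeatureTable:
    """Log-variance-share CSP features for the 2m retained filters.

    ``f_p = log(var(Z_p) / sum_{i in retained} var(Z_i))`` with
    ``Z = W_retained X``. Set ``prefilter`` to band-pass the epochs with the
    model's own sub-band first (used by the filter bank at test time).
    """
    if epochs.n_channels != model.n_channels:
        raise ChannelMismatchError(
            f"model fitted on {model.n_channels} channels, data has {epochs.n_channels}"
        )
    data = epochs.data
    if prefilter and model.band is not None:
        data = bandpass_filter(
            data, epochs.fs, PreprocessConfig(band=model.band, filter_order=model.filter_order)
        )
    w_ret = model.W[model.retained_rows]
    z = np.einsum("fc,tcs->tfs", w_ret, data)
    variances = z.var(axis=-1)
    feats = np.log(variances / variances.sum(axis=1, keepdims=True))
    prefix = f"band_{model.band[0]:g}_{model.band[1]:g}:" if model.band is not None else ""
    names = [f"{prefix}csp_{i + 1}" for i in range(2 * model.m)]
    return DomainFeatureTable(feats, Domain.SPATIAL, names)


def filterbank_csp(
    epochs: EpochedEEG,
    bands: list[tuple[float, float]] | None = None,
    m: int = 2,
    filter_order: int = 5,
) -> tuple[DomainFeatureTable, list[CSPModel]]:
    """Fit CSP per sub-band on broadband epochs; 2m features per band.

    Returns the concatenated spatial feature table and the fitted per-band
    models (needed to transform held-out trials).
    """
    bands = bands if bands is not None else default_filter_bank()
    if not bands:
        raise ConfigurationError("filter bank needs at least one band")
    models, tables = [], []
    for band in bands:
        model = fit_csp(epochs, m=m, band=band, filter_order=filter_order)
        models.append(model)
        tables.append(apply_csp(model, epochs, prefilter=True))
    values = np.hstack([t.values for t in tables])
    names = [name for t in tables for name in t.feature_names]
    return DomainFeatureTable(values, Domain.SPATIAL, names), models


def apply_filterbank_csp(models: list[CSPModel], epochs: EpochedEEG) -> DomainFeatureTable:
    """Transform (broadband) epochs with already-fitted per-band CSP models."""
    tables = [apply_csp(model, epochs, prefilter=True) for model in models]
    values = np.hstack([t.values for t in tables])
    names = [name for t in tables for name in t.feature_names]
    return DomainFeatureTable(values, Domain.SPATIAL, names)
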