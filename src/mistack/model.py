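"""Model/Results facade over the multi-domain rotation-stacking pipeline.

``MultiDomainStackingModel`` is constructed from epoched EEG (or raw
arrays) and a configuration; ``fit()`` trains every stage on the full data
and returns a :class:`MultiDomainStackingResults` carrying the fitted
pipeline, training diagnostics and per-domain contribution rates, with
``summary()``, cross-validation, prediction, plotting and persistence
hanging off the results object.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from .containers import EpochedEEG
from .evaluation import (
    ConfusionCounts,
    CVReport,
    compute_metrics,
    cross_validate,
    feature_count_sweep,
    permutation_null,
)
from .pipeline import MultiDomainPipeline, PipelineConfig
from .stacking import contribution_rates

__all__ = ["MultiDomainStackingModel", "MultiDomainStackingResults"]


class MultiDomainStackingModel:
    """Multi-domain feature rotation + stacking ensemble classifier.

    Parameters
    ----------
    epochs : EpochedEEG
        Labeled two-class trial tensor.
    config : PipelineConfig, optional
        Pipeline settings; keyword overrides (e.g. ``na=16, K=7, seed=3``)
        are applied on top.
    """

    def __init__(self, epochs: EpochedEEG, config: PipelineConfig | None = None, **overrides):
        config = config or PipelineConfig()
        if overrides:
            config = replace(config, **overrides)
        config.validate()
        self.epochs = epochs
        self.config = config

    @classmethod
    def from_arrays(
        cls,
        data: np.ndarray,
        labels: np.ndarray,
        fs: float,
        channel_names: list[str] | None = None,
        config: PipelineConfig | None = None,
        **overrides,
    ) -> "MultiDomainStackingModel":
        epochs = EpochedEEG(data, labels, fs, channel_names or [])
        return cls(epochs, config, **overrides)

    def fit(self) -> "MultiDomainStackingResults":
        pipeline = MultiDomainPipeline(self.config).fit(self.epochs)
        return MultiDomainStackingResults(self, pipeline)


class MultiDomainStackingResults:
    """Fitted pipeline plus diagnostics.

    Attributes
    ----------
    contribution_rates_ : dict
        Per-domain contribution percentages of the meta-perceptron.
    lda_contribution_ : float or None
        Share of total meta weight mass on the LDA supplement.
    train_accuracy_ : float
        Resubstitution accuracy on the training trials.
    """

    def __init__(self, model: MultiDomainStackingModel, pipeline: MultiDomainPipeline):
        self.model = model
        self.pipeline_ = pipeline
        self.contribution_rates_, self.lda_contribution_ = contribution_rates(pipeline.stacked_)
        predictions, proba = pipeline.predict(model.epochs)
        self.train_predictions_ = predictions
        self.train_probabilities_ = proba
        self.train_accuracy_ = float(np.mean(predictions == model.epochs.labels))

    # -- inference -----------------------------------------------------------
    def predict(self, epochs: EpochedEEG | None = None) -> np.ndarray:
        epochs = epochs or self.model.epochs
        return self.pipeline_.predict(epochs)[0]

    def predict_proba(self, epochs: EpochedEEG | None = None) -> np.ndarray:
        epochs = epochs or self.model.epochs
        return self.pipeline_.predict(epochs)[1]

    def score(self, epochs: EpochedEEG) -> dict[str, float]:
        counts = ConfusionCounts.from_predictions(epochs.labels, self.predict(epochs))
        return compute_metrics(counts)

    # -- protocol-level evaluation (refits per fold) -------------------------
    def cross_validate(
        self, n_folds: int | None = None, n_repeats: int | None = None, seed: int | None = None
    ) -> CVReport:
        cfg = self.model.config
        return cross_validate(
            cfg,
            self.model.epochs,
            n_folds=n_folds or cfg.cv_folds,
            n_repeats=n_repeats or cfg.cv_repeats,
            seed=seed,
        )

    def permutation_null(self, n_permutations: int = 10, n_folds: int = 5, seed: int | None = None):
        return permutation_null(
            self.model.config, self.model.epochs, n_permutations, n_folds, seed
        )

    def feature_count_sweep(self, na_grid: list[int], **kwargs):
        return feature_count_sweep(self.model.config, self.model.epochs, na_grid, **kwargs)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        epochs, cfg = self.model.epochs, self.model.config
        width = 58
        lines = [
            "Multi-Domain Rotation + Stacking Ensemble".center(width),
            "=" * width,
            f"{'No. trials:':<28}{epochs.n_trials}",
            f"{'No. channels:':<28}{epochs.n_channels}",
            f"{'Sampling rate (Hz):':<28}{epochs.fs:g}",
            f"{'Band-pass (Hz):':<28}{cfg.preprocess.band[0]:g}-{cfg.preprocess.band[1]:g}",
            f"{'Base classifier:':<28}{cfg.base_kind}",
            f"{'Features/domain (Na):':<28}{self.pipeline_.na_}",
            f"{'Rotation subspaces (K):':<28}{cfg.K}",
            f"{'LDA supplement:':<28}{cfg.use_lda}",
            f"{'Seed:':<28}{cfg.seed}",
            "-" * width,
            f"{'Training accuracy:':<28}{100 * self.train_accuracy_:.2f} %",
            "-" * width,
            "Meta-classifier contribution rates (domains sum to 100%)",
        ]
        for domain, rate in self.contribution_rates_.items():
            lines.append(f"  {domain.value.upper():<6}{rate:6.2f} %")
        if self.lda_contribution_ is not None:
            lines.append(f"  LDA supplement share of total weight mass: {self.lda_contribution_:.2f} %")
        lines.append("=" * width)
        return "\n".join(lines)

    def plot_contributions(self, ax=None):
        """Bar chart of per-domain meta-classifier contribution rates."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        names = [d.value.upper() for d in self.contribution_rates_]
        ax.bar(names, list(self.contribution_rates_.values()), color="tab:blue")
        ax.set_ylabel("contribution rate (%)")
        ax.set_title("meta-classifier domain contributions")
        return ax

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        self.pipeline_.save(directory)

    @classmethod
    def load(cls, directory: str | Path, epochs: EpochedEEG) -> "MultiDomainStackingResults":
        pipeline = MultiDomainPipeline.load(directory)
        model = MultiDomainStackingModel(epochs, pipeline.config)
        return cls(model, pipeline)
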