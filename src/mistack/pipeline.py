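"""End-to-end pipeline: configuration, per-fold fitting and prediction.

The stages follow the flow: band-pass preprocessing -> four-domain feature
extraction -> per-domain RFE selection -> local PCA rotation and composite
fusion -> two-layer stacking. Time, frequency and time-frequency features
are deterministic per-trial functions and can be computed once per dataset;
the supervised stages (CSP, selection, rotation, LDA, classifiers) are fit
on training trials only and applied unchanged to held-out trials.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from .containers import DOMAIN_ORDER, CompositeFeatureTable, Domain, DomainFeatureTable, EpochedEEG
from .csp import apply_csp, default_filter_bank, fit_csp
from .exceptions import ConfigurationError
from .features import (
    BandDefinition,
    HiguchiConfig,
    frequency_domain_features,
    time_domain_features,
    timefrequency_features,
)
from .preprocessing import PreprocessConfig, bandpass_filter
from .rotation import RotationTransform, apply_rotation, compose_features, fit_rotation
from .selection import SelectionResult, rfe_rf
from .stacking import StackedModel, fit_stacking, predict_stacking

__all__ = [
    "PipelineConfig",
    "DomainInputs",
    "precompute_domain_inputs",
    "DomainFeatureExtractor",
    "MultiDomainPipeline",
]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, serializable to one YAML file.

    ``na`` is the per-domain feature count kept by RFE; the string "auto"
    resolves to the smallest domain width so every domain can reach it.
    ``K`` is the number of rotation subspaces, ``csp_m`` the retained CSP
    filter pairs per sub-band.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bands: BandDefinition = field(default_factory=BandDefinition)
    higuchi: HiguchiConfig = field(default_factory=HiguchiConfig)
    csp_m: int = 2
    filterbank: list[tuple[float, float]] = field(default_factory=default_filter_bank)
    na: int | str = "auto"
    K: int = 7
    resample_fraction: float = 0.75
    base_kind: str = "random_forest"
    oof_folds: int = 5
    use_lda: bool = True
    feature_set: str = "composite"  # base-classifier input: significant | rotated | composite
    rfe_rf_params: dict | None = None
    cv_folds: int = 5
    cv_repeats: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.feature_set not in ("significant", "rotated", "composite"):
            raise ConfigurationError(f"unknown feature_set {self.feature_set!r}")
        if isinstance(self.na, str) and self.na != "auto":
            raise ConfigurationError(f"na must be an integer or 'auto', got {self.na!r}")
        if self.K < 1:
            raise ConfigurationError(f"K must be >= 1, got {self.K}")

    def resolve_na(self, domain_widths: dict[Domain, int]) -> int:
        na = min(domain_widths.values()) if self.na == "auto" else int(self.na)
        too_narrow = {d.value: w for d, w in domain_widths.items() if w < na}
        if too_narrow:
            raise ConfigurationError(
                f"na={na} exceeds the width of domain tables {too_narrow}"
            )
        if na < self.K:
            raise ConfigurationError(f"na={na} must be at least K={self.K} rotation blocks")
        return na

    # -- single-file serialization ------------------------------------------
    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, (tuple, list)):
                return [listify(v) for v in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        payload = asdict(self)
        payload["preprocess"] = asdict(self.preprocess)
        payload["bands"] = asdict(self.bands)
        payload["higuchi"] = asdict(self.higuchi)
        return listify(payload)  # JSON/YAML-stable: tuples become lists

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        pre = payload.pop("preprocess", {})
        bands = payload.pop("bands", {})
        hig = payload.pop("higuchi", {})
        cfg = cls(
            preprocess=PreprocessConfig(
                band=tuple(pre.get("band", (8.0, 30.0))),
                filter_order=pre.get("filter_order", 5),
                epoch_window=tuple(pre.get("epoch_window", (0.5, 3.5))),
            ),
            bands=BandDefinition(
                alpha=tuple(bands.get("alpha", (8.0, 13.0))),
                beta=tuple(bands.get("beta", (13.0, 30.0))),
            ),
            higuchi=HiguchiConfig(l_max=hig.get("l_max", 10)),
            **{k: v for k, v in payload.items() if k in cls.__dataclass_fields__},
        )
        cfg.filterbank = [tuple(b) for b in cfg.filterbank]
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class DomainInputs:
    """Trial-level quantities that do not depend on any fitted stage.

    Holds the stateless time/frequency/time-frequency feature tables for
    all trials plus the per-sub-band filtered tensors the filter-bank CSP
    consumes. Computing these once per dataset is safe (no supervision is
    involved) and lets cross-validation refit only the supervised stages.
    """

    tables: dict[Domain, DomainFeatureTable]
    band_filtered: list[tuple[tuple[float, float], np.ndarray]]
    labels: np.ndarray
    fs: float
    n_trials: int


def precompute_domain_inputs(config: PipelineConfig, epochs: EpochedEEG) -> DomainInputs:
    """Band-pass, extract stateless features and pre-filter the CSP sub-bands."""
    config.validate()
    filtered = epochs.with_data(bandpass_filter(epochs.data, epochs.fs, config.preprocess))
    tables = {
        Domain.TIME: time_domain_features(filtered, config.higuchi),
        Domain.FREQUENCY: frequency_domain_features(filtered, config.bands),
        Domain.TIME_FREQUENCY: timefrequency_features(filtered),
    }
    band_filtered = [
        (
            band,
            bandpass_filter(
                epochs.data,
                epochs.fs,
                PreprocessConfig(band=band, filter_order=config.preprocess.filter_order),
            ),
        )
        for band in config.filterbank
    ]
    return DomainInputs(tables, band_filtered, epochs.labels.copy(), epochs.fs, epochs.n_trials)


class DomainFeatureExtractor:
    """Fits the filter-bank CSP stage and produces the four domain tables."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.csp_models_ = None

    def fit(self, inputs: DomainInputs, idx: np.ndarray) -> "DomainFeatureExtractor":
        idx = np.asarray(idx)
        self.csp_models_ = []
        for band, tensor in inputs.band_filtered:
            sub = EpochedEEG(tensor[idx], inputs.labels[idx], inputs.fs)
            # tensors are already band-filtered, so fit on them directly
            model = fit_csp(sub, m=self.config.csp_m)
            model.band = band  # tag for feature naming / later prefiltering
            self.csp_models_.append(model)
        return self

    def transform(self, inputs: DomainInputs, idx: np.ndarray) -> dict[Domain, DomainFeatureTable]:
        if self.csp_models_ is None:
            raise ConfigurationError("extractor is not fitted")
        idx = np.asarray(idx)
        tables = {d: t.select_rows(idx) for d, t in inputs.tables.items()}
        sd_tables = []
        for model, (band, tensor) in zip(self.csp_models_, inputs.band_filtered):
            sub = EpochedEEG(tensor[idx], inputs.labels[idx], inputs.fs)
            sd_tables.append(apply_csp(model, sub))
        values = np.hstack([t.values for t in sd_tables])
        names = [name for t in sd_tables for name in t.feature_names]
        tables[Domain.SPATIAL] = DomainFeatureTable(values, Domain.SPATIAL, names)
        return tables


@dataclass
class _DomainStages:
    selection: SelectionResult
    rotation: RotationTransform


class MultiDomainPipeline:
    """Full trainable pipeline; fit on training trials, predict on held-out ones."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.extractor_: DomainFeatureExtractor | None = None
        self.stages_: dict[Domain, _DomainStages] = {}
        self.stacked_: StackedModel | None = None
        self.na_: int | None = None

    # -- internal helpers ----------------------------------------------------
    def _seed_for(self, stage: str, domain: Domain | None = None) -> int:
        tag = f"{stage}:{domain.value if domain else '-'}"
        mix = np.random.SeedSequence([self.config.seed, zlib.crc32(tag.encode())])
        return int(mix.generate_state(1)[0] % (2**31))

    def _selected_tables(
        self, tables: dict[Domain, DomainFeatureTable]
    ) -> tuple[dict[Domain, np.ndarray], dict[Domain, CompositeFeatureTable]]:
        significant, composite = {}, {}
        for domain in DOMAIN_ORDER:
            stages = self.stages_[domain]
            sig = tables[domain].select_columns(stages.selection.selected_indices)
            rotated = apply_rotation(stages.rotation, sig.values)
            significant[domain] = sig.values
            composite[domain] = compose_features(sig, rotated)
        return significant, composite

    def _base_input(
        self,
        significant: dict[Domain, np.ndarray],
        composite: dict[Domain, CompositeFeatureTable],
    ) -> dict[Domain, np.ndarray]:
        kind = self.config.feature_set
        if kind == "composite":
            return {d: c.values for d, c in composite.items()}
        if kind == "significant":
            return significant
        n_rot = {d: c.values.shape[1] // 2 for d, c in composite.items()}
        return {d: composite[d].values[:, : n_rot[d]] for d in composite}

    # -- public API ----------------------------------------------------------
    def fit(
        self,
        epochs: EpochedEEG | None = None,
        *,
        inputs: DomainInputs | None = None,
        idx: np.ndarray | None = None,
    ) -> "MultiDomainPipeline":
        if inputs is None:
            if epochs is None:
                raise ConfigurationError("provide either epochs or precomputed inputs")
            inputs = precompute_domain_inputs(self.config, epochs)
        idx = np.arange(inputs.n_trials) if idx is None else np.asarray(idx)
        labels = inputs.labels[idx]

        self.extractor_ = DomainFeatureExtractor(self.config).fit(inputs, idx)
        tables = self.extractor_.transform(inputs, idx)
        widths = {d: t.n_features for d, t in tables.items()}
        self.na_ = self.config.resolve_na(widths)

        self.stages_ = {}
        for domain in DOMAIN_ORDER:
            selection = rfe_rf(
                tables[domain],
                labels,
                self.na_,
                rf_params=self.config.rfe_rf_params,
                seed=self._seed_for("rfe", domain),
            )
            sig = tables[domain].select_columns(selection.selected_indices)
            transform = fit_rotation(
                sig.values,
                K=self.config.K,
                resample_fraction=self.config.resample_fraction,
                seed=self._seed_for("rotation", domain),
                labels=labels,
            )
            self.stages_[domain] = _DomainStages(selection, transform)

        significant, composite = self._selected_tables(tables)
        self.stacked_ = fit_stacking(
            self._base_input(significant, composite),
            significant,
            labels,
            base_kind=self.config.base_kind,
            oof_folds=self.config.oof_folds,
            seed=self._seed_for("stacking"),
            use_lda=self.config.use_lda,
        )
        return self

    def predict(
        self,
        epochs: EpochedEEG | None = None,
        *,
        inputs: DomainInputs | None = None,
        idx: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predicted labels and meta probabilities for held-out trials."""
        if self.stacked_ is None:
            raise ConfigurationError("pipeline is not fitted")
        if inputs is None:
            if epochs is None:
                raise ConfigurationError("provide either epochs or precomputed inputs")
            inputs = precompute_domain_inputs(self.config, epochs)
        idx = np.arange(inputs.n_trials) if idx is None else np.asarray(idx)
        tables = self.extractor_.transform(inputs, idx)
        significant, composite = self._selected_tables(tables)
        return predict_stacking(
            self.stacked_, self._base_input(significant, composite), significant
        )

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))
        joblib.dump(
            {"extractor": self.extractor_, "stages": self.stages_, "na": self.na_},
            directory / "stages.joblib",
        )
        self.stacked_.save(directory / "stacked")

    @classmethod
    def load(cls, directory: str | Path) -> "MultiDomainPipeline":
        directory = Path(directory)
        pipeline = cls(PipelineConfig.from_dict(json.loads((directory / "config.json").read_text())))
        bundle = joblib.load(directory / "stages.joblib")
        pipeline.extractor_ = bundle["extractor"]
        pipeline.stages_ = bundle["stages"]
        pipeline.na_ = bundle["na"]
        pipeline.stacked_ = StackedModel.load(directory / "stacked")
        return pipeline
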