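"""Metrics, repeated stratified cross-validation and protocol-level probes.

Binary metrics (accuracy, precision, recall, F1) are computed from
confusion counts with the numerically larger label as the positive class.
The evaluation protocol is repeated stratified k-fold cross-validation
(default 5 x 5-fold, a 4:1 split); every supervised stage — CSP, feature
selection, rotation, LDA, base and meta classifiers — is refit inside each
training fold. A label-permutation probe and a feature-count sweep support
leakage checks and selection-size studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import DOMAIN_ORDER, EpochedEEG
from .exceptions import ConfigurationError
from .pipeline import (
    DomainFeatureExtractor,
    DomainInputs,
    MultiDomainPipeline,
    PipelineConfig,
    precompute_domain_inputs,
)
from .rotation import apply_rotation, compose_features, fit_rotation
from .selection import rfe_rf
from .stacking import (
    fit_stacking,
    make_base_classifier,
    oof_probability_blocks,
    predict_stacking,
)

__all__ = [
    "ConfusionCounts",
    "compute_metrics",
    "CVReport",
    "cross_validate",
    "permutation_null",
    "feature_count_sweep",
    "strategy_comparison",
]

METRIC_NAMES = ("acc", "prec", "rec", "f1")


@dataclass
class ConfusionCounts:
    """Binary confusion counts; the numerically larger label is 'positive'."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def n_evaluated(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, positive=None
    ) -> "ConfusionCounts":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        if positive is None:
            positive = np.unique(np.concatenate([y_true, y_pred])).max()
        t, p = y_true == positive, y_pred == positive
        return cls(
            TP=int(np.sum(t & p)),
            FP=int(np.sum(~t & p)),
            TN=int(np.sum(~t & ~p)),
            FN=int(np.sum(t & ~p)),
        )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Ratios with a zero denominator are defined as 0 with a warning.
    """
    if counts.n_evaluated == 0:
        raise ConfigurationError("cannot compute metrics for zero evaluated trials")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} denominator is zero; defining {name}=0")
            return 0.0
        return num / den

    acc = (counts.TP + counts.TN) / counts.n_evaluated
    prec = ratio(counts.TP, counts.TP + counts.FP, "precision")
    rec = ratio(counts.TP, counts.TP + counts.FN, "recall")
    f1 = ratio_f1(prec, rec)
    return {"acc": acc, "prec": prec, "rec": rec, "f1": f1}


def ratio_f1(prec: float, rec: float) -> float:
    if prec + rec == 0:
        warnings.warn("F1 denominator is zero; defining F1=0")
        return 0.0
    return 2.0 * prec * rec / (prec + rec)


@dataclass
class CVReport:
    """Per-repeat, per-fold metric entries with config snapshot and seed."""

    entries: list[dict] = field(default_factory=list)
    config_snapshot: dict = field(default_factory=dict)
    seed: int = 0
    n_folds: int = 5
    n_repeats: int = 5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def mean(self, metric: str = "acc") -> float:
        return float(self.to_frame()[metric].mean())

    def std(self, metric: str = "acc") -> float:
        return float(self.to_frame()[metric].std(ddof=1))

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [f"{self.n_repeats} x {self.n_folds}-fold cross-validation ({len(frame)} folds)"]
        for m in METRIC_NAMES:
            lines.append(f"  {m:<5} {100 * frame[m].mean():6.2f} % +/- {100 * frame[m].std(ddof=1):.2f}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "entries": self.entries,
                    "config_snapshot": self.config_snapshot,
                    "seed": self.seed,
                    "n_folds": self.n_folds,
                    "n_repeats": self.n_repeats,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "CVReport":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def _check_fold_feasibility(labels: np.ndarray, n_folds: int) -> None:
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ConfigurationError(
            f"need at least n_folds={n_folds} trials per class, min is {counts.min()}"
        )


def cross_validate(
    config: PipelineConfig,
    epochs: EpochedEEG,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int | None = None,
    inputs: DomainInputs | None = None,
) -> CVReport:
    """Repeated stratified k-fold evaluation of the full pipeline.

    Folds are stratified; repeat ``r`` reshuffles with ``seed + r``. All
    supervised stages are refit per training fold.
    """
    seed = config.seed if seed is None else seed
    _check_fold_feasibility(epochs.labels, n_folds)
    inputs = inputs or precompute_domain_inputs(config, epochs)
    report = CVReport(
        config_snapshot=config.to_dict(), seed=seed, n_folds=n_folds, n_repeats=n_repeats
    )
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + r)
        for f, (train_idx, test_idx) in enumerate(
            skf.split(np.zeros(inputs.n_trials), inputs.labels)
        ):
            pipeline = MultiDomainPipeline(replace(config, seed=seed + r)).fit(
                inputs=inputs, idx=train_idx
            )
            predictions, _ = pipeline.predict(inputs=inputs, idx=test_idx)
            counts = ConfusionCounts.from_predictions(inputs.labels[test_idx], predictions)
            entry = {"repeat": r, "fold": f, "n_test": len(test_idx)}
            entry.update(compute_metrics(counts))
            report.entries.append(entry)
    return report


def permutation_null(
    config: PipelineConfig,
    epochs: EpochedEEG,
    n_permutations: int = 10,
    n_folds: int = 5,
    seed: int | None = None,
    inputs: DomainInputs | None = None,
) -> np.ndarray:
    """Mean CV accuracy under label permutation (leakage probe).

    Every supervised stage sees only permuted labels; accuracies should
    center on chance level. Returns one mean accuracy per permutation.
    """
    seed = config.seed if seed is None else seed
    inputs = inputs or precompute_domain_inputs(config, epochs)
    rng = np.random.default_rng(seed)
    means = []
    for p in range(n_permutations):
        permuted = rng.permutation(inputs.labels)
        shuffled = replace(inputs, labels=permuted)
        report = cross_validate(
            replace(config, seed=seed + 1000 + p),
            epochs,
            n_folds=n_folds,
            n_repeats=1,
            seed=seed + 1000 + p,
            inputs=shuffled,
        )
        means.append(report.mean("acc"))
    return np.asarray(means)


def feature_count_sweep(
    config: PipelineConfig,
    epochs: EpochedEEG,
    na_grid: list[int],
    n_folds: int = 5,
    n_repeats: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean CV accuracy per RFE target count Na (selection-size study)."""
    if len(na_grid) == 0:
        raise ConfigurationError("na_grid must contain at least one value")
    inputs = precompute_domain_inputs(config, epochs)
    rows = []
    for na in na_grid:
        report = cross_validate(
            replace(config, na=int(na)),
            epochs,
            n_folds=n_folds,
            n_repeats=n_repeats,
            seed=seed,
            inputs=inputs,
        )
        rows.append({"na": int(na), "mean_acc": report.mean("acc"), "std_acc": report.std("acc")})
    return pd.DataFrame(rows)


def strategy_comparison(
    config: PipelineConfig,
    epochs: EpochedEEG,
    n_folds: int = 5,
    seed: int | None = None,
    inputs: DomainInputs | None = None,
) -> dict[str, float]:
    """Compare feature and fusion strategies on shared folds.

    Per fold (with selection, rotation and all classifiers refit on the
    training part): a single base classifier per domain evaluated on the
    significant features and on the composite features (rotation-fusion
    effect), and the stacking ensemble on significant-feature bases without
    and with the LDA supplement (stacking-fusion effect). Returns mean
    accuracies, with per-domain accuracies averaged over domains.
    """
    seed = config.seed if seed is None else seed
    inputs = inputs or precompute_domain_inputs(config, epochs)
    _check_fold_feasibility(inputs.labels, n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)

    acc: dict[str, list[float]] = {
        "significant": [],
        "composite": [],
        "stacking": [],
        "stacking_fusion": [],
    }
    pipeline_cfg = replace(config, seed=seed)
    for train_idx, test_idx in skf.split(np.zeros(inputs.n_trials), inputs.labels):
        y_train, y_test = inputs.labels[train_idx], inputs.labels[test_idx]
        extractor = DomainFeatureExtractor(pipeline_cfg).fit(inputs, train_idx)
        tables_train = extractor.transform(inputs, train_idx)
        tables_test = extractor.transform(inputs, test_idx)
        na = pipeline_cfg.resolve_na({d: t.n_features for d, t in tables_train.items()})

        sig_train, sig_test, comp_train, comp_test = {}, {}, {}, {}
        domain_acc = {"significant": [], "composite": []}
        for domain in DOMAIN_ORDER:
            selection = rfe_rf(
                tables_train[domain], y_train, na,
                rf_params=pipeline_cfg.rfe_rf_params, seed=seed + 17,
            )
            s_train = tables_train[domain].select_columns(selection.selected_indices)
            s_test = tables_test[domain].select_columns(selection.selected_indices)
            transform = fit_rotation(
                s_train.values, K=pipeline_cfg.K,
                resample_fraction=pipeline_cfg.resample_fraction,
                seed=seed + 31, labels=y_train,
            )
            sig_train[domain], sig_test[domain] = s_train.values, s_test.values
            comp_train[domain] = compose_features(s_train, apply_rotation(transform, s_train.values))
            comp_test[domain] = compose_features(s_test, apply_rotation(transform, s_test.values))

            for name, (ftr, fte) in {
                "significant": (sig_train[domain], sig_test[domain]),
                "composite": (comp_train[domain].values, comp_test[domain].values),
            }.items():
                clf = make_base_classifier(pipeline_cfg.base_kind, seed)
                clf.fit(ftr, y_train)
                domain_acc[name].append(float(np.mean(clf.predict(fte) == y_test)))
        acc["significant"].append(float(np.mean(domain_acc["significant"])))
        acc["composite"].append(float(np.mean(domain_acc["composite"])))

        # stacking variants share base classifiers and out-of-fold blocks
        oof = oof_probability_blocks(
            sig_train, y_train, pipeline_cfg.base_kind,
            pipeline_cfg.oof_folds, seed, list(DOMAIN_ORDER),
        )
        for name, use_lda in (("stacking", False), ("stacking_fusion", True)):
            model = fit_stacking(
                sig_train, sig_train, y_train,
                base_kind=pipeline_cfg.base_kind, oof_folds=pipeline_cfg.oof_folds,
                seed=seed, use_lda=use_lda, _oof_probabilities=oof,
            )
            predictions, _ = predict_stacking(model, sig_test, sig_test)
            acc[name].append(float(np.mean(predictions == y_test)))
    return {name: float(np.mean(values)) for name, values in acc.items()}
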