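"""Two-layer stacking ensemble over per-domain composite features.

Layer one trains a base classifier per feature domain on that domain's
composite features and emits class-probability vectors; the probabilities
the meta-classifier trains on are produced out-of-fold through an internal
stratified split to avoid label leakage. The concatenated significant
features of all domains are additionally projected by linear discriminant
analysis to C-1 coordinates and appended as supplementary meta-features.
Layer two is a one-hidden-layer perceptron over
``[P_td | P_fd | P_tfd | P_sd | f_LDA]``; per-domain contribution rates are
read off its absolute input-to-output weight mass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import DOMAIN_ORDER, CompositeFeatureTable, Domain
from .exceptions import ConfigurationError

__all__ = [
    "StackedModel",
    "make_base_classifier",
    "lda_features",
    "fit_stacking",
    "predict_stacking",
    "contribution_rates",
]

BASE_KINDS = ("random_forest", "svm_rbf", "svm_linear")


def make_base_classifier(kind: str, seed: int):
    """Base classifier with library-default settings.

    Forests run on raw features; SVMs are standardized and get probability
    outputs through 3-fold sigmoid calibration.
    """
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if kind in ("svm_rbf", "svm_linear"):
        kernel = "rbf" if kind == "svm_rbf" else "linear"
        svc = SVC(kernel=kernel, C=1.0, gamma="scale", random_state=seed)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", CalibratedClassifierCV(svc, cv=3, method="sigmoid")),
            ]
        )
    raise ConfigurationError(f"unknown base classifier kind {kind!r}; choose from {BASE_KINDS}")


def _make_meta(meta_params: dict | None, seed: int) -> Pipeline:
    params = dict(
        hidden_layer_sizes=(100,),
        activation="relu",
        solver="adam",
        max_iter=200,
        random_state=seed,
    )
    params.update(meta_params or {})
    return Pipeline([("scale", StandardScaler()), ("mlp", MLPClassifier(**params))])


def lda_features(
    significant_concat: np.ndarray, labels: np.ndarray
) -> tuple[LinearDiscriminantAnalysis, np.ndarray]:
    """LDA projection of concatenated significant features to C-1 coordinates.

    Uses the eigen solver with automatic (Ledoit-Wolf) shrinkage of the
    within-class scatter, which keeps the projection defined when the
    feature count exceeds the trial count.
    """
    X = np.atleast_2d(np.asarray(significant_concat, dtype=float))
    labels = np.asarray(labels)
    if X.shape[0] <= X.shape[1]:
        warnings.warn("fewer trials than features: LDA relies on shrinkage regularization")
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
    lda.fit(X, labels)
    return lda, lda.transform(X)


@dataclass
class StackedModel:
    """Per-domain base classifiers, LDA supplement and trained meta-classifier."""

    base_models: dict[Domain, object]
    base_kind: str
    lda_projector: LinearDiscriminantAnalysis | None
    meta_model: Pipeline
    domains: list[Domain]
    classes_: np.ndarray
    oof_folds: int
    seed: int

    @property
    def n_classes(self) -> int:
        return self.classes_.size

    @property
    def meta_input_width(self) -> int:
        lda_cols = self.n_classes - 1 if self.lda_projector is not None else 0
        return len(self.domains) * self.n_classes + lda_cols

    # -- directory bundle ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "base_kind": self.base_kind,
            "domains": [d.value for d in self.domains],
            "classes": self.classes_.tolist(),
            "oof_folds": self.oof_folds,
            "seed": self.seed,
            "has_lda": self.lda_projector is not None,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for domain, model in self.base_models.items():
            joblib.dump(model, directory / f"base_{domain.value}.joblib")
        if self.lda_projector is not None:
            joblib.dump(self.lda_projector, directory / "lda.joblib")
        joblib.dump(self.meta_model, directory / "meta.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "StackedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        domains = [Domain(d) for d in manifest["domains"]]
        base_models = {
            d: joblib.load(directory / f"base_{d.value}.joblib") for d in domains
        }
        lda = joblib.load(directory / "lda.joblib") if manifest["has_lda"] else None
        return cls(
            base_models=base_models,
            base_kind=manifest["base_kind"],
            lda_projector=lda,
            meta_model=joblib.load(directory / "meta.joblib"),
            domains=domains,
            classes_=np.asarray(manifest["classes"]),
            oof_folds=manifest["oof_folds"],
            seed=manifest["seed"],
        )


def _composite_values(table) -> np.ndarray:
    return table.values if isinstance(table, CompositeFeatureTable) else np.asarray(table)


def _aligned_proba(clf, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """predict_proba with columns aligned to the global sorted class order."""
    proba = clf.predict_proba(X)
    out = np.zeros((X.shape[0], classes.size))
    for j, cls in enumerate(clf.classes_):
        out[:, np.searchsorted(classes, cls)] = proba[:, j]
    return out


def fit_stacking(
    composite_tables: dict[Domain, CompositeFeatureTable | np.ndarray],
    significant_tables: dict[Domain, np.ndarray],
    labels: np.ndarray,
    base_kind: str = "random_forest",
    meta_params: dict | None = None,
    oof_folds: int = 5,
    seed: int = 0,
    use_lda: bool = True,
    domains: tuple[Domain, ...] = DOMAIN_ORDER,
    _oof_probabilities: dict[Domain, np.ndarray] | None = None,
) -> StackedModel:
    """Train the two-layer stacking model.

    Meta-training probabilities are produced out-of-fold with an internal
    stratified ``oof_folds`` split; base models are then refit on all
    training data. ``use_lda=False`` trains the plain stacking variant
    without the discriminant supplement. ``_oof_probabilities`` lets callers
    that compare meta-variants on identical bases reuse precomputed
    out-of-fold blocks.
    """
    domains = [Domain.coerce(d) for d in domains]
    missing = [d.value for d in domains if d not in composite_tables]
    if missing:
        raise ConfigurationError(f"missing composite tables for domains: {missing}")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ConfigurationError("stacking requires at least two classes")
    n = labels.size
    for d in domains:
        if _composite_values(composite_tables[d]).shape[0] != n:
            raise ConfigurationError(f"composite table for {d.value} has wrong trial count")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < oof_folds:
        raise ConfigurationError(
            f"need at least oof_folds={oof_folds} trials per class, min is {counts.min()}"
        )

    # out-of-fold probability blocks per domain
    if _oof_probabilities is None:
        _oof_probabilities = oof_probability_blocks(
            composite_tables, labels, base_kind, oof_folds, seed, domains
        )

    meta_blocks = [_oof_probabilities[d] for d in domains]
    lda = None
    if use_lda:
        concat = np.hstack([np.atleast_2d(significant_tables[d]) for d in domains])
        lda, projected = lda_features(concat, labels)
        meta_blocks.append(projected)
    meta_X = np.hstack(meta_blocks)

    meta = _make_meta(meta_params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        meta.fit(meta_X, labels)

    base_models = {}
    for d in domains:
        clf = make_base_classifier(base_kind, seed)
        clf.fit(_composite_values(composite_tables[d]), labels)
        base_models[d] = clf

    return StackedModel(
        base_models=base_models,
        base_kind=base_kind,
        lda_projector=lda,
        meta_model=meta,
        domains=domains,
        classes_=classes,
        oof_folds=oof_folds,
        seed=seed,
    )


def oof_probability_blocks(
    composite_tables: dict[Domain, CompositeFeatureTable | np.ndarray],
    labels: np.ndarray,
    base_kind: str,
    oof_folds: int,
    seed: int,
    domains: list[Domain],
) -> dict[Domain, np.ndarray]:
    """Out-of-fold class-probability matrix (n_trials x C) per domain."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    skf = StratifiedKFold(n_splits=oof_folds, shuffle=True, random_state=seed)
    blocks: dict[Domain, np.ndarray] = {}
    for d in domains:
        X = _composite_values(composite_tables[d])
        proba = np.zeros((labels.size, classes.size))
        for train_idx, test_idx in skf.split(X, labels):
            clf = make_base_classifier(base_kind, seed)
            clf.fit(X[train_idx], labels[train_idx])
            proba[test_idx] = _aligned_proba(clf, X[test_idx], classes)
        blocks[d] = proba
    return blocks


def predict_stacking(
    model: StackedModel,
    composite_tables: dict[Domain, CompositeFeatureTable | np.ndarray],
    significant_tables: dict[Domain, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and meta probabilities for new trials.

    Ties in the meta probabilities break toward the lower class index.
    """
    blocks = []
    for d in model.domains:
        X = _composite_values(composite_tables[d])
        blocks.append(_aligned_proba(model.base_models[d], X, model.classes_))
    if model.lda_projector is not None:
        if significant_tables is None:
            raise ConfigurationError("model uses the LDA supplement; significant tables required")
        concat = np.hstack([np.atleast_2d(significant_tables[d]) for d in model.domains])
        blocks.append(model.lda_projector.transform(concat))
    meta_X = np.hstack(blocks)
    if meta_X.shape[1] != model.meta_input_width:
        raise ConfigurationError(
            f"meta input width {meta_X.shape[1]} does not match fitted width "
            f"{model.meta_input_width}"
        )
    proba = model.meta_model.predict_proba(meta_X)
    predictions = model.classes_[np.argmax(proba, axis=1)]
    return predictions, proba


def contribution_rates(
    model: StackedModel,
) -> tuple[dict[Domain, float], float | None]:
    """Per-domain contribution percentages from the meta-perceptron weights.

    For meta input ``i``, importance is
    ``sum_h |W_in[i, h]| * sum_o |W_out[h, o]|``; a domain's contribution
    sums its C probability inputs and the four domains are normalized to
    100%. The LDA supplement's share of the total weight mass is reported
    separately (None when the model has no supplement).
    """
    mlp = model.meta_model[-1] if isinstance(model.meta_model, Pipeline) else model.meta_model
    if not isinstance(mlp, MLPClassifier) or len(mlp.coefs_) != 2:
        raise ConfigurationError(
            "contribution rates require a one-hidden-layer perceptron meta-classifier"
        )
    w_in, w_out = np.abs(mlp.coefs_[0]), np.abs(mlp.coefs_[1])
    hidden_mass = w_out.sum(axis=1)  # sum_o |W_out[h, o]|
    importance = w_in @ hidden_mass  # per meta input

    C = model.n_classes
    domain_mass = {
        d: float(importance[k * C : (k + 1) * C].sum()) for k, d in enumerate(model.domains)
    }
    total_domain = sum(domain_mass.values())
    rates = {d: 100.0 * m / total_domain for d, m in domain_mass.items()}
    lda_share = None
    if model.lda_projector is not None:
        lda_mass = float(importance[len(model.domains) * C :].sum())
        lda_share = 100.0 * lda_mass / float(importance.sum())
    return rates, lda_share
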