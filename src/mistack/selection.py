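"""Recursive feature elimination driven by random-forest importance.

Backward selection in the wrapper style: fit a forest on the surviving
features, rank the impurity-based importances, drop the single least
important feature, refit, and stop once the target count Na remains. The
procedure is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .containers import DomainFeatureTable
from .exceptions import ConfigurationError

__all__ = ["SelectionResult", "rfe_rf", "apply_selection"]

DEFAULT_RF_PARAMS = {"n_estimators": 100}


@dataclass
class SelectionResult:
    """Outcome of RFE: surviving column indices plus the elimination trace."""

    selected_indices: np.ndarray
    target_count: int
    elimination_trace: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "selected_indices": self.selected_indices.tolist(),
                    "target_count": self.target_count,
                    "elimination_trace": [
                        [int(i), float(v)] for i, v in self.elimination_trace
                    ],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["selected_indices"]),
            payload["target_count"],
            [(int(i), float(v)) for i, v in payload["elimination_trace"]],
        )


def rfe_rf(
    features: DomainFeatureTable | np.ndarray,
    labels: np.ndarray,
    target_count: int,
    rf_params: dict | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Select ``target_count`` features by recursive elimination with a forest.

    One feature is removed per iteration (the one with the smallest mean
    impurity decrease; ties break toward the lowest column index). With
    ``target_count == n_features`` this is the identity selection with an
    empty trace.
    """
    values = features.values if isinstance(features, DomainFeatureTable) else np.asarray(features)
    labels = np.asarray(labels)
    n, p = values.shape
    if labels.shape != (n,):
        raise ConfigurationError(f"labels shape {labels.shape} does not match {n} trials")
    if not (1 <= target_count <= p):
        raise ConfigurationError(f"target_count must be in 1..{p}, got {target_count}")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ConfigurationError("need at least 2 trials per class for forest fitting")

    params = dict(DEFAULT_RF_PARAMS)
    params.update(rf_params or {})
    rng = np.random.default_rng(seed)

    remaining = list(range(p))
    trace: list[tuple[int, float]] = []
    while len(remaining) > target_count:
        forest = RandomForestClassifier(
            **params, random_state=int(rng.integers(2**31))
        ).fit(values[:, remaining], labels)
        importances = forest.feature_importances_
        worst = int(np.argmin(importances))  # first minimum -> lowest index on ties
        trace.append((remaining[worst], float(importances[worst])))
        del remaining[worst]
    return SelectionResult(np.asarray(remaining), target_count, trace)


def apply_selection(
    features: DomainFeatureTable, result: SelectionResult
) -> DomainFeatureTable:
    """Column subset of a feature table according to a selection result."""
    return features.select_columns(result.selected_indices)
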