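"""Local PCA rotation of the selected feature space and composite fusion.

Following the rotation-forest construction, the Na selected features are
randomly partitioned into K disjoint subspaces; each subspace is PCA-rotated
using the principal-component coefficients estimated on a 75% subsample of
the trials, keeping all components so the per-block coefficient matrices are
square and orthonormal. The block-diagonal coefficient matrix, with rows
re-ordered to the original feature order, forms the orthogonal rotation
R'' applied as ``F_rotated = F_rfe @ R''``. Composite features concatenate
the rotated block with the original selected block.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .containers import CompositeFeatureTable, Domain, DomainFeatureTable
from .exceptions import ConfigurationError

__all__ = ["RotationTransform", "fit_rotation", "apply_rotation", "compose_features"]


@dataclass
class RotationTransform:
    """Fitted subspace partition and assembled rotation matrix.

    subspace_assignment : list of index arrays into the original Na columns,
        one per block (disjoint, covering all columns).
    block_coefficients : per-block square coefficient matrices with
        orthonormal columns.
    rotation_matrix : the (Na, Na) orthogonal matrix R''; input rows are in
        original feature order, output columns in block order.
    """

    subspace_assignment: list[np.ndarray]
    block_coefficients: list[np.ndarray]
    rotation_matrix: np.ndarray
    seed: int

    @property
    def n_features(self) -> int:
        return self.rotation_matrix.shape[0]

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        arrays = {"rotation_matrix": self.rotation_matrix}
        for j, (cols, block) in enumerate(
            zip(self.subspace_assignment, self.block_coefficients)
        ):
            arrays[f"cols_{j}"] = cols
            arrays[f"block_{j}"] = block
        np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
        prefix.with_suffix(".json").write_text(
            json.dumps({"seed": self.seed, "n_blocks": len(self.subspace_assignment)})
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "RotationTransform":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        with np.load(prefix.with_suffix(".npz")) as npz:
            assignment = [npz[f"cols_{j}"] for j in range(meta["n_blocks"])]
            blocks = [npz[f"block_{j}"] for j in range(meta["n_blocks"])]
            rot = npz["rotation_matrix"]
        return cls(assignment, blocks, rot, meta["seed"])


def _fix_signs(coefficients: np.ndarray) -> np.ndarray:
    """Force the largest-magnitude loading of each component to be positive."""
    out = coefficients.copy()
    for col in range(out.shape[1]):
        peak = np.argmax(np.abs(out[:, col]))
        if out[peak, col] < 0:
            out[:, col] = -out[:, col]
    return out


def _subsample(
    rng: np.random.Generator, n: int, fraction: float, labels: np.ndarray | None
) -> np.ndarray:
    """Trial subsample without replacement, class-stratified when labels given."""
    n_sub = int(np.ceil(fraction * n))
    if labels is None:
        return rng.choice(n, size=n_sub, replace=False)
    picked = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        k = int(np.ceil(fraction * members.size))
        picked.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(picked))


def fit_rotation(
    significant: np.ndarray | DomainFeatureTable,
    K: int,
    resample_fraction: float = 0.75,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> RotationTransform:
    """Fit the local rotation on the (n_trials, Na) selected feature matrix.

    The Na columns are split into K random disjoint blocks of size
    floor(Na/K) or ceil(Na/K) (remainder features go one-per-block to the
    first blocks). Per block, the principal-component coefficients of a
    ``resample_fraction`` trial subsample (centered for estimation, applied
    to the uncentered features) form the square block of the rotation
    matrix; component signs are fixed so the largest-magnitude loading is
    positive. A zero-variance block falls back to identity with a warning.
    """
    X = significant.values if isinstance(significant, DomainFeatureTable) else np.asarray(significant)
    X = np.atleast_2d(X)
    n, na = X.shape
    if not (1 <= K <= na):
        raise ConfigurationError(f"K must be in 1..{na}, got {K}")
    if not (0.0 < resample_fraction <= 1.0):
        raise ConfigurationError(f"resample fraction must be in (0, 1], got {resample_fraction}")

    rng = np.random.default_rng(seed)
    permuted = rng.permutation(na)
    base, remainder = divmod(na, K)
    sizes = [base + 1 if j < remainder else base for j in range(K)]

    assignment: list[np.ndarray] = []
    blocks: list[np.ndarray] = []
    rotation = np.zeros((na, na))
    start = 0
    out_col = 0
    for size in sizes:
        cols = permuted[start : start + size]
        start += size
        rows = _subsample(rng, n, resample_fraction, labels)
        if rows.size < size:
            raise ConfigurationError(
                f"subsample of {rows.size} trials cannot support PCA on a {size}-feature block"
            )
        block_data = X[np.ix_(rows, cols)]
        if np.allclose(block_data.var(axis=0), 0.0):
            warnings.warn("zero-variance subspace: using identity coefficients for this block")
            coef = np.eye(size)
        else:
            pca = PCA(n_components=size, svd_solver="full").fit(block_data)
            coef = _fix_signs(pca.components_.T)  # columns = components
        assignment.append(cols)
        blocks.append(coef)
        rotation[np.ix_(cols, np.arange(out_col, out_col + size))] = coef
        out_col += size
    return RotationTransform(assignment, blocks, rotation, seed)


def apply_rotation(
    transform: RotationTransform, significant: np.ndarray | DomainFeatureTable
) -> np.ndarray:
    """Rotate selected features: ``F_rotated = F_rfe @ R''`` (no refit)."""
    X = significant.values if isinstance(significant, DomainFeatureTable) else np.asarray(significant)
    X = np.atleast_2d(X)
    if X.shape[1] != transform.n_features:
        raise ConfigurationError(
            f"expected {transform.n_features} columns, got {X.shape[1]}"
        )
    return X @ transform.rotation_matrix


def compose_features(
    significant: np.ndarray | DomainFeatureTable,
    rotated: np.ndarray,
    domain: Domain | None = None,
) -> CompositeFeatureTable:
    """Concatenate [rotated | significant] into the composite feature table."""
    if isinstance(significant, DomainFeatureTable):
        domain = domain or significant.domain
        significant = significant.values
    significant = np.atleast_2d(np.asarray(significant))
    rotated = np.atleast_2d(np.asarray(rotated))
    if significant.shape[0] != rotated.shape[0]:
        raise ConfigurationError(
            f"row mismatch: {rotated.shape[0]} rotated vs {significant.shape[0]} significant"
        )
    if significant.shape[1] != rotated.shape[1]:
        raise ConfigurationError("rotated and significant blocks must have equal width")
    values = np.hstack([rotated, significant])
    origin = ["rotated"] * rotated.shape[1] + ["significant"] * significant.shape[1]
    return CompositeFeatureTable(values, origin, domain)
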