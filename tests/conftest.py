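import numpy as np
import pytest

from mistack import (
    EpochedEEG,
    PipelineConfig,
    SyntheticConfig,
    generate_feature_tables,
    generate_mi_eeg,
)

#: small forest for unit tests of selection/stacking mechanics (not accuracy)
FAST_RF = {"n_estimators": 25}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_epochs():
    """40-trial, 8-channel synthetic set with strong ERD (fast fixture)."""
    cfg = SyntheticConfig(n_trials_per_class=20, seed=1)
    epochs, manifest = generate_mi_eeg(cfg)
    return epochs, manifest


@pytest.fixture(scope="session")
def toy_csp_epochs(rng):
    """Two-channel trials with swapped per-class channel variances (4,1)/(1,4)."""
    n, T = 60, 200
    d0 = np.stack([np.stack([2.0 * rng.standard_normal(T), rng.standard_normal(T)]) for _ in range(n)])
    d1 = np.stack([np.stack([rng.standard_normal(T), 2.0 * rng.standard_normal(T)]) for _ in range(n)])
    labels = np.r_[np.zeros(n, int), np.ones(n, int)]
    return EpochedEEG(np.concatenate([d0, d1]), labels, 100.0)


@pytest.fixture(scope="session")
def planted_tables():
    """Feature-level fixture: strong class signal in every domain."""
    tables, labels, manifest = generate_feature_tables(
        n=120, per_domain_effect={"td": 2.0, "fd": 2.0, "tfd": 2.0, "sd": 2.0}, seed=7
    )
    return tables, labels, manifest


@pytest.fixture()
def fast_config():
    """Pipeline configuration scaled for unit-test speed."""
    return PipelineConfig(na=8, K=4, rfe_rf_params=FAST_RF, oof_folds=3)
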