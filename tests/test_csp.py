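"""Common spatial patterns: whitening identities, closed-form oracles, filter bank."""

import numpy as np
import pytest
from scipy.linalg import eigh as generalized_eigh

from mistack import (
    EpochedEEG,
    SyntheticConfig,
    apply_csp,
    apply_filterbank_csp,
    default_filter_bank,
    filterbank_csp,
    fit_csp,
    generate_mi_eeg,
)
from mistack.exceptions import ChannelMismatchError, ConfigurationError


def class_mean_cov(data):
    covs = [trial @ trial.T / np.trace(trial @ trial.T) for trial in data]
    return np.mean(covs, axis=0)


class TestFitCsp:
    def test_eigenvalue_complement(self, toy_csp_epochs):
        """W diagonalizes both class covariances and the eigenvalues sum to 1."""
        epochs = toy_csp_epochs
        model = fit_csp(epochs, m=1)
        c1 = class_mean_cov(epochs.data[epochs.labels == 0])
        c2 = class_mean_cov(epochs.data[epochs.labels == 1])
        d1 = model.W @ c1 @ model.W.T
        d2 = model.W @ c2 @ model.W.T
        np.testing.assert_allclose(d1 + d2, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(d1, np.diag(np.diag(d1)), atol=1e-10)
        np.testing.assert_allclose(np.diag(d1), model.eigenvalues, atol=1e-10)

    def test_identical_class_covariances_give_half_eigenvalues(self, rng):
        data = rng.standard_normal((30, 4, 150))
        both = np.concatenate([data, data])
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        model = fit_csp(EpochedEEG(both, labels, 100.0), m=2)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-10)

    def test_matches_closed_form_generalized_eigenproblem(self, toy_csp_epochs):
        """Filters solve C1 w = lambda (C1 + C2) w for the 2x2 case."""
        epochs = toy_csp_epochs
        model = fit_csp(epochs, m=1)
        c1 = class_mean_cov(epochs.data[epochs.labels == 0])
        c2 = class_mean_cov(epochs.data[epochs.labels == 1])
        vals, vecs = generalized_eigh(c1, c1 + c2)
        # descending order to match filter ordering
        vals, vecs = vals[::-1], vecs[:, ::-1]
        np.testing.assert_allclose(model.eigenvalues, vals, atol=1e-10)
        for row, ref in zip(model.W, vecs.T):
            cos = abs(row @ ref) / (np.linalg.norm(row) * np.linalg.norm(ref))
            assert cos == pytest.approx(1.0, abs=1e-10)

    def test_first_and_last_filters_isolate_dominant_channels(self, toy_csp_epochs):
        model = fit_csp(toy_csp_epochs, m=1)
        assert np.argmax(np.abs(model.W[0])) == 0  # class 0 has var (4, 1)
        assert np.argmax(np.abs(model.W[-1])) == 1

    def test_single_class_rejected(self, rng):
        data = rng.standard_normal((10, 3, 100))
        with pytest.raises(ConfigurationError):
            fit_csp(EpochedEEG(data, np.zeros(10, int), 100.0))

    def test_trial_rescaling_invariance(self, toy_csp_epochs, rng):
        """Trace normalization cancels positive per-trial scaling."""
        epochs = toy_csp_epochs
        scales = rng.uniform(0.1, 10.0, size=epochs.n_trials)
        scaled = EpochedEEG(
            epochs.data * scales[:, None, None], epochs.labels, epochs.fs
        )
        np.testing.assert_allclose(
            fit_csp(epochs, m=1).W, fit_csp(scaled, m=1).W, atol=1e-10
        )


class TestApplyCsp:
    def test_variance_shares_sum_to_one(self, toy_csp_epochs):
        model = fit_csp(toy_csp_epochs, m=1)
        table = apply_csp(model, toy_csp_epochs)
        np.testing.assert_allclose(np.exp(table.values).sum(axis=1), 1.0, atol=1e-10)

    def test_m1_gives_two_features(self, toy_csp_epochs):
        table = apply_csp(fit_csp(toy_csp_epochs, m=1), toy_csp_epochs)
        assert table.n_features == 2

    def test_toy_classes_separate_on_first_filter(self, toy_csp_epochs):
        epochs = toy_csp_epochs
        table = apply_csp(fit_csp(epochs, m=1), epochs)
        f1 = table.values[:, 0]
        assert f1[epochs.labels == 0].mean() > f1[epochs.labels == 1].mean()

    def test_channel_mismatch_rejected(self, toy_csp_epochs, rng):
        model = fit_csp(toy_csp_epochs, m=1)
        other = EpochedEEG(rng.standard_normal((4, 3, 100)), [0, 1, 0, 1], 100.0)
        with pytest.raises(ChannelMismatchError):
            apply_csp(model, other)


class TestFilterBank:
    def test_default_bands_and_feature_count(self, small_epochs):
        epochs, _ = small_epochs
        assert default_filter_bank() == [(8, 12), (12, 16), (16, 20), (20, 24), (24, 28), (28, 32)]
        table, models = filterbank_csp(epochs, m=2)
        assert table.n_features == 6 * 2 * 2
        assert len(models) == 6
        assert table.feature_names[0] == "band_8_12:csp_1"

    def test_single_band_reduces_to_plain_csp(self, small_epochs):
        epochs, _ = small_epochs
        table, models = filterbank_csp(epochs, bands=[(8.0, 12.0)], m=2)
        plain = apply_csp(fit_csp(epochs, m=2, band=(8.0, 12.0)), epochs, prefilter=True)
        np.testing.assert_allclose(table.values, plain.values)

    def test_transform_of_heldout_trials_matches_training_path(self, small_epochs):
        epochs, _ = small_epochs
        table, models = filterbank_csp(epochs, m=1)
        again = apply_filterbank_csp(models, epochs)
        np.testing.assert_allclose(table.values, again.values)

    def test_discriminative_band_carries_the_signal(self):
        """ERD planted in the alpha band separates classes through band 8-12,
        not through band 28-32."""
        cfg = SyntheticConfig(
            n_trials_per_class=40, beta_amplitude=0.0, erd_depth=0.8, seed=9
        )
        epochs, _ = generate_mi_eeg(cfg)
        table, _ = filterbank_csp(epochs, m=1)

        def separation(cols):
            x = table.values[:, cols]
            mu0 = x[epochs.labels == 0].mean(axis=0)
            mu1 = x[epochs.labels == 1].mean(axis=0)
            sd = x.std(axis=0)
            return np.abs((mu0 - mu1) / sd).max()

        assert separation([0, 1]) > separation([10, 11])


def test_csp_recovers_planted_erd_channels():
    """Across seeds the strongest weight of an extreme filter sits on a
    channel whose rhythm was modulated."""
    hits = 0
    for seed in range(10):
        cfg = SyntheticConfig(n_trials_per_class=40, seed=seed)
        epochs, manifest = generate_mi_eeg(cfg)
        model = fit_csp(epochs, m=1, band=(8.0, 12.0))
        planted = set(manifest["informative_channels"])
        if int(np.argmax(np.abs(model.W[0]))) in planted:
            hits += 1
    assert hits >= 8
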