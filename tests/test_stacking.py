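"""Two-layer stacking: OOF probabilities, LDA supplement, contribution rates."""

import numpy as np
import pytest

from mistack import (
    DOMAIN_ORDER,
    Domain,
    contribution_rates,
    fit_stacking,
    generate_feature_tables,
    lda_features,
    predict_stacking,
)
from mistack.exceptions import ConfigurationError
from mistack.stacking import StackedModel, make_base_classifier

FAST_META = {"hidden_layer_sizes": (20,), "max_iter": 150}


def table_values(tables):
    return {d: t.values for d, t in tables.items()}


@pytest.fixture(scope="module")
def separable_fit():
    tables, labels, _ = generate_feature_tables(
        n=80, per_domain_effect={d: 3.0 for d in Domain}, seed=3, n_features=8
    )
    values = table_values(tables)
    model = fit_stacking(values, values, labels, meta_params=FAST_META, seed=0)
    return model, values, labels


class TestFitPredict:
    def test_meta_input_width_for_binary_four_domains(self, separable_fit):
        model, _, _ = separable_fit
        assert model.meta_input_width == 4 * 2 + 1

    def test_probability_rows_sum_to_one(self, separable_fit):
        model, values, _ = separable_fit
        _, proba = predict_stacking(model, values, values)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-8)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_separable_data_classified_perfectly(self, separable_fit):
        model, values, labels = separable_fit
        predictions, _ = predict_stacking(model, values, values)
        assert np.array_equal(predictions, labels)

    def test_predict_is_deterministic(self, separable_fit):
        model, values, _ = separable_fit
        a = predict_stacking(model, values, values)
        b = predict_stacking(model, values, values)
        np.testing.assert_array_equal(a[1], b[1])

    def test_missing_domain_rejected(self, separable_fit):
        _, values, labels = separable_fit
        partial = {d: v for d, v in values.items() if d != Domain.SPATIAL}
        with pytest.raises(ConfigurationError, match="sd"):
            fit_stacking(partial, partial, labels)

    def test_single_class_rejected(self, separable_fit):
        _, values, labels = separable_fit
        with pytest.raises(ConfigurationError):
            fit_stacking(values, values, np.zeros_like(labels))

    def test_width_mismatch_at_predict_rejected(self, separable_fit):
        model, values, _ = separable_fit
        bad = {d: v[:, :-1] for d, v in values.items()}
        with pytest.raises(Exception):
            predict_stacking(model, bad, bad)

    def test_base_kind_swap_keeps_architecture(self):
        tables, labels, _ = generate_feature_tables(
            n=60, per_domain_effect={d: 2.0 for d in Domain}, seed=5, n_features=6
        )
        values = table_values(tables)
        widths = set()
        for kind in ("random_forest", "svm_rbf", "svm_linear"):
            model = fit_stacking(
                values, values, labels, base_kind=kind, meta_params=FAST_META, seed=0
            )
            widths.add(model.meta_input_width)
            _, proba = predict_stacking(model, values, values)
            np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-8)
        assert widths == {9}

    def test_save_load_reproduces_predictions(self, separable_fit, tmp_path):
        model, values, _ = separable_fit
        model.save(tmp_path / "stacked")
        loaded = StackedModel.load(tmp_path / "stacked")
        _, p0 = predict_stacking(model, values, values)
        _, p1 = predict_stacking(loaded, values, values)
        np.testing.assert_array_equal(p0, p1)


class TestLdaFeatures:
    def test_direction_matches_closed_form(self, rng):
        """Two spherical Gaussians displaced along axis 0: the discriminant
        direction is Sigma^-1 (mu1 - mu0), i.e. axis 0."""
        n = 200
        X = rng.standard_normal((n, 5))
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        X[y == 1, 0] += 3.0
        lda, projected = lda_features(X, y)
        w = lda.coef_.ravel()
        cos = abs(w[0]) / np.linalg.norm(w)
        assert cos > 0.99
        assert projected.shape == (n, 1)

    def test_label_swap_keeps_discriminant_direction(self, rng):
        """Relabeling the classes leaves the discriminant axis unchanged up to
        sign (direction equivalence)."""
        X = rng.standard_normal((100, 4))
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        X[y == 1, 1] += 2.0
        _, pa = lda_features(X, y)
        _, pb = lda_features(X, 1 - y)
        corr = np.corrcoef(pa.ravel(), pb.ravel())[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-6)

    def test_wide_matrix_warns_and_still_projects(self, rng):
        X = rng.standard_normal((20, 40))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        with pytest.warns(UserWarning, match="shrinkage"):
            _, projected = lda_features(X, y)
        assert projected.shape == (20, 1)


class TestContributionRates:
    def test_rates_sum_to_hundred(self, separable_fit):
        model, _, _ = separable_fit
        rates, lda_share = contribution_rates(model)
        assert sum(rates.values()) == pytest.approx(100.0, abs=1e-6)
        assert lda_share is not None and 0 <= lda_share <= 100

    def test_uniform_weights_give_equal_rates(self, separable_fit):
        import copy

        model = copy.deepcopy(separable_fit[0])
        mlp = model.meta_model[-1]
        mlp.coefs_[0] = np.ones_like(mlp.coefs_[0])
        mlp.coefs_[1] = np.ones_like(mlp.coefs_[1])
        rates, _ = contribution_rates(model)
        for rate in rates.values():
            assert rate == pytest.approx(25.0, abs=1e-9)

    def test_signal_bearing_domain_dominates(self):
        """Signal planted only in the spatial domain: averaged over seeds its
        contribution rate is the maximum."""
        mean_rates = {d: [] for d in DOMAIN_ORDER}
        for seed in range(5):
            tables, labels, _ = generate_feature_tables(
                n=120, per_domain_effect={"sd": 2.5}, seed=seed, n_features=6
            )
            values = table_values(tables)
            model = fit_stacking(
                values, values, labels, meta_params=FAST_META, seed=seed, use_lda=False
            )
            rates, _ = contribution_rates(model)
            for d, r in rates.items():
                mean_rates[d].append(r)
        means = {d: np.mean(v) for d, v in mean_rates.items()}
        assert max(means, key=means.get) == Domain.SPATIAL

    def test_non_mlp_meta_rejected(self, separable_fit):
        import copy

        from sklearn.linear_model import LogisticRegression

        model = copy.deepcopy(separable_fit[0])
        model.meta_model = LogisticRegression()
        with pytest.raises(ConfigurationError):
            contribution_rates(model)
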