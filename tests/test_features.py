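"""Time, frequency and time-frequency feature extractors against oracles."""

import numpy as np
import pytest

from mistack import (
    BandDefinition,
    EpochedEEG,
    HiguchiConfig,
    frequency_domain_features,
    higuchi_fd,
    time_domain_features,
    timefrequency_features,
)
from mistack.features import dwt_energy_decomposition
from mistack.exceptions import ConfigurationError, DecompositionError


def higuchi_reference(x, l_max):
    """Literal curve-length evaluation used as an independent oracle."""
    x = np.asarray(x, float)
    T = len(x)
    mean_lengths = []
    for l in range(1, l_max + 1):
        per_offset = []
        for m in range(1, l + 1):  # 1-based initial times
            q = (T - m) // l
            if q < 1:
                continue
            total = sum(
                abs(x[m - 1 + i * l] - x[m - 1 + (i - 1) * l]) for i in range(1, q + 1)
            )
            per_offset.append(total * (T - 1) / (q * l) / l)
        mean_lengths.append(np.mean(per_offset))
    slope, _ = np.polyfit(-np.log(np.arange(1, l_max + 1)), np.log(mean_lengths), 1)
    return slope


class TestHiguchi:
    def test_linear_ramp_has_dimension_one(self):
        assert higuchi_fd(np.linspace(0, 5, 2000)) == pytest.approx(1.0, abs=0.05)

    def test_gaussian_noise_has_dimension_two(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        assert higuchi_fd(x) == pytest.approx(2.0, abs=0.1)

    def test_matches_literal_curve_length_oracle(self):
        rng = np.random.default_rng(5)
        for x in [np.sin(np.linspace(0, 8 * np.pi, 600)), rng.standard_normal(400)]:
            assert higuchi_fd(x, l_max=8) == pytest.approx(
                higuchi_reference(x, l_max=8), abs=1e-12
            )

    def test_dense_sinusoid_between_line_and_noise(self):
        t = np.arange(5000) / 1000.0
        fd = higuchi_fd(np.sin(2 * np.pi * 5 * t))
        assert 1.0 <= fd <= 1.5

    def test_constant_signal_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="constant"):
            assert higuchi_fd(np.full(100, 3.0)) == 1.0

    def test_l_max_too_large_rejected(self):
        with pytest.raises(ConfigurationError):
            higuchi_fd(np.arange(10.0), l_max=6)


class TestTimeDomain:
    def test_moment_arithmetic(self):
        data = np.array([[[1.0, 2.0, 3.0, 4.0]]])
        epochs = EpochedEEG(data, [0], fs=4.0)
        table = time_domain_features(epochs, HiguchiConfig(l_max=2))
        row = dict(zip(table.feature_names, table.values[0]))
        assert row["ch00:mean"] == pytest.approx(2.5)
        assert row["ch00:var"] == pytest.approx(1.25)  # population variance
        assert row["ch00:rms"] == pytest.approx(np.sqrt(7.5))

    def test_feature_count_is_four_per_channel(self, small_epochs):
        epochs, _ = small_epochs
        table = time_domain_features(epochs)
        assert table.n_features == 4 * epochs.n_channels

    def test_channel_permutation_permutes_feature_blocks(self, small_epochs):
        epochs, _ = small_epochs
        perm = [3, 1, 0, 2, 7, 6, 5, 4]
        permuted = EpochedEEG(
            epochs.data[:, perm], epochs.labels, epochs.fs,
            [epochs.channel_names[i] for i in perm],
        )
        base = time_domain_features(epochs)
        shuffled = time_domain_features(permuted)
        blocks = base.values.reshape(epochs.n_trials, epochs.n_channels, 4)
        np.testing.assert_allclose(
            shuffled.values.reshape(epochs.n_trials, epochs.n_channels, 4),
            blocks[:, perm],
        )


class TestFrequencyDomain:
    def test_alpha_tone_concentrates_alpha_energy(self):
        t = np.arange(300) / 100.0
        data = np.sin(2 * np.pi * 10 * t)[None, None, :]
        table = frequency_domain_features(EpochedEEG(data, [0], 100.0))
        row = dict(zip(table.feature_names, table.values[0]))
        assert row["ch00:energy_alpha"] > 100 * row["ch00:energy_beta"]
        assert row["ch00:psd_alpha"] == pytest.approx(row["ch00:energy_alpha"] / 300)

    def test_zero_signal_gives_zero_features(self):
        table = frequency_domain_features(EpochedEEG(np.zeros((1, 2, 300)), [0], 100.0))
        np.testing.assert_array_equal(table.values, 0.0)

    def test_parseval_identity_for_dft_convention(self, rng):
        """Unnormalized DFT: sum_k |X(k)|^2 == T * sum_t x(t)^2."""
        for _ in range(5):
            x = rng.standard_normal(256)
            lhs = (np.abs(np.fft.fft(x)) ** 2).sum()
            assert lhs == pytest.approx(x.size * (x**2).sum(), rel=1e-10)

    def test_band_energy_matches_manual_bin_sum(self, rng):
        x = rng.standard_normal((1, 1, 300))
        bands = BandDefinition(alpha=(8.0, 13.0), beta=(13.0, 30.0))
        table = frequency_domain_features(EpochedEEG(x, [0], 100.0), bands)
        spectrum = np.fft.rfft(x[0, 0])
        freqs = np.fft.rfftfreq(300, 0.01)
        manual = (np.abs(spectrum[(freqs >= 8) & (freqs < 13)]) ** 2).sum()
        row = dict(zip(table.feature_names, table.values[0]))
        assert row["ch00:energy_alpha"] == pytest.approx(manual, rel=1e-12)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            frequency_domain_features(
                EpochedEEG(np.zeros((1, 1, 300)), [0], 100.0),
                BandDefinition(beta=(13.0, 60.0)),
            )


class TestTimeFrequency:
    def test_zero_signal_gives_zero_energies(self):
        table = timefrequency_features(EpochedEEG(np.zeros((2, 2, 256)), [0, 1], 100.0))
        np.testing.assert_array_equal(table.values, 0.0)

    def test_orthogonal_energy_conservation(self, rng):
        """Periodic db4: approximation + detail energies equal signal energy."""
        for _ in range(5):
            x = rng.standard_normal(320)
            energies = dwt_energy_decomposition(x)
            assert sum(energies.values()) == pytest.approx((x**2).sum(), rel=1e-10)

    def test_dyadic_band_placement_of_tones(self):
        """At fs=100 the nominal bands put 10 Hz in D3 and 5 Hz in D4."""
        t = np.arange(400) / 100.0
        e10 = dwt_energy_decomposition(np.sin(2 * np.pi * 10 * t))
        e5 = dwt_energy_decomposition(np.sin(2 * np.pi * 5 * t))
        assert e10["D3"] > e10["D4"]
        assert e5["D4"] > e5["D3"]

    def test_feature_count_and_level_map(self, small_epochs):
        epochs, _ = small_epochs
        table = timefrequency_features(epochs)
        assert table.n_features == 2 * epochs.n_channels
        swapped = timefrequency_features(epochs, level_map={"alpha": 3, "beta": 4})
        base = table.values.reshape(epochs.n_trials, epochs.n_channels, 2)
        np.testing.assert_allclose(
            swapped.values.reshape(epochs.n_trials, epochs.n_channels, 2),
            base[:, :, ::-1],
        )

    def test_resampling_keeps_level_meaning(self):
        """A 10 Hz tone lands in the same level whether sampled at 100 or 200 Hz."""
        for fs in (100.0, 200.0):
            t = np.arange(int(3 * fs)) / fs
            data = np.sin(2 * np.pi * 10 * t)[None, None, :]
            table = timefrequency_features(EpochedEEG(data, [0], fs))
            row = dict(zip(table.feature_names, table.values[0]))
            # 10 Hz sits in nominal D3 (mapped to beta by default)
            assert row["ch00:dwt_energy_beta"] > row["ch00:dwt_energy_alpha"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(DecompositionError):
            timefrequency_features(EpochedEEG(np.zeros((1, 1, 16)), [0], 100.0))


def test_extractors_are_deterministic(small_epochs):
    epochs, _ = small_epochs
    for extractor in (time_domain_features, frequency_domain_features, timefrequency_features):
        np.testing.assert_array_equal(
            extractor(epochs).values, extractor(epochs).values
        )
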