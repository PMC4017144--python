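import math

import numpy as np
import pytest

from vbcca.synthetic import (
    add_noise_snr,
    downsample,
    generate_random_network,
    rescale_rms,
    two_node_dataset,
)


class TestRandomNetwork:
    def test_edge_count_is_half_n_rounded_up(self):
        for n in (5, 10, 11):
            ds = generate_random_network(n, P=2, T=50, rng=0)
            assert len(ds.truth_directed) == math.ceil(n / 2)

    def test_unidirectional_and_off_diagonal(self):
        ds = generate_random_network(10, P=2, T=50, rng=1)
        for src, tgt in ds.truth_directed:
            assert src != tgt
            assert (tgt, src) not in ds.truth_directed

    def test_coefficient_support_matches_edges(self):
        ds = generate_random_network(10, P=2, T=50, rng=2)
        coeffs = ds.truth_params.coeffs
        for src, tgt in ds.truth_directed:
            assert np.all(coeffs[:, tgt, src] != 0)
        mask = np.zeros((10, 10), dtype=bool)
        for src, tgt in ds.truth_directed:
            mask[tgt, src] = True
        np.fill_diagonal(mask, True)
        assert np.all(coeffs[:, ~mask] == 0)

    def test_coefficient_variance(self):
        draws = []
        rng = np.random.default_rng(3)
        while len(draws) < 10_000:
            ds = generate_random_network(40, P=2, T=2, rng=rng)
            c = ds.truth_params.coeffs
            draws.extend(c[c != 0].tolist())
        var = np.var(draws[:10_000])
        assert var == pytest.approx(0.05, rel=0.05)

    def test_observed_is_hrf_convolved_neuronal(self):
        ds = generate_random_network(4, P=1, T=100, rng=4)
        kernel = ds.hrfs[0]
        expected = np.convolve(ds.neuronal[2], kernel.samples)[:100]
        np.testing.assert_allclose(ds.observed[2], expected)

    def test_rejects_tiny_networks(self):
        with pytest.raises(ValueError):
            generate_random_network(1, P=1, T=10, rng=0)


class TestRescaleRMS:
    def test_all_ones_input(self):
        scaled, factor = rescale_rms(np.ones((3, 10)), target=6.0)
        np.testing.assert_allclose(scaled, math.sqrt(6.0))
        assert factor == pytest.approx(math.sqrt(6.0))

    def test_idempotent_at_target(self, rng):
        Y = rng.normal(size=(2, 40))
        scaled, _ = rescale_rms(Y, target=6.0)
        again, factor = rescale_rms(scaled, target=6.0)
        assert factor == pytest.approx(1.0)
        np.testing.assert_allclose(again, scaled)

    def test_default_target_is_six(self, rng):
        Y = rng.normal(size=(4, 100))
        scaled, _ = rescale_rms(Y)
        assert np.mean(scaled**2) == pytest.approx(6.0)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            rescale_rms(np.zeros((2, 5)))


class TestAddNoise:
    def test_zero_db_noise_equals_signal_power(self, rng):
        Y = rng.normal(size=(3, 200))
        _, sigma2 = add_noise_snr(Y, 0.0, rng)
        power = np.mean((Y - Y.mean(axis=1, keepdims=True)) ** 2)
        assert sigma2 == pytest.approx(power)

    def test_decade_scaling(self, rng):
        Y = rng.normal(size=(3, 200))
        _, s0 = add_noise_snr(Y, 0.0, 1)
        _, s10 = add_noise_snr(Y, 10.0, 1)
        assert s10 == pytest.approx(s0 / 10.0)

    def test_empirical_snr_matches_request(self, rng):
        """Monte-Carlo inversion: measured noise power over 20 seeds should
        reproduce the requested SNR within 0.1 dB."""
        Y = rng.normal(size=(4, 2000))
        power = np.mean((Y - Y.mean(axis=1, keepdims=True)) ** 2)
        request = 7.0
        measured = []
        for seed in range(20):
            noisy, sigma2 = add_noise_snr(Y, request, seed)
            measured.append(10 * np.log10(power / np.mean((noisy - Y) ** 2)))
        assert np.mean(measured) == pytest.approx(request, abs=0.1)

    def test_noise_variance_decreases_with_snr(self, rng):
        Y = rng.normal(size=(2, 500))
        sigmas = [add_noise_snr(Y, s, 0)[1] for s in (-5.0, 0.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(sigmas, sigmas[1:]))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            add_noise_snr(np.ones((2, 50)), 0.0, 0)


class TestDownsample:
    def test_identity_factor(self, rng):
        Y = rng.normal(size=(2, 30))
        np.testing.assert_array_equal(downsample(Y, 1), Y)

    def test_expected_length(self):
        Y = np.zeros((2, 240_000))
        assert downsample(Y, 50).shape == (2, 4800)

    def test_ramp_decimation(self):
        ramp = np.arange(10.0)
        np.testing.assert_array_equal(downsample(ramp, 3), [0.0, 3.0, 6.0])

    def test_factor_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.zeros((1, 5)), 6)


class TestTwoNode:
    def test_neuronal_length_at_one_kilohertz(self):
        ds = two_node_dataset(10, 0.05, rng=0, duration_s=240.0)
        assert ds.neuronal.shape == (2, 240_000)

    def test_coupling_magnitudes_in_range(self):
        rng = np.random.default_rng(5)
        couplings = [
            two_node_dataset(10, 0.05, rng=rng, duration_s=1.0).meta["coupling"]
            for _ in range(200)
        ]
        assert min(couplings) >= 0.4 and max(couplings) <= 0.9

    def test_cross_coefficient_at_delay_lag(self):
        ds = two_node_dataset(10, 0.05, rng=6, duration_s=1.0)
        ((src, tgt),) = ds.truth_directed
        coeffs = ds.truth_params.coeffs
        assert coeffs.shape[0] == 10
        assert coeffs[9, tgt, src] == pytest.approx(ds.meta["coupling"])
        assert coeffs[0, 0, 0] == coeffs[0, 1, 1] == 0.95

    def test_target_follows_delayed_source(self):
        """The target series regressed on its own past and the delayed
        source recovers the generating coefficients."""
        ds = two_node_dataset(5, 0.001, rng=7, duration_s=30.0)
        ((src, tgt),) = ds.truth_directed
        s = ds.neuronal
        d = 5
        y = s[tgt, d:]
        X = np.column_stack([s[tgt, d - 1 : -1], s[src, : -d]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert beta[0] == pytest.approx(0.95, abs=0.02)
        assert beta[1] == pytest.approx(ds.meta["coupling"], abs=0.02)

    def test_pipeline_determinism(self):
        a = two_node_dataset(20, 0.1, rng=8, duration_s=2.0)
        b = two_node_dataset(20, 0.1, rng=8, duration_s=2.0)
        np.testing.assert_array_equal(a.observed, b.observed)
        assert a.truth_directed == b.truth_directed

    def test_true_hrf_mode_returns_generating_kernels(self):
        ds = two_node_dataset(10, 0.5, hrf_mode="return_true_hrf", rng=9, duration_s=2.0)
        assert ds.hrfs[0].dt == pytest.approx(0.5)
        # randomized peaks should generally differ across regions
        assert ds.hrfs[0].peak_time != ds.hrfs[1].peak_time

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            two_node_dataset(0.5, 0.05, rng=0)
        with pytest.raises(ValueError):
            two_node_dataset(10, 0.0503, rng=0)
        with pytest.raises(ValueError):
            two_node_dataset(10, 0.05, hrf_mode="nope", rng=0)
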