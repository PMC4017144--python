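"""Each VB factor update against an independent dense oracle."""

import numpy as np
import pytest
from scipy.linalg import circulant

from vbcca.hrf import HRFKernel
from vbcca.smoother import SmootherState, kalman_smoother
from vbcca.var import companion_transition
from vbcca.vb import (
    CirculantDeconvolver,
    GAMMA_CAP,
    connectivity_matrix,
    update_ard,
    update_innovation_precision,
    update_var_coefficients,
)


def make_kernel(h, dt=1.0):
    return HRFKernel(samples=np.asarray(h, float), dt=dt, peak_time=0.0, undershoot_time=0.0)


def dense_proxy(y, h, beta, theta, x, M):
    """Oracle: explicit circulant-matrix solve of the proxy posterior on the
    zero-padded embedding."""
    hpad = np.zeros(M)
    hpad[: len(h)] = h
    H = circulant(hpad)
    ypad = np.zeros(M)
    ypad[: len(y)] = y
    xpad = np.zeros(M)
    xpad[: len(x)] = x
    Sz = np.linalg.inv(beta * H.T @ H + theta * np.eye(M))
    return Sz @ (beta * H.T @ ypad + theta * xpad), Sz, H, ypad


class TestProxyUpdate:
    def test_matches_dense_circulant_solve(self, rng):
        T, L = 64, 8
        y = rng.normal(size=(1, T))
        h = rng.normal(size=L)
        kern = make_kernel(h)
        theta, beta = 3.7, 1.9
        x = rng.normal(size=(1, T))
        deconv = CirculantDeconvolver(y, [kern], theta)
        z = deconv.update_proxy(np.array([beta]), x)
        expected, *_ = dense_proxy(y[0], h, beta, theta, x[0], deconv.M)
        np.testing.assert_allclose(z[0], expected[:T], atol=1e-8)

    def test_identity_kernel_large_beta_returns_data(self, rng):
        T = 32
        y = rng.normal(size=(1, T))
        deconv = CirculantDeconvolver(y, [make_kernel([1.0])], theta=1.0)
        z = deconv.update_proxy(np.array([1e12]), np.zeros((1, T)))
        np.testing.assert_allclose(z[0], y[0], atol=1e-8)

    def test_large_theta_returns_prior_mean(self, rng):
        T = 32
        y = rng.normal(size=(1, T))
        x = rng.normal(size=(1, T))
        deconv = CirculantDeconvolver(y, [make_kernel([0.3, 0.5])], theta=1e12)
        z = deconv.update_proxy(np.array([1.0]), x)
        np.testing.assert_allclose(z[0], x[0], atol=1e-8)

    def test_covariance_first_row_positive_spectrum(self, rng):
        y = rng.normal(size=(1, 16))
        deconv = CirculantDeconvolver(y, [make_kernel([1.0, 0.4])], theta=2.0)
        deconv.update_proxy(np.array([1.5]), np.zeros((1, 16)))
        row = deconv.covariance_first_row(0)
        spectrum = np.real(np.fft.fft(row))
        assert np.all(spectrum > 0)


class TestNoisePrecisionUpdate:
    def test_matches_dense_evaluation(self, rng):
        """Oracle: the gamma inverse scale evaluated with explicit circulant
        H and Sigma^z matrices on the padded embedding."""
        T, L = 16, 4
        y = rng.normal(size=(1, T))
        h = rng.normal(size=L)
        theta, beta, b0 = 2.1, 0.8, 0.5
        x = rng.normal(size=(1, T))
        deconv = CirculantDeconvolver(y, [make_kernel(h)], theta)
        deconv.update_proxy(np.array([beta]), x)
        b = deconv.noise_inverse_scale(a0_beta=1.0, b0_beta=b0)
        zmean, Sz, H, ypad = dense_proxy(y[0], h, beta, theta, x[0], deconv.M)
        expected = 0.5 * (
            ypad @ ypad
            - 2 * ypad @ H @ zmean
            + zmean @ H.T @ H @ zmean
            + np.trace(H.T @ H @ Sz)
        ) + b0
        assert b[0] == pytest.approx(expected, rel=1e-8)

    def test_zero_residual_gives_prior_scale(self):
        """Perfect fit through an identity kernel with no posterior
        uncertainty leaves only the prior term."""
        T = 8
        y = np.ones((1, T))
        theta = 1e12  # kills posterior variance and pins z to x
        deconv = CirculantDeconvolver(y, [make_kernel([1.0])], theta)
        ypad = np.zeros((1, deconv.M))
        ypad[:, :T] = y
        deconv.update_proxy(np.array([1.0]), ypad[:, : deconv.T] * 0 + y)
        b = deconv.noise_inverse_scale(a0_beta=1.0, b0_beta=2.5)
        assert b[0] == pytest.approx(2.5, abs=1e-6)


def synthetic_smoother_state(rng, n, order, T):
    """A structurally valid SmootherState with randomized moments."""
    d = n * order
    means = rng.normal(size=(T + 1, d))
    covs = []
    for _ in range(T + 1):
        m = rng.normal(size=(d, d))
        covs.append(m @ m.T / d + 0.1 * np.eye(d))
    crosses = [rng.normal(scale=0.1, size=(d, d)) for _ in range(T)]
    return SmootherState(
        means=means,
        sum_cov_prev=sum(covs[:T]),
        sum_cross_topn=sum(c[:n, :] for c in crosses),
        sum_cov_topnn=sum(c[:n, :n] for c in covs[1:]),
        n_obs=n,
        covs=covs,
        cross_covs=crosses,
    )


class TestCoefficientUpdate:
    def test_cg_matches_dense_kron_solve(self, rng):
        """Oracle: assemble the full N^2 P x N^2 P precision with explicit
        Kronecker products and solve densely."""
        n, order, T = 3, 2, 30
        state = synthetic_smoother_state(rng, n, order, T)
        lam = np.diag(rng.uniform(0.5, 2.0, size=n))
        gamma = rng.uniform(0.1, 5.0, size=(n, n))
        abar, avar = update_var_coefficients(state, lam, gamma, order)
        U = state.means[:-1]
        P1 = U.T @ U + state.sum_cov_prev
        rhs = (lam @ (state.means[1:, :n].T @ U + state.sum_cross_topn)).ravel(order="F")
        precision = np.kron(P1, lam) + np.diag(np.tile(gamma.ravel(order="F"), order))
        expected = np.linalg.solve(precision, rhs).reshape((n, n * order), order="F")
        np.testing.assert_allclose(abar, expected, atol=1e-6)
        np.testing.assert_allclose(avar, 1.0 / np.diag(precision).reshape((n, n * order), order="F"), atol=1e-10)

    def test_scalar_closed_form(self, rng):
        """N=1, P=1: <a> = lam * m / (lam * P1 + gamma)."""
        state = synthetic_smoother_state(rng, 1, 1, 12)
        lam = np.array([[1.7]])
        gamma = np.array([[0.9]])
        abar, _ = update_var_coefficients(state, lam, gamma, 1)
        U = state.means[:-1, 0]
        p1 = U @ U + state.sum_cov_prev[0, 0]
        m = state.means[1:, 0] @ U + state.sum_cross_topn[0, 0]
        assert abar[0, 0] == pytest.approx(1.7 * m / (1.7 * p1 + 0.9), rel=1e-8)

    def test_huge_prior_precision_kills_coefficients(self, rng):
        state = synthetic_smoother_state(rng, 2, 2, 20)
        abar, _ = update_var_coefficients(
            state, np.eye(2), np.full((2, 2), 1e12), 2
        )
        assert np.linalg.norm(abar) < 1e-6


class TestInnovationPrecisionUpdate:
    def test_degrees_of_freedom(self, rng):
        state = synthetic_smoother_state(rng, 2, 1, 500)
        nu, w, lam = update_innovation_precision(state, np.zeros((2, 2)), 1.0, np.eye(2))
        assert nu == 501

    def test_zero_residual_returns_prior_scale(self):
        T, n = 10, 2
        means = np.zeros((T + 1, n))
        state = SmootherState(
            means=means,
            sum_cov_prev=np.zeros((n, n)),
            sum_cross_topn=np.zeros((n, n)),
            sum_cov_topnn=np.zeros((n, n)),
            n_obs=n,
        )
        w0 = np.diag([0.2, 0.5])
        nu, w, lam = update_innovation_precision(state, np.zeros((n, n)), 1.0, w0)
        np.testing.assert_allclose(w, w0, atol=1e-12)

    def test_matches_term_by_term_sum(self, rng):
        """Oracle: brute-force evaluation of the expected residual outer
        product, term by term over t, from the stored per-time moments."""
        n, order, T = 2, 2, 10
        state = synthetic_smoother_state(rng, n, order, T)
        abar = rng.normal(scale=0.3, size=(n, n * order))
        nu, w, lam = update_innovation_precision(state, abar, 1.0, np.eye(n))
        p2 = np.zeros((n, n))
        for t in range(1, T + 1):
            mu_s = state.means[t, :n]
            mu_prev = state.means[t - 1]
            resid = mu_s - abar @ mu_prev
            cross = state.cross_covs[t - 1][:n, :]
            p2 += (
                np.outer(resid, resid)
                - cross @ abar.T
                - abar @ cross.T
                + state.covs[t][:n, :n]
                + abar @ state.covs[t - 1] @ abar.T
            )
        expected_winv = p2 + np.eye(n)
        np.testing.assert_allclose(np.linalg.inv(w), expected_winv, atol=1e-8)
        np.testing.assert_allclose(lam, (T + 1.0) * w, atol=1e-10)


class TestARDUpdate:
    def test_mean_is_shape_over_inverse_scale(self):
        abar = np.full((3, 6), 0.1)
        gamma, b = update_ard(abar, abar * 0 + 0.01, 2)
        # shape P/2 = 1 for two lags
        np.testing.assert_allclose(gamma, 1.0 / b)

    def test_hand_example(self):
        abar = np.array([[0.3, 0.1]])  # N=1, P=2 lags
        avar = np.array([[0.01, 0.01]])
        gamma, b = update_ard(abar, avar, 2)
        assert b[0, 0] == pytest.approx(0.06)
        assert gamma[0, 0] == pytest.approx(1.0 / 0.06)

    def test_dead_coefficient_hits_cap(self):
        gamma, _ = update_ard(np.zeros((2, 2)), np.zeros((2, 2)), 1)
        assert np.all(gamma == GAMMA_CAP)


class TestConnectivityMatrix:
    def test_absolute_value_single_lag(self):
        coef = np.zeros((1, 2, 2))
        coef[0, 1, 0] = -0.4
        assert connectivity_matrix(coef)[1, 0] == pytest.approx(0.4)

    def test_zero_coefficients(self):
        np.testing.assert_array_equal(connectivity_matrix(np.zeros((2, 3, 3))), np.zeros((3, 3)))

    def test_sums_absolute_values_across_lags(self):
        coef = np.zeros((2, 2, 2))
        coef[0, 0, 1] = 0.2
        coef[1, 0, 1] = -0.1
        assert connectivity_matrix(coef)[0, 1] == pytest.approx(0.3)
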