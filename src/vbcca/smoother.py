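"""Variational Kalman (Rauch-Tung-Striebel) smoother on the embedding state.

Inside the VB scheme the latent embedding process x(t) (dimension PN) is a
linear-Gaussian chain with transition <A_tilde>, process covariance <Q>
(nonzero only in its top-left N x N block), observation operator
B = [I_N 0] and observation covariance theta^{-1} I_N; the posterior means
of the proxy series z(t) play the role of observations.  The smoother
returns per-time smoothed moments mu_t, Sigma_t and cross-time covariances
Sigma_{t,t-1}, seeded from the prior mu_0 = 0, Sigma_0 = I.

For long series the filter covariance recursion (a Riccati iteration for a
time-invariant system) converges geometrically; once the change between
consecutive covariances drops below ``freeze_tol`` the covariance-dependent
quantities are held fixed and only the cheap mean recursions continue.  The
backward covariance recursions reach their own steady state the same way,
so the per-time covariance sums needed by the VB updates are accumulated in
closed form over the frozen stretch.  Set ``freeze_tol=0`` to disable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FilterResult", "SmootherState", "kalman_forward", "kalman_backward", "kalman_smoother"]


def _is_companion(a_tilde: np.ndarray, n: int) -> bool:
    """True when the rows below the first N form the [I 0] shift blocks."""
    d = a_tilde.shape[0]
    if d == n:
        return True
    lower = a_tilde[n:]
    expect = np.zeros((d - n, d))
    expect[:, : d - n] = np.eye(d - n)
    return np.array_equal(lower, expect)


def _left_apply(a_tilde, a_top, M, n, structured):
    """A @ M, exploiting the shift structure when present."""
    if not structured:
        return a_tilde @ M
    d = a_tilde.shape[0]
    out = np.empty((d,) + M.shape[1:]) if M.ndim > 1 else np.empty(d)
    out[:n] = a_top @ M
    if d > n:
        out[n:] = M[: d - n]
    return out


def _right_apply_t(a_tilde, a_top, M, n, structured):
    """M @ A^T, exploiting the shift structure when present."""
    if not structured:
        return M @ a_tilde.T
    d = a_tilde.shape[0]
    out = np.empty((M.shape[0], d))
    out[:, :n] = M @ a_top.T
    if d > n:
        out[:, n:] = M[:, : d - n]
    return out


@dataclass
class FilterResult:
    """Filtered moments from the forward pass.

    Covariances are stored explicitly up to the freeze index; beyond it the
    steady-state matrices apply.  ``filtered_cov(t)`` / ``predicted_cov(t)``
    hide the bookkeeping.
    """

    means: np.ndarray  # (T+1, D) filtered means, index 0 = prior
    covs: list  # filtered covariances for t = 0..freeze index
    pred_covs: list  # predicted covariances for t = 1..freeze index (covs[t-1] entry)
    gains: list  # Kalman gains for t = 1..freeze index
    freeze_at: int  # first t for which the frozen matrices apply (T+1 if never)
    frozen_cov: np.ndarray | None = None
    frozen_pred: np.ndarray | None = None
    frozen_gain: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.means.shape[0] - 1

    def filtered_cov(self, t: int) -> np.ndarray:
        if t < self.freeze_at:
            return self.covs[t]
        return self.frozen_cov

    def predicted_cov(self, t: int) -> np.ndarray:
        if t < self.freeze_at:
            return self.pred_covs[t - 1]
        return self.frozen_pred

    def gain(self, t: int) -> np.ndarray:
        if t < self.freeze_at:
            return self.gains[t - 1]
        return self.frozen_gain


@dataclass
class SmootherState:
    """Smoothed moments and the covariance sums consumed by the VB updates.

    ``means[t]`` is the smoothed mean of x(t) for t = 0..T.  The sums are
      sum_cov_prev      = sum_{t=1..T} Sigma_{t-1}
      sum_cross_topn    = sum_{t=1..T} (Sigma_{t,t-1})[:N, :]
      sum_cov_topnn     = sum_{t=1..T} (Sigma_t)[:N, :N]
    Per-time covariances are kept only when ``store_covariances`` was set.
    """

    means: np.ndarray
    sum_cov_prev: np.ndarray
    sum_cross_topn: np.ndarray
    sum_cov_topnn: np.ndarray
    n_obs: int
    covs: list | None = None  # Sigma_t for t = 0..T
    cross_covs: list | None = None  # Sigma_{t,t-1} for t = 1..T (index t-1)
    diagnostics: dict = field(default_factory=dict)


def kalman_forward(
    a_tilde: np.ndarray,
    q: np.ndarray,
    z_means: np.ndarray,
    theta: float,
    n_obs: int | None = None,
    freeze_tol: float = 1e-9,
) -> FilterResult:
    """Forward (filtering) pass.

    Parameters
    ----------
    a_tilde : (D, D) mean transition matrix (companion form).
    q : (D, D) mean process covariance, nonzero only in the top-left block.
    z_means : (T, N) proxy posterior means, acting as observations.
    theta : float
        Proxy precision; the observation covariance is theta^{-1} I_N.
    n_obs : observation dimension N (defaults to ``z_means.shape[1]``).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    z_means = np.atleast_2d(np.asarray(z_means, dtype=float))
    T, n = z_means.shape
    if n_obs is not None and n_obs != n:
        raise ValueError("n_obs inconsistent with z_means")
    d = a_tilde.shape[0]
    if a_tilde.shape != (d, d) or q.shape != (d, d):
        raise ValueError("a_tilde and q must be square and matching")
    if d % n:
        raise ValueError("state dimension must be a multiple of n_obs")

    r = 1.0 / theta
    means = np.zeros((T + 1, d))
    cov = np.eye(d)  # Sigma_0^0
    covs = [cov]
    pred_covs: list = []
    gains: list = []
    freeze_at = T + 1
    frozen = False
    frozen_cov = frozen_pred = frozen_gain = None
    a_top = a_tilde[:n, :]  # top block; shift structure exploited when present
    structured = _is_companion(a_tilde, n)

    mu = means[0]
    for t in range(1, T + 1):
        if not frozen:
            prev = cov
            m = _left_apply(a_tilde, a_top, prev, n, structured)
            pred = _right_apply_t(a_tilde, a_top, m, n, structured) + q
            pred = 0.5 * (pred + pred.T)
            s = pred[:n, :n] + r * np.eye(n)
            gain = np.linalg.solve(s, pred[:n, :]).T  # (D, N)
            cov = pred - gain @ pred[:n, :]
            cov = 0.5 * (cov + cov.T)
            if freeze_tol > 0 and np.max(np.abs(cov - prev)) < freeze_tol:
                frozen = True
                freeze_at = t
                frozen_cov, frozen_pred, frozen_gain = cov, pred, gain
            else:
                covs.append(cov)
                pred_covs.append(pred)
                gains.append(gain)
        # mean recursion (always per step)
        mu_pred = _left_apply(a_tilde, a_top, mu, n, structured)
        mu = mu_pred + gain @ (z_means[t - 1] - mu_pred[:n])
        means[t] = mu

    if not np.all(np.isfinite(means[T])):
        raise FloatingPointError("non-finite state encountered in forward pass")
    return FilterResult(
        means=means,
        covs=covs,
        pred_covs=pred_covs,
        gains=gains,
        freeze_at=freeze_at,
        frozen_cov=frozen_cov,
        frozen_pred=frozen_pred,
        frozen_gain=frozen_gain,
    )


def _smoother_gain(filt_cov, a_tilde, a_top, pred_next, n, structured):
    """J_t = Sigma_t^t A^T (Sigma_{t+1}^t)^{-1}, regularizing a singular predicted covariance."""
    d = filt_cov.shape[0]
    sa = _right_apply_t(a_tilde, a_top, filt_cov, n, structured)
    try:
        return np.linalg.solve(pred_next.T, sa.T).T
    except np.linalg.LinAlgError:
        reg = pred_next + 1e-10 * np.trace(pred_next) / d * np.eye(d)
        return np.linalg.solve(reg.T, sa.T).T


def kalman_backward(
    filt: FilterResult,
    a_tilde: np.ndarray,
    n_obs: int,
    freeze_tol: float = 1e-9,
    store_covariances: bool = False,
) -> SmootherState:
    """Backward (smoothing) pass with cross-time covariances.

    Runs down to t = 0 so the smoothed prior state is available to the VB
    coefficient and innovation updates.
    """
    T = filt.T
    d = a_tilde.shape[0]
    n = n_obs
    a_top = a_tilde[:n, :]
    structured = _is_companion(a_tilde, n)

    means = np.array(filt.means)  # smoothed means, seeded with filtered
    cov_next = filt.filtered_cov(T)  # Sigma_T
    sum_cov_prev = np.zeros((d, d))
    sum_cross_topn = np.zeros((n, d))
    sum_cov_topnn = np.array(cov_next[:n, :n])  # t = T term
    covs = [None] * (T + 1) if store_covariances else None
    cross_covs = [None] * T if store_covariances else None
    if store_covariances:
        covs[T] = cov_next

    # Sigma_{T,T-1} = (I - K_T B) A Sigma_{T-1}^{T-1}
    k_T = filt.gain(T)
    prev_f = filt.filtered_cov(T - 1)
    m = _left_apply(a_tilde, a_top, prev_f, n, structured)
    cross_next = m - k_T @ m[:n, :]  # Sigma_{t+1,t} with t = T-1
    j_next = None  # J_{t+1}
    frozen_bwd = False
    n_frozen_steps = 0

    t = T - 1
    while t >= 0:
        filt_cov = filt.filtered_cov(t)
        pred_next = filt.predicted_cov(t + 1)
        j_t = _smoother_gain(filt_cov, a_tilde, a_top, pred_next, n, structured)

        # smoothed covariance and cross-covariance at this step
        cov_t = filt_cov + j_t @ (cov_next - pred_next) @ j_t.T
        cov_t = 0.5 * (cov_t + cov_t.T)
        if t == T - 1:
            cross_t = cross_next  # seeded above
        else:
            af = _left_apply(a_tilde, a_top, filt.filtered_cov(t + 1), n, structured)
            cross_t = filt.filtered_cov(t + 1) @ j_t.T + j_next @ (cross_next - af) @ j_t.T

        # mean recursion
        mu_f = filt.means[t]
        mu_pred = _left_apply(a_tilde, a_top, mu_f, n, structured)
        means[t] = mu_f + j_t @ (means[t + 1] - mu_pred)

        sum_cov_prev += cov_t
        sum_cross_topn += cross_t[:n, :]
        if t >= 1:
            sum_cov_topnn += cov_t[:n, :n]
        if store_covariances:
            covs[t] = cov_t
            cross_covs[t] = cross_t  # Sigma_{t+1,t}

        # steady-state shortcut: once everything is constant, bulk-accumulate
        can_freeze = (
            freeze_tol > 0
            and not store_covariances
            and not frozen_bwd
            and t - 1 >= filt.freeze_at
            and t + 1 >= filt.freeze_at
            and np.max(np.abs(cov_t - cov_next)) < freeze_tol
            and np.max(np.abs(cross_t - cross_next)) < freeze_tol
        )
        cov_next = cov_t
        cross_next = cross_t
        j_next = j_t
        if can_freeze:
            frozen_bwd = True
            # steps t-1 down to filt.freeze_at repeat the same covariances
            lo = filt.freeze_at
            n_frozen_steps = t - lo
            if n_frozen_steps > 0:
                sum_cov_prev += n_frozen_steps * cov_t
                sum_cross_topn += n_frozen_steps * cross_t[:n, :]
                sum_cov_topnn += n_frozen_steps * cov_t[:n, :n]
                # mean-only recursion through the frozen stretch
                for tt in range(t - 1, lo - 1, -1):
                    mu_f = filt.means[tt]
                    mu_pred = _left_apply(a_tilde, a_top, mu_f, n, structured)
                    means[tt] = mu_f + j_t @ (means[tt + 1] - mu_pred)
                t = lo
        t -= 1

    return SmootherState(
        means=means,
        sum_cov_prev=sum_cov_prev,
        sum_cross_topn=sum_cross_topn,
        sum_cov_topnn=sum_cov_topnn,
        n_obs=n,
        covs=covs,
        cross_covs=cross_covs,
        diagnostics={
            "forward_freeze_at": filt.freeze_at,
            "backward_frozen_steps": n_frozen_steps,
        },
    )


def kalman_smoother(
    a_tilde: np.ndarray,
    q: np.ndarray,
    z_means: np.ndarray,
    theta: float,
    freeze_tol: float = 1e-9,
    store_covariances: bool = False,
) -> SmootherState:
    """Convenience wrapper: forward then backward pass."""
    n = np.atleast_2d(z_means).shape[1]
    filt = kalman_forward(a_tilde, q, z_means, theta, freeze_tol=freeze_tol)
    return kalman_backward(
        filt, a_tilde, n, freeze_tol=freeze_tol, store_covariances=store_covariances
    )
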