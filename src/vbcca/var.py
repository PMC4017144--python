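"""Vector autoregressive (VAR) processes and their first-order companion form.

A VAR(P) process on N regions,

    s(t) = sum_{p=1}^{P} A^(p) s(t-p) + eta(t),   eta(t) ~ N(0, Lambda^{-1}),

is represented by its P coefficient matrices and the innovation precision
Lambda.  Stacking P consecutive samples into an embedding state
x(t) = [s(t); s(t-1); ...; s(t-P+1)] turns it into a first-order model
x(t) = A_tilde x(t-1) + eta_tilde(t) whose transition matrix carries the
coefficient blocks in its top N rows and identity shift blocks below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VARParameters",
    "CompanionModel",
    "build_companion",
    "companion_transition",
    "spectral_radius",
    "simulate_var",
]

#: models with companion spectral radius at or above this are treated as
#: unstable: near-unit-root processes blow up numerically over long runs
STABILITY_THRESHOLD = 0.999


@dataclass(frozen=True, eq=False)
class VARParameters:
    """Coefficients {A^(p)} and innovation precision of a VAR(P) model.

    ``coeffs`` has shape (P, N, N); ``coeffs[p-1][i, j]`` predicts region i
    from region j at lag p, so a nonzero entry encodes influence j -> i.
    """

    coeffs: np.ndarray
    innovation_precision: np.ndarray

    def __post_init__(self) -> None:
        coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=float))
        lam = np.asarray(self.innovation_precision, dtype=float)
        if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
            raise ValueError("coeffs must have shape (P, N, N)")
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("coefficients must be finite")
        n = coeffs.shape[1]
        if lam.shape != (n, n):
            raise ValueError("innovation_precision must be N x N")
        if not np.allclose(lam, lam.T):
            raise ValueError("innovation_precision must be symmetric")
        try:
            np.linalg.cholesky(lam)
        except np.linalg.LinAlgError as exc:
            raise ValueError("innovation_precision must be positive definite") from exc
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "innovation_precision", lam)

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_regions(self) -> int:
        return self.coeffs.shape[1]

    @property
    def stacked(self) -> np.ndarray:
        """Coefficients as the N x PN block row [A^(1) ... A^(P)]."""
        return np.hstack(list(self.coeffs))


@dataclass(frozen=True, eq=False)
class CompanionModel:
    """First-order embedding: transition A_tilde and innovation covariance Q.

    Q is zero outside its top-left N x N block, which equals Lambda^{-1}.
    """

    a_tilde: np.ndarray
    q: np.ndarray


def companion_transition(stacked: np.ndarray, order: int) -> np.ndarray:
    """Build the PN x PN companion transition from the N x PN block row."""
    n = stacked.shape[0]
    pn = n * order
    if stacked.shape != (n, pn):
        raise ValueError("stacked coefficients must be N x PN")
    a_tilde = np.zeros((pn, pn))
    a_tilde[:n, :] = stacked
    if order > 1:
        idx = np.arange((order - 1) * n)
        a_tilde[n + idx, idx] = 1.0
    return a_tilde


def build_companion(params: VARParameters) -> CompanionModel:
    n, p = params.n_regions, params.order
    a_tilde = companion_transition(params.stacked, p)
    q = np.zeros((p * n, p * n))
    try:
        q[:n, :n] = np.linalg.inv(params.innovation_precision)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "innovation precision is singular; cannot form Q"
        ) from exc
    return CompanionModel(a_tilde=a_tilde, q=q)


def spectral_radius(model: CompanionModel | VARParameters) -> float:
    """Largest eigenvalue modulus of the companion transition matrix."""
    if isinstance(model, VARParameters):
        model = build_companion(model)
    return float(np.abs(np.linalg.eigvals(model.a_tilde)).max())


def simulate_var(
    params: VARParameters,
    T: int,
    rng: np.random.Generator | int | None = None,
    burn_in: int = 1000,
    force: bool = False,
) -> np.ndarray:
    """Simulate a stable VAR(P) process; returns an (N, T) array.

    Initial condition is s(t) = 0 for t <= 0 and the first ``burn_in``
    samples are discarded to remove the transient.  Deterministic given the
    seed.  Unstable models (companion spectral radius >= 0.999) are refused
    unless ``force`` is set.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    rho = spectral_radius(params)
    if rho >= STABILITY_THRESHOLD:
        if not force:
            raise ValueError(
                f"unstable VAR model (spectral radius {rho:.4f} >= "
                f"{STABILITY_THRESHOLD}); pass force=True to simulate anyway"
            )
        warnings.warn(
            f"simulating unstable VAR model (spectral radius {rho:.4f})",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(rng)
    n, p = params.n_regions, params.order
    stacked = params.stacked
    cov = np.linalg.inv(params.innovation_precision)
    chol = np.linalg.cholesky(cov)
    total = T + burn_in
    innovations = rng.standard_normal((total, n)) @ chol.T
    out = np.zeros((total, n))
    state = np.zeros(p * n)  # [s(t-1); ...; s(t-p)]
    for t in range(total):
        s_new = stacked @ state + innovations[t]
        out[t] = s_new
        if p > 1:
            state[n:] = state[:-n]
        state[:n] = s_new
    return out[burn_in:].T
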