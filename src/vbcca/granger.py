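"""Conditional Wiener-Granger causality (WGC) baseline.

For every ordered pair (j -> i) the conditional Granger magnitude is the
log ratio of the residual variance of region i under the full VAR(P) on all
regions, excluding region j's past, to the residual variance under the full
model, estimated by least squares on the demeaned series.  The VAR order is
either fixed or selected by the Bayesian information criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator
from statsmodels.tsa.api import VAR as _SMVAR

__all__ = ["GCResult", "conditional_granger", "select_order_bic", "GrangerCausality"]


@dataclass(frozen=True, eq=False)
class GCResult:
    """Conditional Granger magnitudes gc[i, j] (influence j -> i) and the order used."""

    gc: np.ndarray
    order: int


def _lag_design(Y: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack lagged regressors: column block p holds all regions at lag p."""
    n, T = Y.shape
    t_eff = T - order
    X = np.empty((t_eff, n * order))
    for p in range(1, order + 1):
        X[:, (p - 1) * n : p * n] = Y[:, order - p : T - p].T
    S = Y[:, order:].T
    return X, S


def _rss(gram: np.ndarray, xts: np.ndarray, sts: np.ndarray, label: str) -> np.ndarray:
    """Residual sum of squares per target column of a least-squares VAR fit."""
    try:
        chol = cho_factor(gram)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"rank-deficient regressor matrix for the {label} model"
        ) from exc
    beta = cho_solve(chol, xts)
    return sts - np.sum(xts * beta, axis=0)


def conditional_granger(Y: np.ndarray, order: int) -> GCResult:
    """Conditional Granger causality on an (N, T) series with a fixed order.

    Regions are demeaned before fitting.  Raw magnitudes (no significance
    thresholding) are returned with negative values floored at zero and a
    zero diagonal.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, T = Y.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    if T <= n * order + order:
        raise ValueError(
            f"series too short for identifiable least squares: need T > {n * order + order}"
        )
    Y = Y - Y.mean(axis=1, keepdims=True)
    X, S = _lag_design(Y, order)
    gram = X.T @ X
    xts = X.T @ S
    sts = np.sum(S**2, axis=0)
    rss_full = _rss(gram, xts, sts, "full")

    gc = np.zeros((n, n))
    all_idx = np.arange(n * order)
    for j in range(n):
        keep = all_idx[all_idx % n != j]
        try:
            rss_red = _rss(gram[np.ix_(keep, keep)], xts[keep], sts, f"reduced (without region {j})")
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"rank-deficient regressors when excluding region {j}"
            ) from exc
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log(rss_red / rss_full)
        ratio[j] = 0.0
        gc[:, j] = np.maximum(ratio, 0.0)
    np.fill_diagonal(gc, 0.0)
    return GCResult(gc=gc, order=order)


def select_order_bic(Y: np.ndarray, max_order: int = 20) -> int:
    """VAR order in 1..max_order minimizing the multivariate Gaussian BIC."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    data = (Y - Y.mean(axis=1, keepdims=True)).T
    sel = _SMVAR(data).select_order(maxlags=max_order, trend="n")
    return max(1, int(sel.selected_orders["bic"]))


class GrangerCausality(BaseEstimator):
    """Conditional Granger-causality estimator over all region pairs.

    Parameters
    ----------
    order : int or "bic"
        Fixed VAR order, or BIC selection over ``1..max_order``.
    max_order : int
        Upper end of the BIC search range.

    Attributes
    ----------
    connectivity_ : ndarray, shape (N, N)
        gc[i, j], the conditional Granger magnitude of j -> i.
    order_ : int
        The order actually used.
    """

    def __init__(self, order: int | str = 1, max_order: int = 20):
        self.order = order
        self.max_order = max_order

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (T, N) array")
        Y = X.T
        if self.order == "bic":
            order = select_order_bic(Y, self.max_order)
        else:
            order = int(self.order)
        result = conditional_granger(Y, order)
        self.connectivity_ = result.gc
        self.order_ = result.order
        return self
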