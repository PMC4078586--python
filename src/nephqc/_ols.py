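"""Shared least-squares helpers.

The spline-point grid search evaluates a leave-one-out CV RMSE for every
candidate knot.  For ordinary least squares the leave-one-out fitted value
has the closed form y_i - e_i / (1 - h_ii), where e_i is the full-sample
residual and h_ii the leverage, so the grid search never needs an explicit
refit loop.  The explicit loop exists independently in the test suite and
must agree to machine precision.
"""

from __future__ import annotations

import numpy as np

from .errors import FitError


def ols_loo_fitted(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out fitted values of OLS on (X, y), plus the full-sample betas.

    Raises FitError when the design is rank deficient or a point has
    leverage ~1 (the fold would be unpredictable without it).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise FitError("rank-deficient design")
    Q, _ = np.linalg.qr(X)
    leverage = np.einsum("ij,ij->i", Q, Q)
    denom = 1.0 - leverage
    if np.any(denom < 1e-10):
        raise FitError("a point has leverage ~1; leave-one-out undefined")
    resid = y - X @ beta
    return y - resid / denom, beta


def loo_rmse_logscale_model(X: np.ndarray, log_y: np.ndarray, y: np.ndarray) -> float:
    """LOO-CV RMSE, on the original concentration scale, of an OLS model
    fit on log_y = ln(y).  Log-scale LOO predictions are exponentiated with
    no retransformation correction."""
    loo_log, _ = ols_loo_fitted(X, log_y)
    err = np.exp(loo_log) - y
    return float(np.sqrt(np.mean(err**2)))
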