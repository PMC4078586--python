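"""Gravimetric-equivalency conversion of humidity-adjusted nephelometric PM.

A nephelometer is factory-calibrated against a standard test dust; cookstove
smoke scatters light differently, so humidity-adjusted nephelometric PM
(HAN PM) must be converted to gravimetric-equivalent PM2.5 with a regression
against co-located filter samples.  Four forms are supported:

``linear_origin``    Gravimetric = b · HAN                 (forced through 0)
``loglog``           ln(Gravimetric) = a + b·ln(HAN)
``loglog_spline``    ln(Gravimetric) = a + b·ln(HAN) + c·max(ln(HAN) − d, 0)
``loglog_quadratic`` ln(Gravimetric) = a + b·ln(HAN) + c·ln(HAN)²

The hinge knot d is chosen by grid search over ln(HAN) from 7.5 to 12.0 in
steps of 0.1, selecting the knot with the smallest leave-one-out CV RMSE on
the original µg/m³ scale (ties broken toward the smallest knot).  Log-family
predictions are plain exponentials of the linear predictor, with no
retransformation (smearing) correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from ._ols import loo_rmse_logscale_model
from .errors import FitError, InputError, RangeWarning

GRAV_FORMS = ("linear_origin", "loglog", "loglog_spline", "loglog_quadratic")

#: applicability range of the calibration, µg/m³ of nephelometric PM
APPLICABILITY_RANGE = (600.0, 66000.0)

SPLINE_GRID_DEFAULT = np.round(np.arange(7.5, 12.0 + 1e-9, 0.1), 1)

_N_PARAMS = {"linear_origin": 1, "loglog": 2, "loglog_quadratic": 3, "loglog_spline": 3}


@dataclass
class GravimetricModel:
    """HAN PM → gravimetric PM2.5 conversion model.

    ``a`` is pinned to 0 for linear_origin.  ``c`` is the hinge or quadratic
    coefficient; ``d`` the spline knot on the ln(HAN PM) scale."""

    form: str
    a: float
    b: float
    c: float | None = None
    d: float | None = None
    cv_rmse: float | None = None
    ci: dict | None = None

    def __post_init__(self) -> None:
        if self.form not in GRAV_FORMS:
            raise InputError(f"unknown gravimetric form {self.form!r}")
        if self.form == "linear_origin" and self.a != 0.0:
            raise InputError("linear_origin requires a = 0")

    def to_dict(self) -> dict:
        return {
            "kind": "gravimetric",
            "form": self.form,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "cv_rmse": self.cv_rmse,
            "ci": self.ci,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GravimetricModel":
        return cls(
            form=d["form"],
            a=float(d["a"]),
            b=float(d["b"]),
            c=None if d.get("c") is None else float(d["c"]),
            d=None if d.get("d") is None else float(d["d"]),
            cv_rmse=d.get("cv_rmse"),
            ci=d.get("ci"),
        )


def _spline_design(lh: np.ndarray, d: float) -> np.ndarray:
    return np.column_stack([np.ones_like(lh), lh, np.maximum(lh - d, 0.0)])


def _ci_dict(res, names) -> dict:
    ci = res.conf_int(alpha=0.05)
    return {n: [float(ci[i, 0]), float(ci[i, 1])] for i, n in enumerate(names)}


def fit_gravimetric(
    han, grav, form: str = "loglog", spline_grid=None
) -> GravimetricModel:
    """Fit a conversion model by ordinary least squares.

    For ``loglog_spline`` every knot in ``spline_grid`` (default 7.5…12.0
    step 0.1) with at least two points on each side is evaluated by
    leave-one-out CV RMSE on the original scale; the best (smallest-knot on
    ties) is refit on all data.  A grid entirely outside the data range
    degrades to a plain loglog fit with a warning.
    """
    han = np.asarray(han, dtype=float)
    grav = np.asarray(grav, dtype=float)
    if han.shape != grav.shape:
        raise InputError("han and grav must have equal length")
    if np.any(han <= 0) or np.any(grav <= 0):
        raise InputError("concentrations must be > 0")
    if form not in GRAV_FORMS:
        raise InputError(f"unknown gravimetric form {form!r}")
    n = len(han)
    if n < _N_PARAMS[form] + 1:
        raise FitError(f"{form}: need at least {_N_PARAMS[form] + 1} points, got {n}")

    if form == "linear_origin":
        res = sm.OLS(grav, han[:, None]).fit()
        return GravimetricModel(
            form, 0.0, float(res.params[0]), ci=_ci_dict(res, ["b"])
        )

    lh = np.log(han)
    lg = np.log(grav)
    if np.ptp(lh) == 0:
        raise FitError("constant regressor")

    if form == "loglog":
        res = sm.OLS(lg, sm.add_constant(lh)).fit()
        return GravimetricModel(
            form, float(res.params[0]), float(res.params[1]), ci=_ci_dict(res, ["a", "b"])
        )

    if form == "loglog_quadratic":
        X = np.column_stack([np.ones_like(lh), lh, lh**2])
        res = sm.OLS(lg, X).fit()
        return GravimetricModel(
            form,
            float(res.params[0]),
            float(res.params[1]),
            float(res.params[2]),
            ci=_ci_dict(res, ["a", "b", "c"]),
        )

    # loglog_spline: knot by exhaustive grid + LOO-CV RMSE (original scale)
    grid = SPLINE_GRID_DEFAULT if spline_grid is None else np.asarray(spline_grid, dtype=float)
    best_rmse, best_d = np.inf, None
    for d in grid:
        if np.sum(lh > d) < 2 or np.sum(lh <= d) < 2:
            continue
        try:
            rmse = loo_rmse_logscale_model(_spline_design(lh, d), lg, grav)
        except FitError:
            continue
        if rmse < best_rmse:  # strict <, ascending grid => smallest knot on ties
            best_rmse, best_d = rmse, float(d)
    if best_d is None:
        warnings.warn(
            "spline grid has no knot interior to the data; falling back to loglog",
            RangeWarning,
            stacklevel=2,
        )
        return fit_gravimetric(han, grav, "loglog")
    res = sm.OLS(lg, _spline_design(lh, best_d)).fit()
    return GravimetricModel(
        form,
        float(res.params[0]),
        float(res.params[1]),
        float(res.params[2]),
        d=best_d,
        cv_rmse=best_rmse,
        ci=_ci_dict(res, ["a", "b", "c"]),
    )


def predict_gravimetric(m: GravimetricModel, han):
    """Gravimetric-equivalent PM2.5 (µg/m³) for HAN PM values.

    Emits a RangeWarning when a value falls outside the ~600–66,000 µg/m³
    range the calibration covers."""
    h = np.asarray(han, dtype=float)
    if np.any(h <= 0):
        raise InputError("han must be > 0")
    lo, hi = APPLICABILITY_RANGE
    if np.any((h < lo) | (h > hi)):
        warnings.warn(
            f"HAN PM outside the calibrated range [{lo:g}, {hi:g}] µg/m³",
            RangeWarning,
            stacklevel=2,
        )
    if m.form == "linear_origin":
        out = m.b * h
    else:
        lh = np.log(h)
        lp = m.a + m.b * lh
        if m.form == "loglog_spline":
            lp = lp + m.c * np.maximum(lh - m.d, 0.0)
        elif m.form == "loglog_quadratic":
            lp = lp + m.c * lh**2
        out = np.exp(lp)
    return out if np.ndim(han) else float(out)
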