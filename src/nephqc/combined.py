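"""One-step combined humidity + gravimetric-equivalency adjustment.

Substituting the log-linear humidity model ln CF = a₂ + b₂·ln(1 − RH) into
the log-log conversion ln(Grav) = a₄ + b₄·ln(HAN), with
HAN = Neph / CF, collapses the two-step quality control into a single
regression of ln(gravimetric PM2.5) on ln(1 − RH) and ln(nephelometric PM):

    ln(Grav PM2.5) = c0 + c1·ln(1 − RH) + c2·ln(Neph PM)  [+ hinge or quad]

so that c0 = a₄ − b₄a₂, c1 = −b₄b₂ and c2 = b₄.  The combined form has one
response variable, involves the reference (gravimetric) value only once,
and uses no RH threshold anywhere.  The hinge variant adds
c3·max(ln(Neph) − knot, 0) with the knot chosen by the same grid-plus-CV
search as the two-step spline; the quadratic variant adds c3·ln(Neph)².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from ._ols import loo_rmse_logscale_model
from .errors import FitError, InputError, RangeWarning
from .gravimetric import APPLICABILITY_RANGE, SPLINE_GRID_DEFAULT
from .sample_io import CoLocationSample, eligible_samples

COMBINED_FORMS = ("loglinear", "loglinear_spline", "loglinear_quadratic")

_N_PARAMS = {"loglinear": 3, "loglinear_spline": 4, "loglinear_quadratic": 4}


@dataclass
class CombinedModel:
    """One-step model of ln(gravimetric PM2.5) in ln(1−RH) and ln(neph PM).

    ``c3`` is the hinge coefficient (spline form) or the quadratic
    coefficient; ``knot`` is the spline point on the ln(nephelometric PM)
    scale (spline form only)."""

    form: str
    c0: float
    c1: float
    c2: float
    c3: float | None = None
    knot: float | None = None
    cv_rmse: float | None = None
    ci: dict | None = None
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        if self.form not in COMBINED_FORMS:
            raise InputError(f"unknown combined form {self.form!r}")

    def to_dict(self) -> dict:
        return {
            "kind": "combined",
            "form": self.form,
            "c0": self.c0,
            "c1": self.c1,
            "c2": self.c2,
            "c3": self.c3,
            "knot": self.knot,
            "cv_rmse": self.cv_rmse,
            "ci": self.ci,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CombinedModel":
        return cls(
            form=d["form"],
            c0=float(d["c0"]),
            c1=float(d["c1"]),
            c2=float(d["c2"]),
            c3=None if d.get("c3") is None else float(d["c3"]),
            knot=None if d.get("knot") is None else float(d["knot"]),
            cv_rmse=d.get("cv_rmse"),
            ci=d.get("ci"),
            provenance=d.get("provenance", "fitted"),
        )


def _design(form: str, ln_neph: np.ndarray, ln1mrh: np.ndarray, knot: float | None):
    cols = [np.ones_like(ln_neph), ln1mrh, ln_neph]
    if form == "loglinear_spline":
        cols.append(np.maximum(ln_neph - knot, 0.0))
    elif form == "loglinear_quadratic":
        cols.append(ln_neph**2)
    return np.column_stack(cols)


def fit_combined_arrays(
    neph, grav, rh, form: str = "loglinear", spline_grid=None
) -> CombinedModel:
    """Fit from plain arrays of nephelometric PM, gravimetric PM and RH."""
    neph = np.asarray(neph, dtype=float)
    grav = np.asarray(grav, dtype=float)
    r = np.asarray(rh, dtype=float)
    if form not in COMBINED_FORMS:
        raise InputError(f"unknown combined form {form!r}")
    if not (neph.shape == grav.shape == r.shape):
        raise InputError("neph, grav and rh must have equal length")
    if np.any(neph <= 0) or np.any(grav <= 0):
        raise InputError("concentrations must be > 0")
    if np.any((r < 0) | (r >= 1)):
        raise InputError("rh must lie in [0, 1)")
    n = len(neph)
    if n < max(5, _N_PARAMS[form] + 1):
        raise FitError(f"{form}: need at least {max(5, _N_PARAMS[form] + 1)} samples")

    ln_neph = np.log(neph)
    ln1mrh = np.log1p(-r)
    lg = np.log(grav)

    def _refit(knot: float | None, cv_rmse: float | None) -> CombinedModel:
        X = _design(form, ln_neph, ln1mrh, knot)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise FitError("collinear design")
        res = sm.OLS(lg, X).fit()
        names = ["c0", "c1", "c2"] + (["c3"] if X.shape[1] == 4 else [])
        ci = res.conf_int(alpha=0.05)
        return CombinedModel(
            form,
            *[float(p) for p in res.params],
            knot=knot,
            cv_rmse=cv_rmse,
            ci={nm: [float(ci[i, 0]), float(ci[i, 1])] for i, nm in enumerate(names)},
        )

    if form != "loglinear_spline":
        return _refit(None, None)

    grid = SPLINE_GRID_DEFAULT if spline_grid is None else np.asarray(spline_grid, dtype=float)
    best_rmse, best_knot = np.inf, None
    for f in grid:
        if np.sum(ln_neph > f) < 2 or np.sum(ln_neph <= f) < 2:
            continue
        X = _design(form, ln_neph, ln1mrh, f)
        try:
            rmse = loo_rmse_logscale_model(X, lg, grav)
        except FitError:
            continue
        if rmse < best_rmse:  # ascending grid => ties go to the smaller knot
            best_rmse, best_knot = rmse, float(f)
    if best_knot is None:
        warnings.warn(
            "spline grid has no knot interior to the data; falling back to loglinear",
            RangeWarning,
            stacklevel=2,
        )
        return fit_combined_arrays(neph, grav, r, "loglinear")
    return _refit(best_knot, best_rmse)


def fit_combined(
    samples: Sequence[CoLocationSample],
    form: str = "loglinear",
    spline_grid=None,
    include_below_lod: bool = False,
) -> CombinedModel:
    """Fit the combined model on a co-location campaign (below-LOD samples
    excluded unless overridden).  No RH threshold is involved."""
    usable = eligible_samples(samples, include_below_lod)
    return fit_combined_arrays(
        [s.neph_pm for s in usable],
        [s.grav_pm for s in usable],
        [s.rh for s in usable],
        form=form,
        spline_grid=spline_grid,
    )


def predict_combined(m: CombinedModel, pm, rh):
    """Gravimetric-equivalent PM2.5 from raw nephelometric PM and RH.

    Vectorized over time series; warns when nephelometric PM falls outside
    the ~600–66,000 µg/m³ applicability range."""
    p = np.asarray(pm, dtype=float)
    r = np.asarray(rh, dtype=float)
    if np.any(p <= 0):
        raise InputError("pm must be > 0")
    if np.any((r < 0) | (r > 0.99)):
        raise InputError("rh must lie in [0, 0.99]")
    lo, hi = APPLICABILITY_RANGE
    if np.any((p < lo) | (p > hi)):
        warnings.warn(
            f"nephelometric PM outside the calibrated range [{lo:g}, {hi:g}] µg/m³",
            RangeWarning,
            stacklevel=2,
        )
    ln_p = np.log(p)
    lp = m.c0 + m.c1 * np.log1p(-r) + m.c2 * ln_p
    if m.form == "loglinear_spline":
        lp = lp + m.c3 * np.maximum(ln_p - m.knot, 0.0)
    elif m.form == "loglinear_quadratic":
        lp = lp + m.c3 * ln_p**2
    out = np.exp(lp)
    return out if (np.ndim(pm) or np.ndim(rh)) else float(out)
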