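"""Humidity correction-factor models for nephelometric PM.

Hygroscopic particle growth makes a nephelometer overestimate PM mass at
high relative humidity, and size shrinkage at very low RH can make it
underestimate.  The correction factor CF(RH) is the ratio of the
humidity-influenced nephelometric concentration to the humidity-independent
(gravimetric) concentration; dividing a nephelometer reading by CF(RH)
yields humidity-adjusted nephelometric PM (HAN PM).

Two model families are supported:

``chakrabarti``   CF = a + b · RH² / (1 − RH)
    The empirical hygroscopic-growth form; the widely used published
    parameterisation has a = 1, b = 0.25.

``richards_log``  ln CF = a + b · ln(1 − RH)
    A log-linear form fit by ordinary least squares; with b < 0, CF rises
    steeply as RH → 1.

Conventionally no adjustment is applied below a 60% RH threshold (CF = 1
there).  Both families are fit on all samples regardless of the threshold;
the threshold is a prediction-time rule only, so a single (a, b) pair
serves both the thresholded and unthresholded applications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import FitError, InputError, ModelValidityError
from .sample_io import CoLocationSample

DEFAULT_RH_THRESHOLD = 0.60

CF_FORMS = ("chakrabarti", "richards_log")


@dataclass
class CorrectionFactorModel:
    """CF(RH) model: functional form plus parameters a, b.

    ``rh_threshold`` is the RH fraction below which no adjustment is made
    when thresholding is requested at prediction time (default 0.60).
    ``provenance`` distinguishes published parameter sets from fits to
    local co-location data.
    """

    form: str
    a: float
    b: float
    rh_threshold: float | None = None
    provenance: str = "fitted"
    ci_a: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.form not in CF_FORMS:
            raise InputError(f"unknown CF form {self.form!r}")

    def to_dict(self) -> dict:
        return {
            "kind": "cf",
            "form": self.form,
            "a": self.a,
            "b": self.b,
            "ci_a": list(self.ci_a) if self.ci_a else None,
            "ci_b": list(self.ci_b) if self.ci_b else None,
            "rh_threshold": self.rh_threshold,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionFactorModel":
        return cls(
            form=d["form"],
            a=float(d["a"]),
            b=float(d["b"]),
            rh_threshold=d.get("rh_threshold"),
            provenance=d.get("provenance", "fitted"),
            ci_a=tuple(d["ci_a"]) if d.get("ci_a") else None,
            ci_b=tuple(d["ci_b"]) if d.get("ci_b") else None,
        )


@dataclass
class ObservedCF:
    """An observed correction factor: neph_pm / grav_pm at a given RH."""

    sample_id: str
    rh: float
    cf: float

    def __post_init__(self) -> None:
        if not self.cf > 0:
            raise InputError(f"{self.sample_id}: observed CF must be > 0")


def observed_cf(s: CoLocationSample) -> ObservedCF:
    """CF = nephelometric / gravimetric for one co-location pair."""
    if s.below_lod:
        raise InputError(f"{s.sample_id}: below-LOD sample excluded from CF calculation")
    if not s.grav_pm > 0:
        raise InputError(f"{s.sample_id}: gravimetric PM must be > 0")
    return ObservedCF(s.sample_id, s.rh, s.neph_pm / s.grav_pm)


def _cf_curve(m: CorrectionFactorModel, rh: np.ndarray) -> np.ndarray:
    if m.form == "chakrabarti":
        return m.a + m.b * rh**2 / (1.0 - rh)
    return np.exp(m.a + m.b * np.log1p(-rh))


def cf_predict(m: CorrectionFactorModel, rh, use_threshold: bool = False):
    """Evaluate CF(RH); with ``use_threshold`` the CF is 1 (no adjustment)
    for RH at or below the model's threshold (default 0.60)."""
    r = np.asarray(rh, dtype=float)
    if np.any((r < 0) | (r > 0.99)):
        raise InputError("rh must lie in [0, 0.99]")
    cf = _cf_curve(m, r)
    if use_threshold:
        thr = m.rh_threshold if m.rh_threshold is not None else DEFAULT_RH_THRESHOLD
        active = r > thr
    else:
        active = np.ones_like(r, dtype=bool)
    if m.form == "chakrabarti" and np.any(cf[active] <= 0):
        raise ModelValidityError(
            f"chakrabarti CF <= 0 for a={m.a}, b={m.b} at some requested RH"
        )
    cf = np.where(active, cf, 1.0)
    return cf if np.ndim(rh) else float(cf)


def fit_cf(observed: Sequence[ObservedCF], form: str) -> CorrectionFactorModel:
    """Fit a CF model by ordinary least squares.

    chakrabarti : CF regressed on x = RH²/(1−RH) (intercept a, slope b)
    richards_log: ln CF regressed on ln(1−RH)    (intercept a, slope b)

    Returns the model with 95% confidence intervals on both parameters.
    """
    if form not in CF_FORMS:
        raise InputError(f"unknown CF form {form!r}")
    if len(observed) < 3:
        raise FitError("need at least 3 observed correction factors")
    rh = np.array([o.rh for o in observed], dtype=float)
    cf = np.array([o.cf for o in observed], dtype=float)
    if np.ptp(rh) == 0:
        raise FitError("rh values all equal; CF regression is degenerate")
    if form == "chakrabarti":
        x = rh**2 / (1.0 - rh)
        y = cf
    else:
        x = np.log1p(-rh)
        y = np.log(cf)
    if np.ptp(x) == 0:
        raise FitError("constant regressor; CF regression is degenerate")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return CorrectionFactorModel(
        form=form,
        a=float(res.params[0]),
        b=float(res.params[1]),
        ci_a=(float(ci[0, 0]), float(ci[0, 1])),
        ci_b=(float(ci[1, 0]), float(ci[1, 1])),
        provenance="fitted",
    )


def adjust_pm(pm, rh, m: CorrectionFactorModel, use_threshold: bool = False):
    """Humidity-adjust PM: HAN PM = PM / CF(RH).  Vectorizes over aligned
    time series for whole-day application."""
    p = np.asarray(pm, dtype=float)
    if np.any(p < 0):
        raise InputError("pm must be >= 0")
    out = p / cf_predict(m, rh, use_threshold=use_threshold)
    return out if (np.ndim(pm) or np.ndim(rh)) else float(out)
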