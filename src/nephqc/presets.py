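"""Published parameter presets from the Nepal cookstove co-location study.

The pDR-1000 calibration campaign behind this package published parameter
sets for three humidity adjustment equations (1a: the original published
hygroscopic form; 1b: the same form refit on the cookstove data; 2a: the
log-linear form refit on the cookstove data), for all four gravimetric
conversion forms under each humidity adjustment (with and without the 60%
RH threshold), and for the combined one-step equation.  They are shipped
here verbatim so published-parameter predictions can be made without
refitting, and so the comparison table can label its approaches the same
way.  Published RMSEs reflect the original 65 field pairs, which are not
distributed; they are context, not reproducible oracles.
"""

from __future__ import annotations

from .combined import CombinedModel
from .humidity import DEFAULT_RH_THRESHOLD, CorrectionFactorModel
from .gravimetric import GravimetricModel

HUMIDITY_EQS = ("1a", "1b", "2a")

#: humidity CF parameter sets; 1a has no published confidence intervals
_CF_PRESETS = {
    "1a": dict(form="chakrabarti", a=1.0, b=0.25, ci_a=None, ci_b=None,
               provenance="published_1a"),
    "1b": dict(form="chakrabarti", a=0.72, b=0.38, ci_a=(0.65, 0.79),
               ci_b=(0.33, 0.44), provenance="published"),
    "2a": dict(form="richards_log", a=-0.72, b=-0.82, ci_a=(-0.82, -0.62),
               ci_b=(-0.93, -0.71), provenance="published"),
}

#: published CF-model RMSE (unitless), keyed (equation, with_threshold)
CF_PUBLISHED_RMSE = {
    ("1a", True): 0.506, ("1a", False): 0.514,
    ("1b", True): 0.521, ("1b", False): 0.495,
    ("2a", True): 0.515, ("2a", False): 0.490,
}


def published_cf_model(eq: str, with_threshold: bool = False) -> CorrectionFactorModel:
    """Published humidity CF model ``eq`` in {'1a', '1b', '2a'}.

    ``with_threshold`` only sets the stored threshold value; whether the
    threshold is applied is decided at prediction time."""
    p = _CF_PRESETS[eq]
    return CorrectionFactorModel(
        form=p["form"], a=p["a"], b=p["b"],
        rh_threshold=DEFAULT_RH_THRESHOLD if with_threshold else None,
        provenance=p["provenance"], ci_a=p["ci_a"], ci_b=p["ci_b"],
    )


# ---------------------------------------------------------------------------
# gravimetric conversion presets, keyed (humidity eq, with_threshold, form).
# Column order in the published table: with threshold 1a, 1b, 2a; without
# threshold 1a, 1b, 2a.  The spline coefficient −4.051 for (1a, True) is an
# order of magnitude off its column neighbours and is almost certainly a
# misprint; it is shipped verbatim but must not be used as a numeric
# reference.

_G = {}


def _grav(eq, thr, form, **kw):
    _G[(eq, thr, form)] = kw


for _eq, _thr, _b, _rmse in [
    ("1a", True, 0.848, 3927), ("1b", True, 0.845, 4002), ("2a", True, 0.831, 4005),
    ("1a", False, 0.892, 3956), ("1b", False, 0.757, 3982), ("2a", False, 0.696, 3955),
]:
    _grav(_eq, _thr, "linear_origin", a=0.0, b=_b, rmse=_rmse)

for _eq, _thr, _a, _b, _rmse in [
    ("1a", True, 2.726, 0.711, 2889), ("1b", True, 2.750, 0.707, 2977),
    ("2a", True, 2.753, 0.706, 2969), ("1a", False, 2.723, 0.715, 2932),
    ("1b", False, 2.510, 0.724, 3001), ("2a", False, 2.395, 0.730, 2990),
]:
    _grav(_eq, _thr, "loglog", a=_a, b=_b, rmse=_rmse)

for _eq, _thr, _a, _b, _c, _d, _rmse in [
    ("1a", True, 0.859, 0.949, -4.051, 8.4, 2703),  # c likely misprinted
    ("1b", True, 0.872, 0.948, -0.411, 8.4, 2768),
    ("2a", True, 0.822, 0.953, -0.416, 8.4, 2773),
    ("1a", False, 0.565, 0.995, -0.430, 8.2, 2742),
    ("1b", False, 0.921, 0.921, -0.471, 8.9, 2650),
    ("2a", False, 0.868, 0.917, -0.502, 9.1, 2620),
]:
    _grav(_eq, _thr, "loglog_spline", a=_a, b=_b, c=_c, d=_d, rmse=_rmse)

for _eq, _thr, _a, _b, _c, _rmse in [
    ("1a", True, -4.867, 2.502, -0.105, 2682), ("1b", True, -4.945, 2.527, -0.106, 2750),
    ("2a", True, -4.951, 2.522, -0.106, 2759), ("1a", False, -4.994, 2.544, -0.107, 2715),
    ("1b", False, -6.049, 2.722, -0.115, 2652), ("2a", False, -6.607, 2.809, -0.119, 2619),
]:
    _grav(_eq, _thr, "loglog_quadratic", a=_a, b=_b, c=_c, rmse=_rmse)


def published_gravimetric_model(eq: str, with_threshold: bool, form: str) -> GravimetricModel:
    """Published conversion model for humidity equation ``eq`` applied
    with/without the 60% RH threshold, in the given functional form."""
    p = _G[(eq, with_threshold, form)]
    return GravimetricModel(
        form=form, a=p["a"], b=p["b"], c=p.get("c"), d=p.get("d"), cv_rmse=float(p["rmse"])
    )


#: combined one-step equation, fitted on the 65 field pairs
COMBINED_EQ7 = CombinedModel(
    form="loglinear", c0=3.102, c1=0.701, c2=0.717, provenance="published"
)

#: combined spline equation: only the knot (8.1, ln-neph scale) and the
#: hinge coefficient (−0.254) were published; the remaining coefficients
#: must be refit on local data before the model can predict.
COMBINED_EQ8_PARTIAL = {"knot": 8.1, "c3": -0.254}

#: published comparison-table RMSEs (µg/m³), keyed by approach number 1–21
PUBLISHED_COMPARISON_RMSE = {
    1: 3066, 2: 3007, 3: 3243,
    4: 2922, 5: 2959, 6: 2962,
    7: 2641, 8: 2600, 9: 2593,
    10: 2696, 11: 2628, 12: 2607,
    13: 2925, 14: 2948, 15: 2948,
    16: 2652, 17: 2687, 18: 2689,
    19: 2716, 20: 2736, 21: 2744,
}


def published_combined_eq7() -> CombinedModel:
    """The published combined loglinear equation (one-step adjustment)."""
    return CombinedModel(**{k: v for k, v in COMBINED_EQ7.to_dict().items()
                            if k not in ("kind", "cv_rmse", "ci", "c3", "knot")})
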