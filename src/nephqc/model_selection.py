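"""Leave-one-out cross-validation and the 21-approach comparison table.

Every adjustment approach is scored by leave-one-out CV RMSE on the
original µg/m³ scale: each co-location pair in turn is held out, every
parameter of the approach is re-estimated on the remaining pairs
(including the spline knot, where applicable), the held-out pair is
predicted, and the root mean squared prediction error is taken over all
folds.  Log-scale model predictions are exponentiated before the error is
computed, with no retransformation correction.

The two-step approaches fit the humidity correction factor and the
gravimetric conversion sequentially inside each fold; the combined
approaches fit a single regression.  The comparison table enumerates the
3 combined forms plus all 18 two-step combinations of
{1a fixed, 1b refit, 2a refit} × {with, without 60% RH threshold} ×
{log-log, log-log + spline, log-log + quadratic}; the traditional linear
conversion is excluded from the comparison because it is uniformly worse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .combined import fit_combined_arrays, predict_combined
from .errors import FoldError, InputError, RangeWarning
from .gravimetric import fit_gravimetric, predict_gravimetric
from .humidity import CorrectionFactorModel, ObservedCF, adjust_pm, cf_predict, fit_cf
from .presets import published_cf_model
from .sample_io import CoLocationSample, eligible_samples


@dataclass
class CVResult:
    """Per-fold LOO predictions and original-scale RMSE for one approach."""

    approach_id: str
    n_folds: int
    predictions: np.ndarray
    observed: np.ndarray
    rmse: float

    @staticmethod
    def from_predictions(approach_id: str, predictions, observed) -> "CVResult":
        predictions = np.asarray(predictions, dtype=float)
        observed = np.asarray(observed, dtype=float)
        rmse = float(np.sqrt(np.mean((predictions - observed) ** 2)))
        return CVResult(approach_id, len(observed), predictions, observed, rmse)


def _default_observe(s):
    if hasattr(s, "grav_pm"):
        return s.grav_pm
    return s[1]


def loo_cv(
    samples: Sequence,
    fit_fn: Callable,
    predict_fn: Callable,
    observe_fn: Callable | None = None,
    approach_id: str = "custom",
) -> CVResult:
    """Exhaustive leave-one-out CV for any fit/predict pair.

    ``fit_fn(train)`` returns a model; ``predict_fn(model, sample)`` a
    prediction on the observation scale; ``observe_fn(sample)`` the
    observed value (defaults to ``.grav_pm`` or the second tuple element).
    """
    samples = list(samples)
    n = len(samples)
    if n < 3:
        raise InputError("need at least 3 samples for leave-one-out CV")
    observe_fn = observe_fn or _default_observe
    obs = np.array([observe_fn(s) for s in samples], dtype=float)
    preds = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RangeWarning)
        for i in range(n):
            train = samples[:i] + samples[i + 1 :]
            try:
                model = fit_fn(train)
                preds[i] = predict_fn(model, samples[i])
            except Exception as exc:  # annotate which fold broke
                raise FoldError(f"fold {i} ({approach_id}): {exc}") from exc
    return CVResult.from_predictions(approach_id, preds, obs)


# ---------------------------------------------------------------------------
# convenience wrappers


def loo_cv_gravimetric(han, grav, form: str, spline_grid=None, approach_id=None) -> CVResult:
    pairs = list(zip(np.asarray(han, dtype=float), np.asarray(grav, dtype=float)))
    return loo_cv(
        pairs,
        fit_fn=lambda tr: fit_gravimetric(
            [p[0] for p in tr], [p[1] for p in tr], form, spline_grid
        ),
        predict_fn=lambda m, s: float(predict_gravimetric(m, s[0])),
        approach_id=approach_id or f"gravimetric:{form}",
    )


def loo_cv_combined(
    samples: Sequence[CoLocationSample], form: str, spline_grid=None, approach_id=None
) -> CVResult:
    usable = eligible_samples(samples)
    return loo_cv(
        usable,
        fit_fn=lambda tr: fit_combined_arrays(
            [s.neph_pm for s in tr],
            [s.grav_pm for s in tr],
            [s.rh for s in tr],
            form,
            spline_grid,
        ),
        predict_fn=lambda m, s: float(predict_combined(m, s.neph_pm, s.rh)),
        approach_id=approach_id or f"combined:{form}",
    )


def two_step_cv(
    samples: Sequence[CoLocationSample],
    cf_form: str,
    use_threshold: bool,
    grav_form: str,
    spline_grid=None,
    cf_model: CorrectionFactorModel | None = None,
    approach_id: str | None = None,
) -> CVResult:
    """LOO CV of the sequential two-step adjustment.

    Per fold: (1) fit the CF model on the training pairs' observed
    correction factors (or keep ``cf_model`` fixed when given, as for the
    published 1a parameters); (2) humidity-adjust the training
    nephelometric values with the fold's CF model and threshold rule;
    (3) fit the gravimetric conversion on the training (HAN, grav) pairs;
    (4) adjust and convert the held-out pair with the fold's two models.
    """
    usable = eligible_samples(samples)
    if len(usable) < 4:
        raise InputError("need at least 4 usable samples for two-step CV")

    def fit_fold(train):
        rh = np.array([s.rh for s in train])
        neph = np.array([s.neph_pm for s in train])
        grav = np.array([s.grav_pm for s in train])
        if cf_model is None:
            cfs = [ObservedCF(s.sample_id, s.rh, s.neph_pm / s.grav_pm) for s in train]
            m_cf = fit_cf(cfs, cf_form)
        else:
            m_cf = cf_model
        han = adjust_pm(neph, rh, m_cf, use_threshold=use_threshold)
        m_grav = fit_gravimetric(han, grav, grav_form, spline_grid)
        return m_cf, m_grav

    def predict_fold(models, s):
        m_cf, m_grav = models
        han = s.neph_pm / cf_predict(m_cf, s.rh, use_threshold=use_threshold)
        return float(predict_gravimetric(m_grav, han))

    label = approach_id or (
        f"two_step:{cf_form}:{'thr' if use_threshold else 'nothr'}:{grav_form}"
    )
    return loo_cv(usable, fit_fold, predict_fold, approach_id=label)


def cf_model_rmse(
    observed: Sequence[ObservedCF],
    form: str | None = None,
    use_threshold: bool = False,
    cf_model: CorrectionFactorModel | None = None,
) -> CVResult:
    """Correction-factor model RMSE on the dimensionless CF scale.

    For a fixed published model the RMSE is the plain residual RMSE over
    all points (no parameters were estimated from the data); for a refit
    form it is the leave-one-out CV RMSE.
    """
    observed = list(observed)
    obs = np.array([o.cf for o in observed])
    if cf_model is not None:
        preds = np.array([cf_predict(cf_model, o.rh, use_threshold) for o in observed])
        return CVResult.from_predictions(f"cf:{cf_model.provenance}", preds, obs)
    return loo_cv(
        observed,
        fit_fn=lambda tr: fit_cf(tr, form),
        predict_fn=lambda m, o: float(cf_predict(m, o.rh, use_threshold)),
        observe_fn=lambda o: o.cf,
        approach_id=f"cf:{form}:{'thr' if use_threshold else 'nothr'}",
    )


# ---------------------------------------------------------------------------
# the 21-approach comparison


_COMBINED_FORMS_BY_ROW = {1: "loglinear", 2: "loglinear_spline", 3: "loglinear_quadratic"}
_GRAV_FORM_BY_EQ = {"eq4": "loglog", "eq5": "loglog_spline", "eq6": "loglog_quadratic"}


def approach_specs() -> list[dict]:
    """The 21 approaches, numbered as in the published comparison: 1–3 the
    combined forms, 4–12 two-step without threshold, 13–21 with threshold
    (within each block, conversion eq 4/5/6 × humidity eq 1a/1b/2a)."""
    specs = [
        {"approach": i, "method": "combined", "combined_form": f,
         "humidity_eq": None, "threshold": None, "conversion": None}
        for i, f in _COMBINED_FORMS_BY_ROW.items()
    ]
    i = 4
    for threshold in (False, True):
        for conv in ("eq4", "eq5", "eq6"):
            for hum in ("1a", "1b", "2a"):
                specs.append(
                    {"approach": i, "method": "two_step", "combined_form": None,
                     "humidity_eq": hum, "threshold": threshold, "conversion": conv}
                )
                i += 1
    return specs


def _run_approach(spec: dict, samples, spline_grid) -> CVResult:
    if spec["method"] == "combined":
        return loo_cv_combined(
            samples, spec["combined_form"], spline_grid,
            approach_id=str(spec["approach"]),
        )
    cf_model = None
    cf_form = {"1a": "chakrabarti", "1b": "chakrabarti", "2a": "richards_log"}[spec["humidity_eq"]]
    if spec["humidity_eq"] == "1a":  # published parameters, never refit
        cf_model = published_cf_model("1a", with_threshold=spec["threshold"])
    return two_step_cv(
        samples,
        cf_form,
        use_threshold=spec["threshold"],
        grav_form=_GRAV_FORM_BY_EQ[spec["conversion"]],
        spline_grid=spline_grid,
        cf_model=cf_model,
        approach_id=str(spec["approach"]),
    )


def comparison_table(
    samples: Sequence[CoLocationSample],
    spline_grid=None,
    approaches: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, dict[int, CVResult]]:
    """Cross-validated RMSE for every adjustment approach.

    Returns the summary table (one row per approach, sorted by approach
    number) and the per-approach CVResult objects.  ``approaches`` limits
    the run to a subset of approach numbers."""
    usable = eligible_samples(samples)
    if len(usable) < 6:
        raise InputError("need at least 6 usable samples for the comparison table")
    rows, results = [], {}
    for spec in approach_specs():
        if approaches is not None and spec["approach"] not in approaches:
            continue
        res = _run_approach(spec, usable, spline_grid)
        results[spec["approach"]] = res
        rows.append(
            {
                "approach": spec["approach"],
                "method": spec["method"],
                "humidity_eq": spec["humidity_eq"] or "",
                "threshold": "" if spec["threshold"] is None else spec["threshold"],
                "conversion": spec["conversion"] or spec["combined_form"],
                "n_folds": res.n_folds,
                "cv_rmse_ugm3": res.rmse,
            }
        )
    df = pd.DataFrame(rows).sort_values("approach").reset_index(drop=True)
    return df, results


def insample_rmse_logmodel(predictions, observed) -> float:
    """Training (in-sample) RMSE on the original scale."""
    predictions = np.asarray(predictions, dtype=float)
    observed = np.asarray(observed, dtype=float)
    return float(np.sqrt(np.mean((predictions - observed) ** 2)))
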