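"""Synthetic co-location campaigns and instrument time series.

No field data ship with this package, so every stage of the pipeline is
exercised on synthetic campaigns with the statistical structure the
analysis assumes:

* a latent true concentration, log-uniform over the gravimetric range the
  calibration covers (~600–26,000 µg/m³), with RH drawn independently;
* a concentration-dependent "dry bias" power law for the nephelometer,
  ln(dry neph) = α + β·ln(true), with β > 1 so that the inverse log-log
  slope 1/β ≈ 0.71 matches the magnitude seen in field calibrations and
  makes the spline/quadratic conversion forms non-trivial;
* a multiplicative humidity correction factor CF(RH) applied to the dry
  nephelometer response;
* multiplicative lognormal noise.  By default the noise sits on the
  gravimetric reading (the response of every regression in the pipeline),
  which matches the ~12% duplicate precision of field filter samples and
  makes ordinary least squares the correct estimator for the generating
  parameters.  ``noise_on="neph"`` instead perturbs the nephelometer
  reading; note that this induces the classic errors-in-predictor
  attenuation when ln(grav) is regressed on ln(neph).
* lognormal noise is centred on the log scale (median-unbiased), matching
  the log-scale fits; ``mean_one_noise=True`` recentres it to mean 1 on
  the natural scale, which is the centring under which the linear-scale
  hygroscopic CF fit is unbiased.

Auxiliary generators produce data directly in the regression direction of
specific model forms (hinged calibration pairs, combined-model campaigns,
exactly two-step-compatible campaigns) for parameter- and knot-recovery
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .combined import CombinedModel
from .errors import ConfigError, InputError
from .humidity import CorrectionFactorModel, cf_predict
from .sample_io import CoLocationSample, NephTimeSeries, RHTimeSeries


def _default_cf_truth() -> CorrectionFactorModel:
    # the published log-linear CF fit from the cookstove campaign
    return CorrectionFactorModel(form="richards_log", a=-0.72, b=-0.82,
                                 provenance="published")


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic 65-pair co-location campaign.

    Defaults emulate the field campaign this package models: 65 pairs,
    gravimetric PM2.5 log-uniform over ~600–26,000 µg/m³, RH uniform over
    15–95%, a log-linear humidity CF with the published parameters, a dry
    calibration power law with β = 1.4 (inverse log-log slope 1/β ≈ 0.714)
    and α = −3.36 (inverse intercept −α/β = 2.4), and 0.3 SD lognormal
    noise — together placing nephelometric readings in the observed
    ~600–66,000 µg/m³ span.
    """

    seed: int
    n_samples: int = 65
    grav_range: tuple[float, float] = (600.0, 26000.0)
    rh_range: tuple[float, float] = (0.15, 0.95)
    cf_truth: CorrectionFactorModel = field(default_factory=_default_cf_truth)
    dry_alpha: float = -3.36
    dry_beta: float = 1.4
    noise_sigma: float = 0.3
    noise_on: str = "grav"  # "grav" | "neph"
    mean_one_noise: bool = False
    hinge_knot: float | None = None  # on the ln(gravimetric) scale
    hinge_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not (0 < self.grav_range[0] < self.grav_range[1]):
            raise ConfigError("invalid grav_range")
        if not (0 <= self.rh_range[0] < self.rh_range[1] < 1):
            raise ConfigError("invalid rh_range")
        if self.dry_beta <= 0:
            raise ConfigError("dry_beta must be > 0")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.noise_on not in ("grav", "neph"):
            raise ConfigError("noise_on must be 'grav' or 'neph'")


_FUELS = np.array(["wood", "crop_waste", "wood_mixed"])
_HOMES = np.array(["occupied", "mock"])
_WINDOW = np.array(["closed", "open"])


def generate_campaign(cfg: GeneratorConfig) -> list[CoLocationSample]:
    """Draw one synthetic co-location campaign.  Deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    lg = rng.uniform(np.log(cfg.grav_range[0]), np.log(cfg.grav_range[1]), cfg.n_samples)
    rh = rng.uniform(cfg.rh_range[0], cfg.rh_range[1], cfg.n_samples)
    ln_dry = cfg.dry_alpha + cfg.dry_beta * lg
    if cfg.hinge_knot is not None:
        ln_dry = ln_dry + cfg.hinge_coef * np.maximum(lg - cfg.hinge_knot, 0.0)
    cf = cf_predict(cfg.cf_truth, rh)
    eps = rng.normal(0.0, cfg.noise_sigma, cfg.n_samples) if cfg.noise_sigma > 0 else np.zeros(
        cfg.n_samples
    )
    if cfg.mean_one_noise:
        eps = eps - cfg.noise_sigma**2 / 2.0
    if cfg.noise_on == "grav":
        grav = np.exp(lg + eps)
        neph = np.exp(ln_dry) * cf
    else:
        grav = np.exp(lg)
        neph = np.exp(ln_dry) * cf * np.exp(eps)

    fuel = rng.choice(_FUELS, cfg.n_samples, p=[0.6, 0.2, 0.2])
    home = rng.choice(_HOMES, cfg.n_samples, p=[0.8, 0.2])
    window = rng.choice(_WINDOW, cfg.n_samples)
    kitchen = np.round(rng.uniform(12.0, 40.0, cfg.n_samples), 1)

    return [
        CoLocationSample(
            sample_id=f"S{i:03d}",
            neph_pm=float(neph[i]),
            grav_pm=float(grav[i]),
            rh=float(rh[i]),
            covariates={
                "fuel_type": str(fuel[i]),
                "home_type": str(home[i]),
                "window_door_status": str(window[i]),
                "kitchen_size": float(kitchen[i]),
            },
        )
        for i in range(cfg.n_samples)
    ]


def implied_combined_truth(cfg: GeneratorConfig) -> tuple[float, float, float]:
    """Combined-model coefficients implied by the generator algebra.

    Inverting ln(neph) = α + β·ln(grav) + a₂ + b₂·ln(1−RH) gives
    ln(grav) = −(α + a₂)/β − (b₂/β)·ln(1−RH) + (1/β)·ln(neph),
    so (c0, c1, c2) = (−(α + a₂)/β, −b₂/β, 1/β)."""
    if cfg.cf_truth.form != "richards_log":
        raise InputError("combined truth is only defined for a richards_log CF")
    if cfg.hinge_knot is not None:
        raise InputError("combined truth is only defined without a generator hinge")
    a2, b2 = cfg.cf_truth.a, cfg.cf_truth.b
    return (
        -(cfg.dry_alpha + a2) / cfg.dry_beta,
        -b2 / cfg.dry_beta,
        1.0 / cfg.dry_beta,
    )


def pure_humidity_config(cfg: GeneratorConfig) -> GeneratorConfig:
    """A copy of ``cfg`` with no concentration-dependent calibration bias
    (β = 1, α = 0), so the observed CF equals CF_truth × noise exactly —
    the conditions under which CF parameter recovery is identified."""
    return replace(cfg, dry_alpha=0.0, dry_beta=1.0)


# ---------------------------------------------------------------------------
# generators in specific regression directions


def generate_hinged_pairs(
    n: int,
    a: float,
    b: float,
    c: float,
    knot: float,
    ln_han_range: tuple[float, float] = (6.4, 11.1),
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(HAN, gravimetric) pairs from an exact hinge model on ln(HAN):
    ln(grav) = a + b·ln(han) + c·max(ln(han) − knot, 0) + ε."""
    rng = np.random.default_rng(seed)
    lh = rng.uniform(*ln_han_range, n)
    eps = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    lg = a + b * lh + c * np.maximum(lh - knot, 0.0) + eps
    return np.exp(lh), np.exp(lg)


def generate_from_combined(
    model: CombinedModel,
    n: int = 65,
    neph_range: tuple[float, float] = (600.0, 66000.0),
    rh_range: tuple[float, float] = (0.15, 0.95),
    sigma: float = 0.0,
    seed: int = 0,
) -> list[CoLocationSample]:
    """Campaign drawn exactly from a combined model (noise on ln grav)."""
    rng = np.random.default_rng(seed)
    ln_neph = rng.uniform(np.log(neph_range[0]), np.log(neph_range[1]), n)
    rh = rng.uniform(*rh_range, n)
    lp = model.c0 + model.c1 * np.log1p(-rh) + model.c2 * ln_neph
    if model.form == "loglinear_spline":
        lp = lp + model.c3 * np.maximum(ln_neph - model.knot, 0.0)
    elif model.form == "loglinear_quadratic":
        lp = lp + model.c3 * ln_neph**2
    eps = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    grav = np.exp(lp + eps)
    return [
        CoLocationSample(f"C{i:03d}", float(np.exp(ln_neph[i])), float(grav[i]), float(rh[i]))
        for i in range(n)
    ]


def generate_from_two_step(
    cf_model: CorrectionFactorModel,
    a: float,
    b: float,
    n: int = 65,
    grav_range: tuple[float, float] = (600.0, 26000.0),
    rh_range: tuple[float, float] = (0.15, 0.95),
    seed: int = 0,
) -> list[CoLocationSample]:
    """Noiseless campaign exactly consistent with the sequential model:
    ln(grav) = a + b·ln(HAN) with HAN = neph / CF(rh).

    With b = 1 the observed correction factor neph/grav depends on RH
    alone, so the CF regression and the conversion regression are both
    exactly specified simultaneously — the setting in which the one-step
    and two-step fits coincide."""
    rng = np.random.default_rng(seed)
    lg = rng.uniform(np.log(grav_range[0]), np.log(grav_range[1]), n)
    rh = rng.uniform(*rh_range, n)
    ln_han = (lg - a) / b
    neph = np.exp(ln_han) * cf_predict(cf_model, rh)
    return [
        CoLocationSample(f"T{i:03d}", float(neph[i]), float(np.exp(lg[i])), float(rh[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# instrument time series

_TAU_RISE_S = 240.0  # exponential rise time constant during a cooking event
_TAU_DECAY_S = 1200.0  # post-event decay back toward baseline
_TICK_S = 10.0


def generate_timeseries(
    duration_h: float,
    events: Sequence[tuple[float, float]] = ((30.0, 60.0),),
    baseline: float = 50.0,
    peak: float = 20000.0,
    rh_profile: float | Callable[[np.ndarray], np.ndarray] = 0.60,
    seed: int = 0,
    noise_sigma: float = 0.05,
    start: str = "2014-03-01T06:00:00",
    sample_id: str = "TS001",
) -> tuple[NephTimeSeries, RHTimeSeries]:
    """A day-style 10-second instrument record with cooking events.

    ``events`` are (start_min, end_min) windows; PM rises exponentially
    from baseline toward ``peak`` during an event and decays back after
    it.  ``rh_profile`` is a constant fraction or a callable of elapsed
    hours.  Deterministic given seed.
    """
    if duration_h <= 0:
        raise InputError("duration must be > 0")
    n = int(round(duration_h * 3600.0 / _TICK_S)) + 1  # inclusive ends
    t = np.arange(n) * _TICK_S

    ev = sorted((float(s), float(e)) for s, e in events)
    for (s0, e0), (s1, _) in zip(ev, ev[1:]):
        if s1 < e0:
            raise ConfigError(f"events overlap: ({s0}, {e0}) and starting {s1}")
    for s0, e0 in ev:
        if not (0 <= s0 < e0 <= duration_h * 60.0):
            raise ConfigError(f"event ({s0}, {e0}) outside the record")

    pm = np.full(n, float(baseline))
    amp = float(peak) - float(baseline)
    for s0, e0 in ev:
        t0, t1 = s0 * 60.0, e0 * 60.0
        during = (t >= t0) & (t <= t1)
        pm[during] += amp * (1.0 - np.exp(-(t[during] - t0) / _TAU_RISE_S))
        level_end = amp * (1.0 - np.exp(-(t1 - t0) / _TAU_RISE_S))
        after = t > t1
        pm[after] += level_end * np.exp(-(t[after] - t1) / _TAU_DECAY_S)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pm = pm * np.exp(rng.normal(0.0, noise_sigma, n))

    hours = t / 3600.0
    if callable(rh_profile):
        rh = np.asarray(rh_profile(hours), dtype=float) * np.ones(n)
    else:
        rh = np.full(n, float(rh_profile))
    rh = np.clip(rh, 0.0, 0.99)
    temp = 22.0 + 6.0 * np.sin(2.0 * np.pi * (hours - 8.0) / 24.0)

    ts = pd.date_range(pd.Timestamp(start), periods=n, freq="10s")
    return (
        NephTimeSeries(sample_id, ts, pm),
        RHTimeSeries(sample_id, ts, rh, temp),
    )
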