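"""Instrument-log ingest, alignment, and gravimetric sample processing.

The field setup pairs a passive nephelometer (10-second PM readings in
µg/m³) with a temperature/RH logger, plus a filter-based gravimetric
sampler that runs only during the active flame period of a cooking test.
This module reads those logs, aligns the two time series on nearest
timestamps, averages the nephelometric signal over the gravimetric
sampling window, computes filter concentrations with blank correction and
a limit-of-detection flag, and assembles the co-location table every
downstream model consumes.

Relative humidity is a fraction in [0, 0.99] everywhere downstream of
ingest.  Percent columns are detected and converted here, and values are
capped at 0.99 because the adjustment models involve ln(1 - RH).

CSV dialects
------------
nephelometer log : ``timestamp,pm_ugm3`` (ISO-8601 timestamps, one row per
    10-s tick)
RH log           : ``timestamp,temp_c,rh`` (``rh`` in percent or fraction,
    auto-detected: any value > 1.5 implies percent; a ``rh_pct`` column
    name forces percent)
co-location table: ``sample_id,neph_pm,grav_pm,rh,fuel_type,home_type,``
    ``window_door_status,kitchen_size,below_lod``
filter records   : ``filter_id,pre_ug,post_ug,blank_ug,flow_lpm,duration_min``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    InputError,
    WindowError,
)

logger = logging.getLogger(__name__)

RH_CAP = 0.99
DEFAULT_ALIGN_TOLERANCE_S = 5.0  # half the nominal 10-s logging interval

CAMPAIGN_COLUMNS = [
    "sample_id",
    "neph_pm",
    "grav_pm",
    "rh",
    "fuel_type",
    "home_type",
    "window_door_status",
    "kitchen_size",
    "below_lod",
]
COVARIATE_COLUMNS = ["fuel_type", "home_type", "window_door_status", "kitchen_size"]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class NephTimeSeries:
    """Nephelometer PM time series at nominal 10-second spacing."""

    sample_id: str
    timestamps: pd.DatetimeIndex
    pm: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.pm = np.asarray(self.pm, dtype=float)
        if len(self.timestamps) == 0:
            raise InputError(f"{self.sample_id}: empty PM series")
        if len(self.timestamps) != len(self.pm):
            raise InputError(f"{self.sample_id}: timestamp/pm length mismatch")
        if self.timestamps.has_duplicates or not self.timestamps.is_monotonic_increasing:
            raise FormatError(f"{self.sample_id}: timestamps not strictly increasing")
        if not np.all(np.isfinite(self.pm)):
            raise InputError(f"{self.sample_id}: non-finite PM values")

    def __len__(self) -> int:
        return len(self.pm)


@dataclass
class RHTimeSeries:
    """Relative-humidity (and optionally temperature) time series.

    ``rh`` is stored as a fraction in [0, RH_CAP]."""

    sample_id: str
    timestamps: pd.DatetimeIndex
    rh: np.ndarray
    temperature: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.rh = np.asarray(self.rh, dtype=float)
        if len(self.timestamps) == 0:
            raise InputError(f"{self.sample_id}: empty RH series")
        if len(self.timestamps) != len(self.rh):
            raise InputError(f"{self.sample_id}: timestamp/rh length mismatch")
        if self.timestamps.has_duplicates or not self.timestamps.is_monotonic_increasing:
            raise FormatError(f"{self.sample_id}: timestamps not strictly increasing")
        if np.any((self.rh < 0) | (self.rh >= 1.0)):
            raise InputError(f"{self.sample_id}: rh outside [0, 1) after ingest")
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)

    def __len__(self) -> int:
        return len(self.rh)


@dataclass
class FilterSample:
    """One gravimetric filter sample (weights in µg, flow in L/min)."""

    filter_id: str
    pre_weight: float
    post_weight: float
    duration: float
    blank_correction: float = 2.0
    flow_rate: float = 4.0
    lod: float = 5.0

    #: tolerance (µg) for post_weight < pre_weight before it is treated as
    #: a weighing error rather than an unexposed/negative-net filter
    WEIGHT_TOLERANCE = 5.0

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise InputError(f"{self.filter_id}: flow_rate must be > 0")
        if self.duration <= 0:
            raise InputError(f"{self.filter_id}: duration must be > 0")
        if self.post_weight < self.pre_weight - self.WEIGHT_TOLERANCE:
            raise InputError(
                f"{self.filter_id}: post weight below pre weight by more than "
                f"{self.WEIGHT_TOLERANCE} µg"
            )


@dataclass
class CoLocationSample:
    """One paired observation from the co-location campaign."""

    sample_id: str
    neph_pm: float
    grav_pm: float
    rh: float
    covariates: dict = field(default_factory=dict)
    below_lod: bool = False

    def __post_init__(self) -> None:
        if not self.neph_pm > 0:
            raise InputError(f"{self.sample_id}: neph_pm must be > 0")
        if not self.below_lod and not self.grav_pm > 0:
            raise InputError(f"{self.sample_id}: grav_pm must be > 0 unless below LOD")
        if not (0 <= self.rh < 1):
            raise InputError(f"{self.sample_id}: rh must be in [0, 1)")


def eligible_samples(
    samples: Sequence[CoLocationSample], include_below_lod: bool = False
) -> list[CoLocationSample]:
    """Samples usable for model fitting.  Below-LOD samples are excluded by
    default; pass include_below_lod=True to override."""
    if include_below_lod:
        return list(samples)
    return [s for s in samples if not s.below_lod]


# ---------------------------------------------------------------------------
# instrument logs


def read_neph_log(path: str | Path, sample_id: str) -> NephTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"timestamp", "pm_ugm3"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    pm = pd.to_numeric(df["pm_ugm3"], errors="coerce")
    keep = ts.notna() & pm.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d unparseable row(s)", sample_id, n_dropped)
    if keep.sum() == 0:
        raise InputError(f"{path}: no parseable rows")
    sub = pd.DataFrame({"ts": ts[keep], "pm": pm[keep]}).sort_values("ts")
    return NephTimeSeries(sample_id, pd.DatetimeIndex(sub["ts"]), sub["pm"].to_numpy())


def read_rh_log(path: str | Path, sample_id: str) -> RHTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    rh_col = "rh" if "rh" in df.columns else ("rh_pct" if "rh_pct" in df.columns else None)
    if rh_col is None or "timestamp" not in df.columns:
        raise FormatError(f"{path}: expected columns timestamp,[temp_c,]rh")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    rh = pd.to_numeric(df[rh_col], errors="coerce")
    keep = ts.notna() & rh.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d unparseable RH row(s)", sample_id, n_dropped)
    if keep.sum() == 0:
        raise InputError(f"{path}: no parseable rows")
    rh_vals = rh[keep].to_numpy(dtype=float)

    if rh_col == "rh_pct":
        if np.nanmax(rh_vals) <= 1.5:
            raise FormatError(
                f"{path}: column named rh_pct but values look fractional (max <= 1.5)"
            )
        rh_vals = rh_vals / 100.0
    elif np.nanmax(rh_vals) > 1.5:  # percent, auto-detected
        rh_vals = rh_vals / 100.0

    n_clamped = int(np.sum((rh_vals < 0) | (rh_vals > RH_CAP)))
    if n_clamped:
        logger.warning("%s: clamped %d RH value(s) into [0, %.2f]", sample_id, n_clamped, RH_CAP)
    rh_vals = np.clip(rh_vals, 0.0, RH_CAP)

    temp = None
    if "temp_c" in df.columns:
        temp = pd.to_numeric(df["temp_c"], errors="coerce")[keep].to_numpy(dtype=float)

    sub = pd.DataFrame({"ts": ts[keep].to_numpy(), "rh": rh_vals})
    if temp is not None:
        sub["temp_c"] = temp
    sub = sub.sort_values("ts")
    return RHTimeSeries(
        sample_id,
        pd.DatetimeIndex(sub["ts"]),
        sub["rh"].to_numpy(),
        sub["temp_c"].to_numpy() if temp is not None else None,
    )


def write_neph_log(series: NephTimeSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"), "pm_ugm3": series.pm}
    ).to_csv(path, index=False)


def write_rh_log(series: RHTimeSeries, path: str | Path) -> None:
    out = {"timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S")}
    out["temp_c"] = (
        series.temperature if series.temperature is not None else np.full(len(series), np.nan)
    )
    out["rh"] = series.rh  # fraction; max <= RH_CAP keeps auto-detection unambiguous
    pd.DataFrame(out).to_csv(path, index=False)


def align_series(
    neph: NephTimeSeries,
    rh: RHTimeSeries,
    tolerance: float = DEFAULT_ALIGN_TOLERANCE_S,
) -> pd.DataFrame:
    """Nearest-timestamp join of the two instrument series within
    ±tolerance seconds.  Returns columns timestamp, pm, rh (plus temp_c
    when the RH logger recorded temperature)."""
    left = pd.DataFrame({"timestamp": neph.timestamps, "pm": neph.pm})
    right = pd.DataFrame({"timestamp": rh.timestamps, "rh": rh.rh})
    if rh.temperature is not None:
        right["temp_c"] = rh.temperature
    merged = pd.merge_asof(
        left,
        right,
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(seconds=tolerance),
    )
    matched = merged.dropna(subset=["rh"]).reset_index(drop=True)
    n_dropped = len(merged) - len(matched)
    if n_dropped:
        logger.warning(
            "%s/%s: dropped %d row(s) with no RH match within ±%gs",
            neph.sample_id,
            rh.sample_id,
            n_dropped,
            tolerance,
        )
    if matched.empty:
        raise AlignmentError(
            f"{neph.sample_id}/{rh.sample_id}: no timestamps match within ±{tolerance}s"
        )
    return matched


def window_average(aligned: pd.DataFrame, start, end) -> tuple[float, float, int]:
    """Arithmetic means of pm and rh over rows with start <= t <= end
    (inclusive ends).  Returns (mean_pm, mean_rh, n_points)."""
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if not start < end:
        raise InputError("window start must precede end")
    mask = (aligned["timestamp"] >= start) & (aligned["timestamp"] <= end)
    n = int(mask.sum())
    if n == 0:
        raise WindowError(f"no data points in window [{start}, {end}]")
    sub = aligned.loc[mask]
    return float(sub["pm"].mean()), float(sub["rh"].mean()), n


# ---------------------------------------------------------------------------
# gravimetric filters


def gravimetric_concentration(f: FilterSample) -> tuple[float, bool]:
    """Blank-corrected filter concentration in µg/m³ and a below-LOD flag.

    net mass = post - pre - blank; sampled volume = flow × duration / 1000
    (m³).  A negative net mass is reported as 0 µg/m³ with below_lod True.
    """
    volume_m3 = f.flow_rate * f.duration / 1000.0
    if volume_m3 <= 0:
        raise InputError(f"{f.filter_id}: non-positive sampled volume")
    net_mass = f.post_weight - f.pre_weight - f.blank_correction
    if net_mass < 0:
        logger.warning("%s: negative net mass (%.1f µg); reporting 0", f.filter_id, net_mass)
        return 0.0, True
    return net_mass / volume_m3, bool(net_mass < f.lod)


def duplicate_precision(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Duplicate-sample precision: per pair |x1 - x2| / mean(x1, x2) × 100.

    Returns the mean over pairs and the SD (ddof=1) of the per-pair
    precision values; a single pair has SD 0."""
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise InputError("no duplicate pairs")
    arr = arr.reshape(-1, 2)
    if np.any(arr <= 0):
        raise InputError("duplicate concentrations must be > 0")
    prec = np.abs(arr[:, 0] - arr[:, 1]) / arr.mean(axis=1) * 100.0
    sd = float(prec.std(ddof=1)) if len(prec) > 1 else 0.0
    return float(prec.mean()), sd


def read_filter_records(path: str | Path) -> list[FilterSample]:
    df = pd.read_csv(path)
    required = {"filter_id", "pre_ug", "post_ug", "duration_min"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            FilterSample(
                filter_id=str(row.filter_id),
                pre_weight=float(row.pre_ug),
                post_weight=float(row.post_ug),
                duration=float(row.duration_min),
                blank_correction=float(getattr(row, "blank_ug", 2.0)),
                flow_rate=float(getattr(row, "flow_lpm", 4.0)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# co-location table


def campaign_frame(samples: Sequence[CoLocationSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "neph_pm": s.neph_pm,
            "grav_pm": s.grav_pm,
            "rh": s.rh,
            "below_lod": s.below_lod,
        }
        for c in COVARIATE_COLUMNS:
            row[c] = s.covariates.get(c, "")
        rows.append(row)
    return pd.DataFrame(rows, columns=CAMPAIGN_COLUMNS)


def write_campaign(samples: Sequence[CoLocationSample], path: str | Path) -> None:
    campaign_frame(samples).to_csv(path, index=False)


def read_campaign(path: str | Path) -> list[CoLocationSample]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"sample_id", "neph_pm", "grav_pm", "rh"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        cov = {}
        for c in COVARIATE_COLUMNS:
            v = getattr(row, c, None)
            if v is not None and not (isinstance(v, float) and np.isnan(v)) and v != "":
                cov[c] = v
        samples.append(
            CoLocationSample(
                sample_id=str(row.sample_id),
                neph_pm=float(row.neph_pm),
                grav_pm=float(row.grav_pm),
                rh=float(row.rh),
                covariates=cov,
                below_lod=bool(getattr(row, "below_lod", False)),
            )
        )
    return samples
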