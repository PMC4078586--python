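"""Apply the fitted one-step adjustment to a day-style instrument record.

Aligns the example nephelometer and RH logs, converts every 10-second
tick to gravimetric-equivalent PM2.5 with the combined model refit on the
campaign, and summarises the adjusted series (the published one-step
equation is applied alongside for comparison).
"""

import warnings
from pathlib import Path

import numpy as np

from nephqc import (
    RangeWarning,
    align_series,
    fit_combined,
    predict_combined,
    read_campaign,
    read_neph_log,
    read_rh_log,
)
from nephqc.gravimetric import APPLICABILITY_RANGE
from nephqc.presets import published_combined_eq7

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    warnings.simplefilter("ignore", RangeWarning)
    samples = read_campaign(OUT / "campaign.csv")
    model = fit_combined(samples, "loglinear")
    eq7 = published_combined_eq7()

    neph = read_neph_log(OUT / "logs" / "example_neph.csv", "example")
    rh = read_rh_log(OUT / "logs" / "example_rh.csv", "example")
    aligned = align_series(neph, rh)
    pm = np.maximum(aligned["pm"].to_numpy(), 1e-9)
    rh_vals = aligned["rh"].to_numpy()
    aligned["pm25_graveq_ugm3"] = predict_combined(model, pm, rh_vals)
    aligned["pm25_graveq_published_ugm3"] = predict_combined(eq7, pm, rh_vals)
    aligned["timestamp"] = aligned["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    aligned.to_csv(OUT / "adjusted_timeseries.csv", index=False, float_format="%.3f")

    lo, hi = APPLICABILITY_RANGE
    outside = np.mean((pm < lo) | (pm > hi)) * 100
    print(f"adjusted {len(aligned)} ticks -> {OUT / 'adjusted_timeseries.csv'}")
    print(
        f"  raw nephelometric: mean {pm.mean():8.0f}, max {pm.max():8.0f} µg/m³\n"
        f"  refit adjustment : mean {aligned['pm25_graveq_ugm3'].mean():8.0f}, "
        f"max {aligned['pm25_graveq_ugm3'].max():8.0f} µg/m³\n"
        f"  published eq     : mean {aligned['pm25_graveq_published_ugm3'].mean():8.0f}, "
        f"max {aligned['pm25_graveq_published_ugm3'].max():8.0f} µg/m³\n"
        f"  {outside:.1f}% of ticks outside the {lo:g}-{hi:g} µg/m³ applicability range"
    )


if __name__ == "__main__":
    main()
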