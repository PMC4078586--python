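"""Fit every gravimetric-equivalency conversion form on the campaign.

For each humidity adjustment (1a fixed, 1b and 2a refit; with and without
the 60% RH threshold) the nephelometric values are converted to HAN PM
and the four conversion forms are fit, recording coefficients and the
leave-one-out CV RMSE on the original µg/m³ scale — the analogue of the
published conversion-parameter summary.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from nephqc import RangeWarning, adjust_pm, fit_cf, fit_gravimetric, observed_cf, read_campaign
from nephqc.model_selection import loo_cv_gravimetric
from nephqc.presets import published_cf_model

OUT = Path(__file__).resolve().parents[1] / "results"
FORMS = ["linear_origin", "loglog", "loglog_spline", "loglog_quadratic"]


def main() -> None:
    warnings.simplefilter("ignore", RangeWarning)
    samples = read_campaign(OUT / "campaign.csv")
    cfs = [observed_cf(s) for s in samples]
    rh = np.array([s.rh for s in samples])
    neph = np.array([s.neph_pm for s in samples])
    grav = np.array([s.grav_pm for s in samples])

    cf_models = {
        "1a": published_cf_model("1a"),
        "1b": fit_cf(cfs, "chakrabarti"),
        "2a": fit_cf(cfs, "richards_log"),
    }
    rows = []
    for eq, m_cf in cf_models.items():
        for thr in (True, False):
            han = adjust_pm(neph, rh, m_cf, use_threshold=thr)
            for form in FORMS:
                m = fit_gravimetric(han, grav, form)
                cv = loo_cv_gravimetric(han, grav, form)
                rows.append(
                    {
                        "humidity_eq": eq,
                        "threshold": thr,
                        "form": form,
                        "a": m.a,
                        "b": m.b,
                        "c": m.c,
                        "d": m.d,
                        "cv_rmse_ugm3": cv.rmse,
                    }
                )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "gravimetric_models.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"-> {OUT / 'gravimetric_models.csv'}")
    best = table.loc[table["cv_rmse_ugm3"].idxmin()]
    print(
        f"best conversion: {best['form']} under eq {best['humidity_eq']} "
        f"({'with' if best['threshold'] else 'without'} threshold), "
        f"CV RMSE {best['cv_rmse_ugm3']:.0f} µg/m³"
    )


if __name__ == "__main__":
    main()
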