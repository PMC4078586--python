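"""Fit the humidity correction-factor models on the campaign.

Reproduces the structure of the humidity-model summary: the published
hygroscopic equation with fixed parameters (1a), the same form refit on
the campaign (1b), and the log-linear form refit on the campaign (2a) —
each scored on the dimensionless CF scale with and without the 60% RH
threshold (plain residual RMSE for the fixed model, leave-one-out CV for
the refit models).
"""

from pathlib import Path

import pandas as pd

from nephqc import fit_cf, observed_cf, read_campaign
from nephqc.model_selection import cf_model_rmse
from nephqc.presets import published_cf_model
from nephqc.serialize import save_model

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = read_campaign(OUT / "campaign.csv")
    cfs = [observed_cf(s) for s in samples]

    m_1b = fit_cf(cfs, "chakrabarti")
    m_2a = fit_cf(cfs, "richards_log")
    save_model(m_1b, OUT / "humidity_1b.json")
    save_model(m_2a, OUT / "humidity_2a.json")

    rows = []
    for eq, model, form in [
        ("1a", published_cf_model("1a"), None),
        ("1b", None, "chakrabarti"),
        ("2a", None, "richards_log"),
    ]:
        fitted = model or {"1b": m_1b, "2a": m_2a}[eq]
        row = {
            "equation": eq,
            "a": fitted.a,
            "b": fitted.b,
            "ci_a": fitted.ci_a,
            "ci_b": fitted.ci_b,
        }
        for thr in (True, False):
            res = cf_model_rmse(cfs, form=form, use_threshold=thr, cf_model=model)
            row[f"rmse_{'with' if thr else 'without'}_threshold"] = res.rmse
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "humidity_models.csv", index=False)
    print(table.to_string(index=False))
    print(f"-> {OUT / 'humidity_models.csv'}")
    better = table.loc[table["rmse_without_threshold"].idxmin(), "equation"]
    print(f"best CF fit without threshold: equation {better}")


if __name__ == "__main__":
    main()
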