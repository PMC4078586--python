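"""The 21-approach cross-validated comparison.

Scores the 3 one-step combined forms and all 18 two-step combinations by
exhaustive leave-one-out CV RMSE on the original scale, writes the table,
and names the winner.
"""

import warnings
from pathlib import Path

from nephqc import RangeWarning, comparison_table, read_campaign

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    warnings.simplefilter("ignore", RangeWarning)
    samples = read_campaign(OUT / "campaign.csv")
    table, _ = comparison_table(samples)
    table.to_csv(OUT / "approach_comparison.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    best = table.loc[table["cv_rmse_ugm3"].idxmin()]
    combined_best = table[table["method"] == "combined"]["cv_rmse_ugm3"].min()
    print(f"-> {OUT / 'approach_comparison.csv'}")
    print(
        f"minimum CV RMSE: approach {int(best['approach'])} "
        f"({best['method']}, {best['conversion']}, humidity {best['humidity_eq'] or '-'}) "
        f"at {best['cv_rmse_ugm3']:.0f} µg/m³"
    )
    print(f"best one-step combined approach: {combined_best:.0f} µg/m³")


if __name__ == "__main__":
    main()
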