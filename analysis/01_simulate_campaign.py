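"""Generate the synthetic co-location campaign used by the later stages.

Draws 65 paired nephelometer/gravimetric samples at the default study
conditions (gravimetric ~600-26,000 µg/m³ log-uniform, RH 15-95%,
log-linear humidity CF, dry-bias power law beta = 1.4, sigma = 0.3
lognormal noise) and writes the campaign table plus one example pair of
10-second instrument logs.
"""

from pathlib import Path

import numpy as np

from nephqc import GeneratorConfig, generate_campaign, write_campaign
from nephqc.sample_io import write_neph_log, write_rh_log
from nephqc.synthetic import generate_timeseries

SEED = 17
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = GeneratorConfig(seed=SEED)
    samples = generate_campaign(cfg)
    write_campaign(samples, OUT / "campaign.csv")

    neph = np.array([s.neph_pm for s in samples])
    grav = np.array([s.grav_pm for s in samples])
    rh = np.array([s.rh for s in samples])
    print(f"campaign: {len(samples)} pairs -> {OUT / 'campaign.csv'}")
    print(f"  nephelometric PM: {neph.min():8.0f} - {neph.max():8.0f} µg/m³")
    print(f"  gravimetric PM  : {grav.min():8.0f} - {grav.max():8.0f} µg/m³")
    print(f"  RH              : {rh.min()*100:5.1f} - {rh.max()*100:5.1f} %")

    ts_neph, ts_rh = generate_timeseries(
        duration_h=1.5,
        events=((20.0, 50.0),),
        baseline=50.0,
        peak=20000.0,
        rh_profile=lambda h: 0.55 + 0.2 * np.sin(2 * np.pi * h / 24.0),
        seed=SEED,
    )
    logdir = OUT / "logs"
    logdir.mkdir(exist_ok=True)
    write_neph_log(ts_neph, logdir / "example_neph.csv")
    write_rh_log(ts_rh, logdir / "example_rh.csv")
    print(f"example instrument logs ({len(ts_neph)} ticks) -> {logdir}")


if __name__ == "__main__":
    main()
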