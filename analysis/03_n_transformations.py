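#!/usr/bin/env python
"""Gross and net N transformation rates from simulated pool-dilution and
two-point extraction data.

Simulates ¹⁵N pool-dilution pairs under per-surface gross rates (4 h and
24 h extractions), estimates gross mineralization with the pool-dilution
equations, derives net rates from the same pools, and writes
results/n_rates.csv. Surfaces with strong immobilization show the
method's real failure mode: enrichment rising instead of diluting marks
the gross rate non-determinable."""

from pathlib import Path

import numpy as np
import pandas as pd

from thawnitro.ntrans import gross_rates_kb, net_rates
from thawnitro.synthetic import sim_pool_dilution

SEED = 42
RESULTS = Path(__file__).resolve().parents[1] / "results"

# generating gross rates (mg N kg-1 DW d-1): production, consumption
SCENARIOS = {
    "vegetated_holocene": (0.8, 0.6),
    "bare_fresh_yedoma": (0.3, 0.25),
    "yedoma_moss": (1.5, 1.0),
    "yedoma_grass": (2.5, 1.5),
}
DT = 1.0 - 4.0 / 24.0  # 4 h -> 24 h


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    rows = []
    for surface, (p, c) in SCENARIOS.items():
        for rep in range(5):
            m0 = rng.uniform(3.0, 8.0)
            pair = sim_pool_dilution(p, c, M0=m0, APE0=9.0, dt=DT)
            gross = gross_rates_kb(pair)
            # net rates from the same NH4 pool plus a static NO3 pool
            no3 = rng.uniform(0.5, 2.0)
            net = net_rates(pair.M0, no3, pair.Mt, no3, pair.t0, pair.t1)
            rows.append(
                dict(surface_class=surface, replicate=rep,
                     gross_production=gross.production, gross_consumption=gross.consumption,
                     determinable=gross.determinable,
                     net_mineralization=net.net_mineralization,
                     net_ammonification=net.net_ammonification,
                     net_nitrification=net.net_nitrification,
                     true_production=p, true_consumption=c)
            )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "n_rates.csv", index=False)
    ok = df[df["determinable"]]
    err = np.max(np.abs(ok["gross_production"] - ok["true_production"]) / ok["true_production"])
    print(f"{len(df)} samples; worst gross-production recovery error "
          f"{100 * err:.2e} % (estimator exact under constant rates)")
    print(df.groupby("surface_class")[["gross_production", "net_mineralization"]]
            .mean().round(3).to_string())
    print(f"-> {RESULTS / 'n_rates.csv'}")


if __name__ == "__main__":
    main()
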