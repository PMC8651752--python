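#!/usr/bin/env python
"""Thermal-erosion geometry on a synthetic cliff scene, then the thaw-front
N-mobilization and N₂O emission-factor budget on the measured constants.

Part 1 writes a DEM pair and dated cliff polylines to disk (ESRI ASCII +
vertex CSVs), reads them back, and recovers the generating retreat and
eroded volume — the full file-format round trip of the geometry stage.
Part 2 runs the budget chain: eroded volume 223,502 m³ over 7 years along
a 1,700 m section retreating at 3.7 m yr⁻¹; 82 vol-% ground ice, bulk
density 1,220 kg m⁻³, total N 0.16%, mineral N 35.3 mg kg⁻¹; the median
flux of the revegetated grass surfaces (548 μg N m⁻² d⁻¹) over a 100-day
snow-free season. Writes results/erosion_budget.json."""

import json
from pathlib import Path

from thawnitro.erosion import (
    annual_volume_per_area,
    dem_volume,
    emission_budget,
    n_mobilization,
    read_ascii_grid,
    read_polylines_csv,
    transect_retreat,
    write_ascii_grid,
    write_polylines_csv,
)
from thawnitro.synthetic import sim_dem_pair

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def geometry_roundtrip() -> None:
    scene = sim_dem_pair(nx=100, ny=200, cell_size=2.0, cliff_height=20.0,
                         retreat=10.0, epoch_years=2.0)
    SCRATCH.mkdir(exist_ok=True)
    write_ascii_grid(SCRATCH / "dem_old.asc", scene.dem_old, cellsize=scene.cell_size)
    write_ascii_grid(SCRATCH / "dem_new.asc", scene.dem_new, cellsize=scene.cell_size)
    write_polylines_csv(SCRATCH / "cliff_boundaries.csv", scene.cliff_boundaries)

    old, hdr = read_ascii_grid(SCRATCH / "dem_old.asc")
    new, _ = read_ascii_grid(SCRATCH / "dem_new.asc")
    scene.cliff_boundaries = read_polylines_csv(SCRATCH / "cliff_boundaries.csv")
    vol = dem_volume(old, new, hdr["cellsize"])
    stats = transect_retreat(scene, spacing=10.0)
    print("synthetic scene (from files on disk):")
    print(f"  retreat rate median {stats.median:.2f} m/yr over {stats.n_transects} transects "
          f"(truth {scene.true_retreat / scene.epoch_years:.2f})")
    print(f"  eroded volume {vol:,.0f} m3 (analytic truth {scene.true_volume:,.0f})")


def budget() -> dict:
    ava = annual_volume_per_area(223_502.0, 7.0, 3.7, 1700.0)
    mob = n_mobilization(ava, ice_fraction=0.82, bulk_density=1220.0,
                         total_n_frac=0.0016, mineral_n_content=35.3)
    emis = emission_budget(548.0, 100.0, mob.mineral_n_release)
    out = {
        "annual_volume_per_area_m3_m2_yr": round(ava, 3),
        "sediment_mass_kg_m2_yr": round(mob.sediment_mass, 1),
        "total_n_release_kg_m2_yr": round(mob.total_n_release, 3),
        "mineral_n_release_g_m2_yr": round(mob.mineral_n_release, 2),
        "seasonal_n2o_loss_mg_m2": round(emis.seasonal_loss, 2),
        "emission_factor_pct": round(emis.emission_factor, 4),
        "fold_below_ipcc_1pct": round(emis.fold_below_ipcc, 2),
    }
    print("\nthaw-front N budget:")
    for k, v in out.items():
        print(f"  {k}: {v}")
    return out


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    geometry_roundtrip()
    out = budget()
    (RESULTS / "erosion_budget.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"-> {RESULTS / 'erosion_budget.json'}")


if __name__ == "__main__":
    main()
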