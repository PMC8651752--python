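"""Synthetic data generators emulating the field and laboratory measurements.

Every analysis stage in the package has a generator here that produces
inputs with the statistical structure the stage assumes, with known ground
truth, so the whole pipeline is testable without field data:

* chamber headspace series — linear accumulation from a prescribed flux
  plus i.i.d. Gaussian analytical noise on the mixing ratios;
* ¹⁵N pool-dilution pairs — the constant-gross-rate model solved exactly;
* incubation series — linear production with an optional consumption
  (decline) or steady-state (plateau) phase after an onset day;
* DEM pairs — a plateau–cliff–shore scene whose cliff foot moves inland by
  a known retreat, with the analytic eroded volume and dated boundary
  polylines recorded;
* gene count tables — multinomial draws around prescribed relative
  abundances;
* surface property/flux tables — draws within per-surface-class ranges
  from the packaged profile file.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chamber import ChamberSeries
from .erosion import ErosionScene
from .incubation import DEFAULT_SAMPLING_DAYS, IncubationSeries
from .ntrans import PoolDilutionPair
from .units import AMBIENT_N2O_PPM, flux_to_slope

__all__ = [
    "SurfaceProfile",
    "SimulationConfig",
    "load_surface_profiles",
    "sim_chamber_series",
    "sim_pool_dilution",
    "sim_incubation_series",
    "sim_dem_pair",
    "sim_gene_counts",
    "sim_surface_table",
]

DEFAULT_CHAMBER_TIMES = (0.0, 12.5, 25.0, 37.5, 50.0)  # minutes


@dataclass
class SurfaceProfile:
    """Per-surface-class ranges used by :func:`sim_surface_table`."""

    surface_class: str
    wfps_range: tuple[float, float]
    no3_range: tuple[float, float]  # mg N kg-1 DW
    nh4_range: tuple[float, float]  # mg N kg-1 DW
    cn_ratio: float
    flux_median: float  # μg N m-2 d-1
    flux_range: tuple[float, float]
    assumed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("wfps_range", "no3_range", "nh4_range", "flux_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (low <= high)")
        if not (0 <= self.wfps_range[0] and self.wfps_range[1] <= 1):
            raise ValueError("wfps_range bounds must lie in [0, 1]")
        if not self.flux_range[0] <= self.flux_median <= self.flux_range[1]:
            raise ValueError("flux_median must lie within flux_range")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_replicates: int = 5
    noise_sd: float = 0.0
    sampling_times: Sequence[float] = DEFAULT_CHAMBER_TIMES

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if np.any(np.diff(np.asarray(self.sampling_times)) <= 0):
            raise ValueError("sampling_times must be strictly increasing")


def load_surface_profiles() -> dict[str, SurfaceProfile]:
    """The packaged surface-class profiles (printed values; gaps marked assumed)."""
    text = resources.files("thawnitro").joinpath("data/surface_profiles.json").read_text()
    raw = json.loads(text)
    out = {}
    for name, spec in raw.items():
        if name.startswith("_"):
            continue
        out[name] = SurfaceProfile(
            surface_class=name,
            wfps_range=tuple(spec["wfps_range"]),
            no3_range=tuple(spec["no3_range"]),
            nh4_range=tuple(spec["nh4_range"]),
            cn_ratio=spec["cn_ratio"],
            flux_median=spec["flux_median"],
            flux_range=tuple(spec["flux_range"]),
            assumed=tuple(spec.get("assumed", ())),
        )
    return out


# ---------------------------------------------------------------------------
# Chamber series

def sim_chamber_series(
    true_flux: float,
    chamber_height: float = 0.15,
    air_temp: float = 283.15,
    pressure: float = 101325.0,
    times: Sequence[float] = DEFAULT_CHAMBER_TIMES,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    ambient: float = AMBIENT_N2O_PPM,
    analyte: str = "N2O",
    standard_sd: float = 0.003,
) -> ChamberSeries:
    """Headspace series accumulating linearly from ``true_flux``.

    The slope is the exact inversion of the flux unit conversion, so a
    noise-free series fed back through the flux computation recovers
    ``true_flux`` to floating point. Gaussian noise of SD ``noise_sd``
    (ppm) is added independently per sample, modeling GC analytical error.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    slope = flux_to_slope(true_flux, chamber_height, air_temp, pressure, analyte)
    conc = ambient + slope * times
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        conc = conc + rng.normal(0.0, noise_sd, size=times.size)
    return ChamberSeries(
        times=times,
        mixing_ratios=conc,
        analyte=analyte,
        chamber_height=chamber_height,
        air_temp=air_temp,
        pressure=pressure,
        standard_sd=standard_sd,
    )


# ---------------------------------------------------------------------------
# Pool dilution

def sim_pool_dilution(
    gross_production: float,
    gross_consumption: float,
    M0: float,
    APE0: float,
    dt: float = 1.0 - 4.0 / 24.0,
    t0: float = 4.0 / 24.0,
    target_pool: str = "NH4",
) -> PoolDilutionPair:
    """Exact pool sizes and enrichment after ``dt`` days of constant gross rates.

    Model: dM/dt = p − c; dH/dt = −c·H/M with H the ¹⁵N excess mass
    (APE = 100·H/M). Closed forms:

    * p ≠ c:  M(t) = M0 + (p−c)t,  H(t) = H0·(M/M0)^(−c/(p−c))
    * p = c:  M(t) = M0,           H(t) = H0·exp(−c·t/M0)
    """
    if M0 <= 0 or APE0 <= 0:
        raise ValueError("M0 and APE0 must be positive")
    if gross_production < 0 or gross_consumption < 0:
        raise ValueError("gross rates must be non-negative")
    p, c = gross_production, gross_consumption
    net = p - c
    Mt = M0 + net * dt
    if Mt <= 0:
        raise ValueError("parameters drive the pool non-positive within dt")
    H0 = APE0 / 100.0 * M0
    if net == 0:
        Ht = H0 * math.exp(-c * dt / M0)
    else:
        Ht = H0 * (Mt / M0) ** (-c / net)
    APEt = 100.0 * Ht / Mt
    return PoolDilutionPair(M0=M0, Mt=Mt, APE0=APE0, APEt=APEt, t0=t0, t1=t0 + dt, target_pool=target_pool)


# ---------------------------------------------------------------------------
# Incubation series

def sim_incubation_series(
    production_rate: float,
    consumption_onset: Optional[float] = None,
    times: Sequence[float] = DEFAULT_SAMPLING_DAYS,
    soil_dw: float = 0.02,
    seed: Optional[int] = None,
    noise_sd: float = 0.0,
    post_onset: str = "decline",
    decline_rate: Optional[float] = None,
    treatment: str = "anoxic",
    amendment: str = "none",
) -> IncubationSeries:
    """Headspace N₂O amount rising linearly, then declining or plateauing.

    ``production_rate`` is μg N kg⁻¹ DW d⁻¹; until ``consumption_onset``
    (days; None = never) the flask accumulates at that rate, after which
    the amount declines at ``decline_rate`` (default: half the production
    rate; the net-consumption behavior of plain anoxic flasks) or stays
    flat (``post_onset="plateau"``, the acetylene steady state).
    """
    if soil_dw <= 0:
        raise ValueError("soil_dw must be positive")
    if post_onset not in ("decline", "plateau"):
        raise ValueError("post_onset must be 'decline' or 'plateau'")
    times = np.asarray(times, dtype=float)
    per_flask = production_rate * soil_dw  # μg N d-1
    if consumption_onset is None:
        amounts = per_flask * times
    else:
        dec = (production_rate / 2.0 if decline_rate is None else decline_rate) * soil_dw
        peak = per_flask * consumption_onset
        amounts = np.where(
            times <= consumption_onset,
            per_flask * times,
            peak if post_onset == "plateau" else np.maximum(0.0, peak - dec * (times - consumption_onset)),
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        amounts = amounts + rng.normal(0.0, noise_sd, size=times.size)
    return IncubationSeries(
        times=times,
        headspace_n2o=amounts,
        soil_dw=soil_dw,
        treatment=treatment,
        amendment=amendment,
    )


# ---------------------------------------------------------------------------
# DEM pair

def sim_dem_pair(
    nx: int,
    ny: int,
    cell_size: float,
    cliff_height: float,
    retreat: float,
    seed: Optional[int] = None,
    cliff_foot_frac: float = 0.4,
    epoch_years: float = 1.0,
    noise_sd: float = 0.0,
) -> ErosionScene:
    """Plateau–cliff–shore DEM pair whose cliff foot moves inland by ``retreat``.

    The grid has the shore at low y and the plateau (elevation
    ``cliff_height``) at high y, separated by a vertical cliff whose foot
    sits at ``cliff_foot_frac`` of the y-extent in the old DEM and
    ``retreat`` metres further inland in the new one. The analytic eroded
    volume (retreat × cliff length × cliff height) and the generating
    retreat are recorded on the scene for recovery tests, along with the
    dated cliff-boundary polylines and the shoreline baseline.
    """
    if cliff_height <= 0:
        raise ValueError("cliff_height must be positive")
    extent_y = ny * cell_size
    foot_old = cliff_foot_frac * extent_y
    foot_new = foot_old + retreat
    if retreat < 0 or foot_new >= extent_y:
        raise ValueError("retreat must be non-negative and keep the cliff inside the domain")

    # cell-center y, row 0 northernmost (inland)
    y_centers = (extent_y - (np.arange(ny) + 0.5) * cell_size)[:, None] * np.ones((1, nx))
    dem_old = np.where(y_centers >= foot_old, cliff_height, 0.0)
    dem_new = np.where(y_centers >= foot_new, cliff_height, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dem_old = dem_old + rng.normal(0.0, noise_sd, dem_old.shape)
        dem_new = dem_new + rng.normal(0.0, noise_sd, dem_new.shape)

    length = nx * cell_size
    shoreline = np.array([[0.0, 0.0], [length, 0.0]])
    boundaries = {
        0.0: np.array([[0.0, foot_old], [length, foot_old]]),
        float(epoch_years): np.array([[0.0, foot_new], [length, foot_new]]),
    }
    return ErosionScene(
        dem_old=dem_old,
        dem_new=dem_new,
        cell_size=cell_size,
        shoreline=shoreline,
        cliff_boundaries=boundaries,
        section_length=length,
        epoch_years=epoch_years,
        true_volume=retreat * length * cliff_height,
        true_retreat=retreat,
    )


# ---------------------------------------------------------------------------
# Gene counts

def sim_gene_counts(
    profile: Mapping[str, float],
    total_reads: int,
    seed: Optional[int] = None,
    n_samples: int = 1,
) -> pd.DataFrame:
    """Multinomial gene count table with expected relative abundances ``profile``.

    ``profile`` maps gene family → percent of all captured sequences; the
    remainder (to 100%) is assigned to an ``other`` column.
    """
    genes = list(profile)
    probs = np.array([profile[g] for g in genes], dtype=float)
    if np.any(probs < 0):
        raise ValueError("profile percentages must be non-negative")
    total_pct = probs.sum()
    if total_pct > 100.0 + 1e-9:
        raise ValueError("profile percentages must sum to at most 100")
    cols = genes + (["other"] if "other" not in genes else [])
    if "other" not in genes:
        probs = np.append(probs, 100.0 - total_pct)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_reads, probs / probs.sum(), size=n_samples)
    return pd.DataFrame(counts, columns=cols)


# ---------------------------------------------------------------------------
# Surface property / flux tables

def _half_interval_draw(rng: np.random.Generator, lo: float, med: float, hi: float, n: int) -> np.ndarray:
    """Draw with exact median ``med``: half the mass in [lo, med], half in
    [med, hi]; log-uniform within a half when its endpoints are positive,
    uniform otherwise (fluxes can be negative: uptake)."""
    sides = rng.random(n) < 0.5
    out = np.empty(n)
    for mask, a, b in ((sides, lo, med), (~sides, med, hi)):
        k = int(mask.sum())
        if a > 0 and b > 0:
            out[mask] = np.exp(rng.uniform(np.log(a), np.log(b), k))
        else:
            out[mask] = rng.uniform(a, b, k)
    return out


def sim_surface_table(profile: SurfaceProfile, n: int, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw ``n`` plots of soil moisture, mineral N and N₂O flux for one class.

    WFPS and mineral N are uniform within the profile ranges; fluxes are
    drawn log-uniformly within each half-range around the class median, so
    the population median equals ``flux_median`` while spanning the full
    printed range (field fluxes are strongly right-skewed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "surface_class": profile.surface_class,
            "wfps": rng.uniform(*profile.wfps_range, n),
            "no3": rng.uniform(*profile.no3_range, n),
            "nh4": rng.uniform(*profile.nh4_range, n),
            "cn": profile.cn_ratio,
            "flux": _half_interval_draw(
                rng, profile.flux_range[0], profile.flux_median, profile.flux_range[1], n
            ),
        }
    )
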