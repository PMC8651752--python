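"""Thermal-erosion geometry and the permafrost N-mobilization budget.

Three stages:

1. **Cliff retreat** from dated cliff-boundary polylines: transects are
   cast perpendicular to a shoreline baseline at fixed spacing; per
   transect, the distance from the baseline to the nearest intersection
   with each dated cliff line is measured, and the retreat rate is the
   change in that distance divided by the elapsed years. The median and
   quartiles over transects summarize the section.
2. **Eroded volume** from DEM differencing: positive elevation loss
   (old − new) summed over cells × cell area; positive values mean
   subsidence due to thaw and erosion.
3. **N mobilization and emission factor**: the annually eroded volume per
   unit of annually eroded footprint, reduced by the ground-ice fraction,
   converted to sediment mass with the bulk density and then to total and
   mineral N with the measured N contents; the seasonal N₂O loss over a
   100-day snow-free season divided by the liberated mineral N gives the
   emission factor, compared against the IPCC default of 1%.

Grids are planar metric (projected coordinates); DEMs are read and written
as ESRI ASCII grids, polylines as ordered x,y vertex CSVs with a date column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_polylines_csv",
    "write_polylines_csv",
    "ErosionScene",
    "RetreatStats",
    "NMobilizationBudget",
    "EmissionBudget",
    "transect_retreat",
    "dem_volume",
    "annual_volume_per_area",
    "n_mobilization",
    "emission_budget",
]


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (6-line header + row-major elevations, north up)

def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header dict).

    NODATA cells are returned as NaN. The array is row-major with the first
    row being the northernmost (as stored in the file).
    """
    path = Path(path)
    header: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines[:6]:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            key = parts[0].lower()
            header[key] = float(parts[1]) if "." in parts[1] or "e" in parts[1].lower() or key not in ("ncols", "nrows") else int(parts[1])
            n_header += 1
        else:
            break
    header["ncols"] = int(header["ncols"])
    header["nrows"] = int(header["nrows"])
    header.setdefault("nodata_value", -9999.0)
    arr = np.loadtxt(lines[n_header:], dtype=float)
    arr = arr.reshape(header["nrows"], header["ncols"])
    arr[arr == header["nodata_value"]] = np.nan
    return arr, header


def write_ascii_grid(
    path: str | Path,
    arr: np.ndarray,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
    nodata_value: float = -9999.0,
) -> None:
    """Write an array as an ESRI ASCII grid (NaN → NODATA)."""
    arr = np.asarray(arr, dtype=float)
    out = np.where(np.isnan(arr), nodata_value, arr)
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata_value}\n")
        np.savetxt(fh, out, fmt="%.4f")


def read_polylines_csv(path: str | Path) -> dict[float, np.ndarray]:
    """Read dated polylines from a CSV of ordered vertices (columns: date, x, y)."""
    df = pd.read_csv(path)
    return {float(d): g[["x", "y"]].to_numpy() for d, g in df.groupby("date", sort=True)}


def write_polylines_csv(path: str | Path, lines: Mapping[float, np.ndarray]) -> None:
    frames = [
        pd.DataFrame({"date": d, "x": np.asarray(v)[:, 0], "y": np.asarray(v)[:, 1]})
        for d, v in lines.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scene container

@dataclass
class ErosionScene:
    """Co-registered DEM pair plus the digitized shoreline and dated cliff lines."""

    dem_old: np.ndarray
    dem_new: np.ndarray
    cell_size: float
    shoreline: np.ndarray  # (n, 2) baseline vertices
    cliff_boundaries: dict[float, np.ndarray] = field(default_factory=dict)  # date (yr) -> vertices
    section_length: Optional[float] = None  # m
    epoch_years: float = 1.0
    true_volume: Optional[float] = None  # analytic volume for synthetic scenes
    true_retreat: Optional[float] = None  # generating retreat for synthetic scenes

    def __post_init__(self) -> None:
        if self.dem_old.shape != self.dem_new.shape:
            raise ValueError("DEMs must be co-registered (same shape)")
        if self.epoch_years <= 0:
            raise ValueError("epoch_years must be positive")


@dataclass
class RetreatStats:
    per_transect_rates: np.ndarray  # m yr-1
    median: float
    q25: float
    q75: float
    n_transects: int
    n_dropped: int = 0  # transects failing to intersect both dated lines


# ---------------------------------------------------------------------------
# Transect retreat

def _as_linestring(vertices: np.ndarray) -> LineString:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
        raise ValueError("polyline needs >= 2 (x, y) vertices")
    return LineString(v)


def _nearest_intersection_distance(
    station: Point, normal: np.ndarray, target: LineString, reach: float
) -> Optional[float]:
    """Distance from station to the nearest crossing of the transect with target.

    The transect is cast along ±normal over ``reach``; when it crosses a
    sinuous cliff line more than once the nearest crossing is used.
    """
    a = Point(station.x - reach * normal[0], station.y - reach * normal[1])
    b = Point(station.x + reach * normal[0], station.y + reach * normal[1])
    inter = LineString([a, b]).intersection(target)
    if inter.is_empty:
        return None
    pts: list[Point] = []
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        if isinstance(g, Point):
            pts.append(g)
        else:  # collinear overlap: use its endpoints
            pts.extend(Point(c) for c in g.coords)
    return min(station.distance(p) for p in pts)


def transect_retreat(
    scene: ErosionScene,
    spacing: float = 10.0,
    date_pair: Optional[tuple[float, float]] = None,
) -> RetreatStats:
    """Cliff retreat statistics from transects cast off the shoreline baseline.

    Parameters
    ----------
    scene
        Provides the shoreline (baseline) and ≥2 dated cliff boundaries.
    spacing
        Along-baseline distance between transect stations, m.
    date_pair
        The two dates (years) to difference; defaults to (earliest, latest).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if len(scene.cliff_boundaries) < 2 and date_pair is None:
        raise ValueError("need two dated cliff boundaries")
    if date_pair is None:
        dates = sorted(scene.cliff_boundaries)
        date_pair = (dates[0], dates[-1])
    d0, d1 = date_pair
    if d1 <= d0:
        raise ValueError("date_pair must be increasing")
    baseline = _as_linestring(scene.shoreline)
    line0 = _as_linestring(scene.cliff_boundaries[d0])
    line1 = _as_linestring(scene.cliff_boundaries[d1])

    # generous reach: far enough to cross any cliff line in the scene
    reach = 4.0 * max(
        baseline.distance(line0) + line0.length,
        baseline.distance(line1) + line1.length,
    )

    n_stations = max(2, int(baseline.length // spacing) + 1)
    rates = []
    dropped = 0
    eps = min(spacing, baseline.length) * 1e-3
    for i in range(n_stations):
        s = min(i * spacing, baseline.length)
        station = baseline.interpolate(s)
        ahead = baseline.interpolate(min(s + eps, baseline.length))
        behind = baseline.interpolate(max(s - eps, 0.0))
        tangent = np.array([ahead.x - behind.x, ahead.y - behind.y])
        norm = np.hypot(*tangent)
        if norm == 0:
            dropped += 1
            continue
        normal = np.array([-tangent[1], tangent[0]]) / norm
        dist0 = _nearest_intersection_distance(station, normal, line0, reach)
        dist1 = _nearest_intersection_distance(station, normal, line1, reach)
        if dist0 is None or dist1 is None:
            dropped += 1
            continue
        rates.append((dist1 - dist0) / (d1 - d0))
    if not rates:
        raise ValueError("no transect intersects both dated cliff boundaries")
    arr = np.asarray(rates)
    return RetreatStats(
        per_transect_rates=arr,
        median=float(np.median(arr)),
        q25=float(np.percentile(arr, 25)),
        q75=float(np.percentile(arr, 75)),
        n_transects=arr.size,
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# DEM differencing

def dem_volume(
    dem_old: np.ndarray,
    dem_new: np.ndarray,
    cell_size: float,
    mask: Optional[Polygon] = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Eroded volume (m³) from positive elevation loss old − new.

    Only positive differences (subsidence/erosion) contribute, per the
    sign convention that positive change means thaw-driven surface loss.
    NODATA (NaN) cells in either grid are skipped. An optional polygon
    mask (in grid coordinates, row 0 at the top) restricts the sum to
    cells whose centers fall inside.
    """
    dem_old = np.asarray(dem_old, dtype=float)
    dem_new = np.asarray(dem_new, dtype=float)
    if dem_old.shape != dem_new.shape:
        raise ValueError("grids must be co-registered (same shape)")
    diff = dem_old - dem_new
    valid = ~(np.isnan(dem_old) | np.isnan(dem_new))
    if not valid.any():
        raise ValueError("all cells are NODATA")
    if mask is not None:
        nrows, ncols = dem_old.shape
        x0, y0 = origin
        xs = x0 + (np.arange(ncols) + 0.5) * cell_size
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * cell_size  # row 0 = north
        from shapely import points as _shapely_points, contains as _shapely_contains

        xx, yy = np.meshgrid(xs, ys)
        inside = _shapely_contains(mask, _shapely_points(xx.ravel(), yy.ravel())).reshape(dem_old.shape)
        valid &= inside
    loss = np.where(valid, np.clip(diff, 0.0, None), 0.0)
    return float(loss.sum() * cell_size**2)


# ---------------------------------------------------------------------------
# Nitrogen mobilization budget

@dataclass
class NMobilizationBudget:
    """Constants and derived quantities of the thaw-front N-release chain."""

    annual_volume_per_area: float  # m3 m-2 yr-1
    ice_fraction: float  # vol fraction
    bulk_density: float  # kg m-3 of the sediment (ice-free) fraction
    total_n_frac: float  # mass fraction of dry sediment
    mineral_n_content: float  # mg N kg-1 DW
    sediment_volume: float = 0.0  # m3 m-2 yr-1
    sediment_mass: float = 0.0  # kg m-2 yr-1
    total_n_release: float = 0.0  # kg N m-2 yr-1
    mineral_n_release: float = 0.0  # g N m-2 yr-1


@dataclass
class EmissionBudget:
    daily_flux_median: float  # μg N m-2 d-1
    season_days: float
    seasonal_loss: float  # mg N m-2 yr-1
    emission_factor: float  # % of mineral N released
    ipcc_ef: float  # %
    fold_below_ipcc: Optional[float]


def annual_volume_per_area(
    eroded_volume: float,
    epoch_years: float,
    retreat_rate: float,
    section_length: float,
) -> float:
    """Annually eroded volume per unit of annually eroded footprint area.

    The normalizing area is the annual retreat footprint: median retreat
    rate × cliff section length. (The alternative — the full DEM-difference
    footprint — is available by passing that area as
    ``retreat_rate × section_length`` equivalents.)
    """
    denom = retreat_rate * section_length
    if denom <= 0 or epoch_years <= 0:
        raise ValueError("epoch, retreat rate and section length must be positive")
    return eroded_volume / epoch_years / denom


def n_mobilization(
    annual_volume_per_area: float,
    ice_fraction: float = 0.82,
    bulk_density: float = 1220.0,
    total_n_frac: float = 0.0016,
    mineral_n_content: float = 35.3,
) -> NMobilizationBudget:
    """Annual total and mineral N liberated per m² of thaw-front footprint.

    Defaults are the Yedoma characteristics: 82 vol-% ground ice, dry bulk
    density 1.22 g cm⁻³, total N 0.16% DW and mineral N 35.3 mg N kg⁻¹ DW.
    """
    if not 0 <= ice_fraction < 1:
        raise ValueError("ice_fraction must be in [0, 1)")
    if annual_volume_per_area < 0:
        raise ValueError("annual_volume_per_area must be non-negative")
    sediment_volume = annual_volume_per_area * (1.0 - ice_fraction)
    sediment_mass = sediment_volume * bulk_density  # kg m-2 yr-1
    total_n = sediment_mass * total_n_frac  # kg N m-2 yr-1
    mineral_n = sediment_mass * mineral_n_content / 1000.0  # mg/kg * kg = mg -> g
    return NMobilizationBudget(
        annual_volume_per_area=annual_volume_per_area,
        ice_fraction=ice_fraction,
        bulk_density=bulk_density,
        total_n_frac=total_n_frac,
        mineral_n_content=mineral_n_content,
        sediment_volume=sediment_volume,
        sediment_mass=sediment_mass,
        total_n_release=total_n,
        mineral_n_release=mineral_n,
    )


def emission_budget(
    daily_flux_median: float,
    season_days: float = 100.0,
    mineral_n_release: Optional[float] = None,
    ipcc_ef: float = 1.0,
) -> EmissionBudget:
    """Seasonal N₂O-N loss and its emission factor against liberated mineral N.

    ``seasonal_loss`` (mg N m⁻² yr⁻¹) = median daily flux (μg N m⁻² d⁻¹)
    × snow-free season length / 1000. When ``mineral_n_release``
    (g N m⁻² yr⁻¹) is given, the emission factor (% of liberated mineral N
    lost as N₂O-N) and its fold-distance below the IPCC fertilizer default
    (1%) are computed.
    """
    if season_days <= 0:
        raise ValueError("season_days must be positive")
    seasonal_loss = daily_flux_median * season_days / 1000.0  # μg -> mg
    ef = math.nan
    fold = None
    if mineral_n_release is not None:
        if mineral_n_release <= 0:
            raise ValueError("mineral_n_release must be positive")
        ef = seasonal_loss / (mineral_n_release * 1000.0) * 100.0  # both in mg
        fold = ipcc_ef / ef if ef > 0 else None
    return EmissionBudget(
        daily_flux_median=daily_flux_median,
        season_days=season_days,
        seasonal_loss=seasonal_loss,
        emission_factor=ef,
        ipcc_ef=ipcc_ef,
        fold_below_ipcc=fold,
    )
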