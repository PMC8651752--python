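"""Static-chamber greenhouse-gas flux computation with RMSE-based quality control.

A closed (static) chamber accumulates gas above the soil surface; the flux
is obtained from the ordinary-least-squares slope of the headspace mixing
ratio against time, converted to an areal mass flux with the ideal-gas law.
Positive fluxes are emissions, negative fluxes uptake.

Quality control follows the field convention of comparing the regression
RMSE (in ppm) with the analytical repeatability of standard gas mixtures
in the relevant concentration range: a series is rejected when
RMSE > 3 × SD(standards).

A Fickian soil pore-gas gradient estimate is also provided for surfaces
where chamber deployment is impossible; it uses the Millington–Quirk
tortuosity model for the effective diffusivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .units import (
    AMBIENT_N2O_PPM,
    SEC_PER_DAY,
    molar_density,
    slope_to_flux,
)

__all__ = [
    "ChamberSeries",
    "FluxResult",
    "PoreGasProfile",
    "compute_flux",
    "quality_flag",
    "pore_gradient_flux",
    "compute_flux_table",
]


@dataclass
class ChamberSeries:
    """One chamber enclosure: headspace mixing ratios over time plus geometry.

    ``chamber_height`` is the chamber volume divided by its footprint area (m),
    ``standard_sd`` the analytical SD of standard gas mixtures (ppm) used for QC.
    """

    times: np.ndarray  # minutes since closure
    mixing_ratios: np.ndarray  # ppm
    analyte: str = "N2O"
    chamber_height: float = 0.15
    air_temp: float = 283.15  # K
    pressure: float = 101325.0  # Pa
    standard_sd: float = 0.003  # ppm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mixing_ratios = np.asarray(self.mixing_ratios, dtype=float)
        if self.times.size != self.mixing_ratios.size:
            raise ValueError("times and mixing_ratios must have equal length")
        if self.times.size < 3:
            raise ValueError("need at least 3 samples per enclosure")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.chamber_height <= 0:
            raise ValueError("chamber_height must be positive")
        if self.air_temp <= 0:
            raise ValueError("air_temp must be positive (K)")
        if self.analyte not in ("N2O", "CH4", "CO2"):
            raise ValueError(f"unknown analyte {self.analyte!r}")


@dataclass
class FluxResult:
    """Slope, converted areal flux, fit diagnostics and the QC verdict."""

    slope: float  # ppm min-1
    flux: float  # μg N m-2 d-1 (N2O) or mg C m-2 d-1 (CH4, CO2)
    r2: float
    rmse: float  # ppm
    qc_pass: bool
    analyte: str = "N2O"


def quality_flag(rmse: float, standard_sd: float) -> bool:
    """Accept a series unless its regression RMSE exceeds 3 × the standard SD.

    The boundary itself (RMSE == 3·SD) is accepted: rejection requires
    strict exceedance.
    """
    if rmse < 0 or standard_sd < 0:
        raise ValueError("rmse and standard_sd must be non-negative")
    return not rmse > 3.0 * standard_sd


def compute_flux(series: ChamberSeries) -> FluxResult:
    """OLS fit of mixing ratio vs. time over all samples, converted to a flux.

    No points are dropped; r² and RMSE are reported so that poor enclosures
    can be screened with :func:`quality_flag` (applied automatically here).
    """
    t = series.times
    y = series.mixing_ratios
    if t[-1] == t[0]:
        raise ValueError("zero time span")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(sse / t.size))
    # a perfectly constant series is a perfect fit of a zero slope
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    flux = slope_to_flux(slope, series.chamber_height, series.air_temp, series.pressure, series.analyte)
    return FluxResult(
        slope=float(slope),
        flux=float(flux),
        r2=float(r2),
        rmse=rmse,
        qc_pass=quality_flag(rmse, series.standard_sd),
        analyte=series.analyte,
    )


@dataclass
class PoreGasProfile:
    """Soil pore-gas concentration at depth plus the porosity terms of the
    Millington–Quirk effective diffusivity."""

    depth: float  # m
    pore_concentration: float  # ppm
    air_filled_porosity: float
    total_porosity: float
    surface_concentration: float = AMBIENT_N2O_PPM  # ppm

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.air_filled_porosity <= self.total_porosity <= 1:
            raise ValueError("require 0 <= air-filled <= total porosity <= 1")


#: free-air diffusivity of N2O at 293 K, m² s⁻¹
D0_N2O_293K = 1.43e-5


def pore_gradient_flux(profile: PoreGasProfile, temp: float, pressure: float) -> float:
    """Diffusive N₂O flux from a pore-gas concentration gradient, μg N m⁻² day⁻¹.

    Fick's first law with the Millington–Quirk tortuosity:
    Ds = D0 · θa^(10/3) / φ², D0 temperature-scaled as (T/293)^1.75.
    The concentration difference is converted from ppm to mol m⁻³ with the
    ideal-gas law at the given temperature and pressure.
    """
    gradient_ppm = profile.pore_concentration - profile.surface_concentration
    if profile.air_filled_porosity == 0:
        if gradient_ppm != 0:
            raise ValueError("no diffusion pathway: zero air-filled porosity with nonzero gradient")
        return 0.0
    d0 = D0_N2O_293K * (temp / 293.0) ** 1.75
    ds = d0 * profile.air_filled_porosity ** (10.0 / 3.0) / profile.total_porosity**2
    delta_c = gradient_ppm * 1e-6 * molar_density(pressure, temp)  # mol m-3
    flux_mol = ds * delta_c / profile.depth  # mol m-2 s-1
    return flux_mol * 28.0134 * 1e6 * SEC_PER_DAY  # μg N m-2 d-1


def compute_flux_table(df: pd.DataFrame) -> pd.DataFrame:
    """Compute one flux per enclosure from a long-format chamber table.

    Expected columns: plot_id, surface_class, analyte, time_min, conc_ppm,
    height_m, temp_C, pressure_Pa, standard_sd_ppm.
    """
    rows = []
    for (plot, analyte), grp in df.groupby(["plot_id", "analyte"], sort=False):
        grp = grp.sort_values("time_min")
        series = ChamberSeries(
            times=grp["time_min"].to_numpy(),
            mixing_ratios=grp["conc_ppm"].to_numpy(),
            analyte=str(analyte),
            chamber_height=float(grp["height_m"].iloc[0]),
            air_temp=float(grp["temp_C"].iloc[0]) + 273.15,
            pressure=float(grp["pressure_Pa"].iloc[0]),
            standard_sd=float(grp["standard_sd_ppm"].iloc[0]),
        )
        res = compute_flux(series)
        rows.append(
            {
                "plot_id": plot,
                "surface_class": grp["surface_class"].iloc[0],
                "analyte": analyte,
                "slope_ppm_min": res.slope,
                "flux": res.flux,
                "r2": res.r2,
                "rmse_ppm": res.rmse,
                "qc_pass": res.qc_pass,
            }
        )
    return pd.DataFrame(rows)
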