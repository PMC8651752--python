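"""Soil physical and chemical derivations: porosity, WFPS, dry-weight-basis
mineral nitrogen, C/N ratio.

WFPS (water-filled pore space) is volumetric water content divided by total
porosity, with porosity from bulk and particle density. Salt-extractable
NH₄⁺/NO₃⁻ concentrations measured in the extract (mg N L⁻¹) are converted
to a dry-soil mass basis (mg N kg⁻¹ DW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SoilSample",
    "DEFAULT_PARTICLE_DENSITY",
    "porosity",
    "wfps",
    "extract_to_dw",
    "cn_ratio",
    "derive_soil_table",
]

#: mineral-soil default when particle density was not measured, g cm⁻³
DEFAULT_PARTICLE_DENSITY = 2.65


@dataclass
class SoilSample:
    vwc: float  # volumetric water content, fraction
    bulk_density: float  # g cm-3
    particle_density: float = DEFAULT_PARTICLE_DENSITY  # g cm-3
    gravimetric_water: float = 0.0  # g g-1 DW
    total_c: float = 0.0  # % DW
    organic_c: float = 0.0  # % DW
    total_n: float = 0.0  # % DW
    ph: float = 7.0
    extract_nh4: float = 0.0  # mg N L-1 extract
    extract_no3: float = 0.0  # mg N L-1 extract
    extract_ratio: float = 3.0  # volume extractant per volume soil

    def __post_init__(self) -> None:
        if not 0 <= self.vwc <= 1:
            raise ValueError("vwc must be a fraction in [0, 1]")
        if not self.particle_density > self.bulk_density > 0:
            raise ValueError("require particle_density > bulk_density > 0")
        for name in ("total_c", "organic_c", "total_n"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100]")


def porosity(bulk_density: float, particle_density: float = DEFAULT_PARTICLE_DENSITY) -> float:
    """Total porosity φ = 1 − ρ_bulk/ρ_particle."""
    phi = 1.0 - bulk_density / particle_density
    if phi <= 0:
        raise ValueError("non-positive porosity: bulk density >= particle density")
    return phi


def wfps(vwc: float, bulk_density: float, particle_density: float = DEFAULT_PARTICLE_DENSITY) -> float:
    """Water-filled pore space = VWC / porosity.

    Values above 1 can arise from field VWC measurement error; they are
    returned as-is with a warning rather than clipped, so the caller can
    decide how to treat apparent super-saturation.
    """
    out = vwc / porosity(bulk_density, particle_density)
    if out > 1:
        warnings.warn(f"WFPS {out:.3f} exceeds 1 (apparent super-saturation)", stacklevel=2)
    return out


def extract_to_dw(
    extract_conc: float,
    extract_volume: float,
    soil_fresh_mass: float,
    gravimetric_water: float,
) -> float:
    """Convert a salt-extract concentration to mg N per kg dry soil.

    Parameters
    ----------
    extract_conc
        mg N per litre of extract.
    extract_volume
        litres of extractant used.
    soil_fresh_mass
        grams of fresh soil extracted.
    gravimetric_water
        g water per g dry soil, used to convert fresh to dry mass.
    """
    if soil_fresh_mass <= 0:
        raise ValueError("soil_fresh_mass must be positive")
    dry_mass_g = soil_fresh_mass / (1.0 + gravimetric_water)
    if dry_mass_g <= 0:
        raise ValueError("zero dry mass")
    return extract_conc * extract_volume / (dry_mass_g / 1000.0)


def cn_ratio(total_c: float, total_n: float) -> float:
    """Mass ratio of total carbon to total nitrogen (both % DW)."""
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    return total_c / total_n


def derive_soil_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns (wfps, cn) to a soil-property table.

    Expected columns: vwc, bulk_density, particle_density (optional),
    total_c, total_n. Rows with total_n == 0 get NaN C/N.
    """
    out = df.copy()
    pd_col = out.get("particle_density")
    if pd_col is None:
        out["particle_density"] = DEFAULT_PARTICLE_DENSITY
        out["particle_density_assumed"] = True
    phi = 1.0 - out["bulk_density"] / out["particle_density"]
    out["wfps"] = out["vwc"] / phi
    out["cn"] = out["total_c"] / out["total_n"].where(out["total_n"] > 0)
    return out
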