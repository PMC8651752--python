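"""Physical constants and gas unit conversions shared across modules.

Mixing ratios are handled in ppm (μmol mol⁻¹). Areal fluxes are expressed
in the units conventional for each gas: μg N m⁻² day⁻¹ for N₂O and
mg C m⁻² day⁻¹ for CH₄ and CO₂.
"""

from __future__ import annotations

R_GAS = 8.314  # J mol-1 K-1

#: grams of the reported element per mole of gas
ELEMENT_MASS = {
    "N2O": 28.0134,  # g N per mol N2O (two N atoms)
    "CH4": 12.011,   # g C per mol
    "CO2": 12.011,   # g C per mol
}

#: multiplier from grams to the reporting mass unit (μg for N2O, mg for CH4/CO2)
_MASS_SCALE = {"N2O": 1e6, "CH4": 1e3, "CO2": 1e3}

MIN_PER_DAY = 1440.0
SEC_PER_DAY = 86400.0

AMBIENT_N2O_PPM = 0.33  # atmospheric N2O mixing ratio


def molar_density(pressure: float, temp: float) -> float:
    """Moles of gas per m³ at ``pressure`` (Pa) and ``temp`` (K), ideal gas."""
    if temp <= 0:
        raise ValueError("temperature must be positive (K)")
    return pressure / (R_GAS * temp)


def slope_to_flux(
    slope_ppm_min: float,
    chamber_height: float,
    temp: float,
    pressure: float,
    analyte: str = "N2O",
) -> float:
    """Convert a headspace accumulation slope into an areal flux.

    Parameters
    ----------
    slope_ppm_min
        Rate of change of the mixing ratio, ppm min⁻¹.
    chamber_height
        Chamber volume per footprint area, m.
    temp, pressure
        Headspace air temperature (K) and pressure (Pa).
    analyte
        ``"N2O"`` (returns μg N m⁻² day⁻¹) or ``"CH4"``/``"CO2"``
        (returns mg C m⁻² day⁻¹).
    """
    mass = ELEMENT_MASS[analyte]
    scale = _MASS_SCALE[analyte]
    mol_per_m2_min = slope_ppm_min * 1e-6 * chamber_height * molar_density(pressure, temp)
    return mol_per_m2_min * mass * scale * MIN_PER_DAY


def flux_to_slope(
    flux: float,
    chamber_height: float,
    temp: float,
    pressure: float,
    analyte: str = "N2O",
) -> float:
    """Exact inverse of :func:`slope_to_flux` (ppm min⁻¹ from an areal flux)."""
    mass = ELEMENT_MASS[analyte]
    scale = _MASS_SCALE[analyte]
    denom = 1e-6 * chamber_height * molar_density(pressure, temp) * mass * scale * MIN_PER_DAY
    if denom == 0:
        raise ValueError("degenerate chamber geometry")
    return flux / denom


def ppm_to_mass(
    ppm: float, volume_m3: float, temp: float, pressure: float, analyte: str = "N2O"
) -> float:
    """Gas amount in a closed volume, as μg N (N₂O) or mg C (CH₄/CO₂)."""
    return ppm * 1e-6 * volume_m3 * molar_density(pressure, temp) * ELEMENT_MASS[analyte] * _MASS_SCALE[analyte]
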