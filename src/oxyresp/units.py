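"""Dissolved-oxygen unit conversions for freshwater respirometry.

Converts among mg O2 L^-1, kPa partial pressure and % air saturation as a
function of water temperature and barometric pressure, using the
Benson & Krause (1984) equilibrium-solubility equations in the form
standardised by the USGS for freshwater (with an optional linear salinity
term).

Conventions used throughout the package: temperatures in degrees Celsius,
pressures in kPa, concentrations in mg O2 per litre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaterConditions",
    "o2_saturation_concentration",
    "water_vapour_pressure_kpa",
    "po2_air_kpa",
    "mgL_to_kPa",
    "kPa_to_mgL",
    "percent_saturation",
]

#: Mole fraction of O2 in dry air.
O2_MOLE_FRACTION = 0.20946

#: Standard atmosphere in kPa.
STANDARD_ATMOSPHERE_KPA = 101.325


@dataclass(frozen=True)
class WaterConditions:
    """Ambient water conditions that set the O2 solubility context.

    Parameters
    ----------
    temperature : float
        Water temperature in degrees C. Valid range 0-40.
    barometric_pressure : float
        Barometric pressure in kPa. Valid range 80-110 (sea-level weather).
    salinity : float
        Practical salinity units; default 0 (freshwater).
    """

    temperature: float
    barometric_pressure: float = STANDARD_ATMOSPHERE_KPA
    salinity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature <= 40.0:
            raise ValueError(
                f"temperature {self.temperature} degC outside the valid range [0, 40]"
            )
        if not 80.0 <= self.barometric_pressure <= 110.0:
            raise ValueError(
                f"barometric_pressure {self.barometric_pressure} kPa outside "
                "the valid range [80, 110]"
            )
        if self.salinity < 0.0:
            raise ValueError("salinity must be >= 0")


def water_vapour_pressure_kpa(temperature: float) -> float:
    """Saturation vapour pressure of water in kPa (Benson & Krause form)."""
    tk = temperature + 273.15
    ln_pwv_atm = 11.8571 - 3840.70 / tk - 216961.0 / tk**2
    return math.exp(ln_pwv_atm) * STANDARD_ATMOSPHERE_KPA


def o2_saturation_concentration(cond: WaterConditions) -> float:
    """Equilibrium (air-saturated) dissolved-O2 concentration in mg/L.

    Benson & Krause baseline at 1 atm moist air, with the USGS salinity
    factor and pressure correction applied for the supplied conditions.
    """
    t = cond.temperature
    tk = t + 273.15

    ln_c_star = (
        -139.34411
        + 1.575701e5 / tk
        - 6.642308e7 / tk**2
        + 1.243800e10 / tk**3
        - 8.621949e11 / tk**4
    )
    c_star = math.exp(ln_c_star)  # mg/L at 1 atm moist air

    if cond.salinity > 0.0:
        c_star *= math.exp(
            -cond.salinity * (0.017674 - 10.754 / tk + 2140.7 / tk**2)
        )

    p_atm = cond.barometric_pressure / STANDARD_ATMOSPHERE_KPA
    pwv_atm = water_vapour_pressure_kpa(t) / STANDARD_ATMOSPHERE_KPA
    theta = 0.000975 - 1.426e-5 * t + 6.436e-8 * t**2
    pressure_factor = (
        p_atm
        * (1.0 - pwv_atm / p_atm)
        * (1.0 - theta * p_atm)
        / ((1.0 - pwv_atm) * (1.0 - theta))
    )
    return c_star * pressure_factor


def po2_air_kpa(cond: WaterConditions) -> float:
    """Partial pressure of O2 in water-saturated air, kPa."""
    return O2_MOLE_FRACTION * (
        cond.barometric_pressure - water_vapour_pressure_kpa(cond.temperature)
    )


def mgL_to_kPa(conc, cond: WaterConditions):
    """Convert dissolved O2 from mg/L to kPa partial pressure.

    A concentration at full air saturation maps to the atmospheric PO2 for
    the same conditions by construction. Accepts scalars or arrays.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    out = conc / o2_saturation_concentration(cond) * po2_air_kpa(cond)
    return float(out) if out.ndim == 0 else out


def kPa_to_mgL(po2, cond: WaterConditions):
    """Convert O2 partial pressure (kPa) to mg/L; exact inverse of mgL_to_kPa."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("partial pressure must be >= 0")
    out = po2 / po2_air_kpa(cond) * o2_saturation_concentration(cond)
    return float(out) if out.ndim == 0 else out


def percent_saturation(conc, cond: WaterConditions):
    """Dissolved O2 as percent of air saturation."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    out = 100.0 * conc / o2_saturation_concentration(cond)
    return float(out) if out.ndim == 0 else out
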