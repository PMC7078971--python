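"""Closed-form gas physics for open-channel metabolism and CO2 evasion work.

Schmidt numbers, conversion between the standardized gas exchange
coefficient K600 and gas-specific coefficients, dissolved O2 saturation,
barometric pressure with elevation, Henry's-law CO2 unit conversion and
the O2-to-carbon stoichiometric conversion.

Units follow the conventions of the stream metabolism literature:
temperature in deg C, pressure in atm, gas exchange coefficients in
day^-1, O2 in g m^-3, CO2 either as ppm partial pressure or mol m^-3,
areal rates in g (O2 or C) m^-2 day^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaterConditions",
    "GasExchange",
    "schmidt_o2",
    "schmidt_co2",
    "k600_to_kgas",
    "kgas_to_k600",
    "o2_saturation",
    "barometric_pressure",
    "henry_kh_co2",
    "co2_ppm_to_molar",
    "co2_molar_to_ppm",
    "o2_to_carbon",
    "carbon_to_o2",
]

# Validity range of the Schmidt-number polynomials (freshwater fits).
_T_MIN, _T_MAX = -1.0, 40.0

#: Molar masses, g/mol.
M_O2 = 32.0
M_C = 12.0

#: Isothermal scale height of the barometric formula, m (15 deg C standard
#: atmosphere, H = R*T / (M_air * g)).
SCALE_HEIGHT_M = 8434.0

#: Reference Schmidt number for K600 (CO2 in freshwater at 20 deg C).
SCHMIDT_REFERENCE = 600.0


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T < _T_MIN) or np.any(T > _T_MAX):
        raise ValueError(
            f"temperature outside the supported range [{_T_MIN}, {_T_MAX}] degC"
        )
    return T


@dataclass(frozen=True)
class WaterConditions:
    """Physical state of the water column at a site.

    Parameters
    ----------
    temperature : float
        Water temperature, deg C, in [-1, 40].
    pressure : float
        Ambient barometric pressure at the water surface, atm.
    elevation : float
        Site elevation, m above sea level.
    """

    temperature: float
    pressure: float = 1.0
    elevation: float = 0.0

    def __post_init__(self) -> None:
        _check_temperature(self.temperature)
        if not self.pressure > 0:
            raise ValueError("pressure must be positive")
        if self.elevation < 0:
            raise ValueError("elevation must be non-negative")


@dataclass(frozen=True)
class GasExchange:
    """Gas exchange coefficients of one site-day, all in day^-1.

    ``KO2`` and ``KCO2`` are the gas-specific coefficients obtained from
    the standardized ``K600`` by Schmidt scaling.
    """

    K600: float
    KO2: float
    KCO2: float

    def __post_init__(self) -> None:
        if min(self.K600, self.KO2, self.KCO2) < 0:
            raise ValueError("gas exchange coefficients must be non-negative")

    @classmethod
    def from_k600(cls, K600: float, temperature: float) -> "GasExchange":
        return cls(
            K600=K600,
            KO2=k600_to_kgas(K600, schmidt_o2(temperature)),
            KCO2=k600_to_kgas(K600, schmidt_co2(temperature)),
        )


def schmidt_o2(T):
    """Schmidt number of O2 in freshwater at temperature ``T`` (deg C).

    Cubic polynomial fit; dimensionless. Valid for T in [-1, 40].
    """
    T = _check_temperature(T)
    return 1800.6 - 120.1 * T + 3.78 * T**2 - 0.0476 * T**3


def schmidt_co2(T):
    """Schmidt number of CO2 in freshwater at temperature ``T`` (deg C)."""
    T = _check_temperature(T)
    return 1911.1 - 118.1 * T + 3.45 * T**2 - 0.0413 * T**3


def k600_to_kgas(K600, SC):
    """Convert K600 to the exchange coefficient of a gas with Schmidt number SC.

    Kx = K600 * (600 / SCx) ** 0.5 (unsheltered-surface exponent -0.5).
    """
    K600 = np.asarray(K600, dtype=float)
    SC = np.asarray(SC, dtype=float)
    if np.any(K600 < 0):
        raise ValueError("K600 must be non-negative")
    if np.any(SC <= 0):
        raise ValueError("Schmidt number must be positive")
    return K600 * (SCHMIDT_REFERENCE / SC) ** 0.5


def kgas_to_k600(Kx, SC):
    """Inverse of :func:`k600_to_kgas`; round-trips to machine precision."""
    Kx = np.asarray(Kx, dtype=float)
    SC = np.asarray(SC, dtype=float)
    if np.any(Kx < 0):
        raise ValueError("Kx must be non-negative")
    if np.any(SC <= 0):
        raise ValueError("Schmidt number must be positive")
    return Kx / (SCHMIDT_REFERENCE / SC) ** 0.5


def _o2_sat_1atm(T):
    """Benson-Krause equilibrium O2 concentration at 1 atm moist air, mg/L."""
    TK = np.asarray(T, dtype=float) + 273.15
    lnC = (
        -139.34411
        + 1.575701e5 / TK
        - 6.642308e7 / TK**2
        + 1.243800e10 / TK**3
        - 8.621949e11 / TK**4
    )
    return np.exp(lnC)


def _water_vapour_pressure_atm(T):
    """Saturation vapour pressure of water, atm (Antoine-type fit)."""
    TK = np.asarray(T, dtype=float) + 273.15
    return np.exp(11.8571 - 3840.70 / TK - 216961.0 / TK**2)


def o2_saturation(T, pressure=1.0):
    """Dissolved O2 concentration at 100% saturation, g O2 m^-3.

    Garcia-Gordon/Benson-Krause equilibrium concentration at 1 atm moist
    air, corrected to ambient barometric ``pressure`` (atm) with the
    standard vapour-pressure correction; to first order the value scales
    with pressure. Strictly decreasing in temperature.
    """
    T = _check_temperature(T)
    pressure = np.asarray(pressure, dtype=float)
    if np.any(pressure <= 0):
        raise ValueError("pressure must be positive")
    c_star = _o2_sat_1atm(T)
    pwv = _water_vapour_pressure_atm(T)
    return c_star * (pressure - pwv) / (1.0 - pwv)


def barometric_pressure(P0, dz, scale_height=SCALE_HEIGHT_M):
    """Barometric pressure after an elevation change of ``dz`` metres.

    Isothermal barometric formula P = P0 * exp(-dz / H) with scale height
    H = 8434 m; ``dz`` positive when moving upward from the reference.
    """
    P0 = np.asarray(P0, dtype=float)
    dz = np.asarray(dz, dtype=float)
    if not np.all(np.isfinite(dz)):
        raise ValueError("dz must be finite")
    return P0 * np.exp(-dz / scale_height)


def henry_kh_co2(T):
    """Henry's-law solubility of CO2 in freshwater, mol L^-1 atm^-1.

    Weiss (1974) K0 fit at zero salinity as a function of temperature.
    """
    T = _check_temperature(T)
    TK = np.asarray(T, dtype=float) + 273.15
    ln_k0 = -58.0931 + 90.5069 * (100.0 / TK) + 22.2940 * np.log(TK / 100.0)
    return np.exp(ln_k0)


def co2_ppm_to_molar(pCO2, T):
    """Convert a CO2 partial pressure (ppm) to dissolved CO2, mol m^-3.

    concentration = pCO2 * 1e-6 atm * KH(T), with KH in mol L^-1 atm^-1
    converted to mol m^-3 atm^-1; linear in pCO2.
    """
    pCO2 = np.asarray(pCO2, dtype=float)
    if np.any(pCO2 < 0):
        raise ValueError("pCO2 must be non-negative")
    return pCO2 * 1e-6 * henry_kh_co2(T) * 1000.0


def co2_molar_to_ppm(conc, T):
    """Inverse of :func:`co2_ppm_to_molar` (mol m^-3 -> ppm)."""
    conc = np.asarray(conc, dtype=float)
    return conc / (henry_kh_co2(T) * 1000.0) * 1e6


def o2_to_carbon(rate):
    """Convert an areal O2 rate to carbon units (g O2 -> g C).

    Assumes 1 mol O2 produced/consumed per mol CO2 (photosynthetic and
    respiratory quotients of 1), i.e. multiply by 12/32. Sign-preserving.
    """
    rate = np.asarray(rate, dtype=float)
    if not np.all(np.isfinite(rate)):
        raise ValueError("rate must be finite")
    out = rate * (M_C / M_O2)
    return float(out) if out.ndim == 0 else out


def carbon_to_o2(rate):
    """Convert an areal carbon rate back to O2 units (g C -> g O2)."""
    rate = np.asarray(rate, dtype=float)
    if not np.all(np.isfinite(rate)):
        raise ValueError("rate must be finite")
    out = rate * (M_O2 / M_C)
    return float(out) if out.ndim == 0 else out
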