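"""CO2 evasion and its diel metrics.

The air-water CO2 flux per unit streambed area is

    E = KCO2 * z * ([CO2]w - [CO2]a)

with KCO2 the gas-specific exchange coefficient (day^-1), z the mean
depth (m) and the concentrations in mol m^-3; the flux is converted to
g C m^-2 day^-1 (x12) and is positive when the stream degasses.
The atmospheric reference is 380 ppm converted through Henry's law at
the water temperature. Diel metrics per day: the within-day pCO2 range
(dCO2), the day-night contrast in cumulative evasion, mean rates in 1-h
bins centred on solar noon and solar midnight, and the coefficient of
variation SD/mean x 100.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar
from .gas_physics import M_C, co2_ppm_to_molar, k600_to_kgas, schmidt_co2

__all__ = [
    "FluxRecord",
    "evasion_rate",
    "atmospheric_reference",
    "evasion_series",
    "delta_co2",
    "diel_evasion_change",
    "noon_midnight",
    "cv",
    "daily_flux_record",
]

ATM_CO2_PPM_DEFAULT = 380.0


@dataclass(frozen=True)
class FluxRecord:
    """Per-day CO2 flux summary for one site-day.

    Rates in g C m^-2 day^-1; ``diel_evasion_change`` in g C m^-2
    (negative when daytime evasion is suppressed, e.g. by GPP);
    ``delta_co2`` in ppm. ``noon`` / ``midnight`` are the mean rates in
    the 1-h bins centred on solar noon and solar midnight; they are NaN
    (and ``polar`` True) when the sun never sets so no night bin exists.
    """

    day: dt.date
    mean_evasion: float
    delta_co2: float
    diel_evasion_change: float
    noon_evasion: float
    midnight_evasion: float
    cv_evasion: float
    polar: bool


def evasion_rate(kco2, z, co2_w, co2_a):
    """Instantaneous CO2 evasion, g C m^-2 day^-1 (positive = efflux)."""
    kco2 = np.asarray(kco2, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(kco2 < 0):
        raise ValueError("KCO2 must be non-negative")
    if np.any(z <= 0):
        raise ValueError("depth must be positive")
    out = kco2 * z * (np.asarray(co2_w, float) - np.asarray(co2_a, float)) * M_C
    return float(out) if out.ndim == 0 else out


def atmospheric_reference(temperature, atm_ppm: float = ATM_CO2_PPM_DEFAULT):
    """Dissolved CO2 in equilibrium with the atmosphere, mol m^-3.

    Converts the atmospheric mixing ratio (default 380 ppm) at the water
    temperature; temperature-dependent through Henry's constant.
    """
    return co2_ppm_to_molar(atm_ppm, temperature)


def evasion_series(
    pco2_ppm,
    temperature,
    k600,
    depth,
    atm_ppm: float = ATM_CO2_PPM_DEFAULT,
):
    """Per-timestep evasion from sensor pCO2, temperature, K600 and depth.

    KCO2 is derived per timestep from K600 and the Schmidt number at the
    concurrent temperature; concentrations via Henry's law.
    """
    temperature = np.asarray(temperature, dtype=float)
    co2_w = co2_ppm_to_molar(pco2_ppm, temperature)
    co2_a = atmospheric_reference(temperature, atm_ppm)
    kco2 = k600_to_kgas(k600, schmidt_co2(temperature))
    return evasion_rate(kco2, depth, co2_w, co2_a)


def delta_co2(pco2_ppm) -> float:
    """Within-day pCO2 range: highest minus lowest concentration, ppm."""
    pco2_ppm = np.asarray(pco2_ppm, dtype=float)
    return float(np.ptp(pco2_ppm))


def diel_evasion_change(
    evasion,
    times: pd.DatetimeIndex,
    sunrise: dt.datetime | None,
    sunset: dt.datetime | None,
) -> float:
    """Day-night contrast in cumulative evasion, g C m^-2.

    Defined as (mean daytime rate - mean night-time rate) times the
    daytime duration, i.e. the daytime cumulative evasion minus the
    evasion the same interval would have produced at the night-time
    rate. This duration-normalized convention stays well defined for any
    photoperiod; with no sunrise/sunset (polar day) it is NaN.
    """
    if sunrise is None or sunset is None:
        return float("nan")
    evasion = np.asarray(evasion, dtype=float)
    day_mask = np.asarray((times >= sunrise) & (times <= sunset))
    night_mask = ~day_mask
    if not day_mask.any() or not night_mask.any():
        return float("nan")
    day_hours = (sunset - sunrise).total_seconds() / 3600.0
    return float(
        (evasion[day_mask].mean() - evasion[night_mask].mean()) * day_hours / 24.0
    )


def noon_midnight(
    evasion,
    times: pd.DatetimeIndex,
    solar_noon: dt.datetime,
    solar_midnight: dt.datetime | None = None,
    half_width: dt.timedelta = dt.timedelta(minutes=30),
) -> tuple[float, float]:
    """Mean evasion rate in the 1-h bins centred on solar noon/midnight.

    Solar (not clock) times are used: at high latitude in summer the two
    differ by up to an hour. The midnight bin may extend past the
    calendar day; samples outside the record are simply absent.
    """
    evasion = np.asarray(evasion, dtype=float)

    def bin_mean(centre: dt.datetime) -> float:
        mask = np.asarray(
            (times >= centre - half_width) & (times <= centre + half_width)
        )
        return float(evasion[mask].mean()) if mask.any() else float("nan")

    if solar_midnight is None:
        # the solar midnight inside the same calendar day as the noon
        if solar_noon.hour >= 12:
            solar_midnight = solar_noon - dt.timedelta(hours=12)
        else:
            solar_midnight = solar_noon + dt.timedelta(hours=12)
    return bin_mean(solar_noon), bin_mean(solar_midnight)


def cv(values) -> float:
    """Coefficient of variation: sample SD / mean x 100, %."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    m = values.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(values.std(ddof=1) / m * 100.0)


def daily_flux_record(
    day_frame: pd.DataFrame,
    k600,
    latitude: float,
    longitude: float,
    atm_ppm: float = ATM_CO2_PPM_DEFAULT,
) -> FluxRecord:
    """All diel CO2 flux metrics for one day of sensor data.

    ``day_frame`` carries one calendar day with columns pco2,
    temperature and depth; ``k600`` is the day's gas exchange
    coefficient (scalar or per-timestep series). Solar events come from
    site coordinates.
    """
    date = day_frame.index[0].date()
    ev = evasion_series(
        day_frame["pco2"].to_numpy(),
        day_frame["temperature"].to_numpy(),
        k600,
        day_frame["depth"].to_numpy(),
        atm_ppm,
    )
    st = solar.sun_times(latitude, longitude, date)
    # whichever solar midnight falls inside this calendar day
    if st.solar_noon.hour >= 12:
        midnight = st.solar_noon - dt.timedelta(hours=12)
    else:
        midnight = st.solar_noon + dt.timedelta(hours=12)
    noon_ev, mid_ev = noon_midnight(ev, day_frame.index, st.solar_noon, midnight)
    return FluxRecord(
        day=date,
        mean_evasion=float(np.mean(ev)),
        delta_co2=delta_co2(day_frame["pco2"].to_numpy()),
        diel_evasion_change=diel_evasion_change(
            ev, day_frame.index, st.sunrise, st.sunset
        ),
        noon_evasion=noon_ev,
        midnight_evasion=mid_ev,
        cv_evasion=cv(ev),
        polar=st.polar_day,
    )
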