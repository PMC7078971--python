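"""Solar geometry: elevation angle, sunrise/sunset and solar noon.

NOAA-style low-precision solar position (Spencer Fourier series for
declination and the equation of time). Accuracy is a few minutes in event
times, which is ample for photoperiod bookkeeping, night-window placement
and noon/midnight flux bins. All timestamps are UTC; longitude is used
only to shift solar time.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

__all__ = ["SunTimes", "solar_elevation", "sun_times"]

#: Zenith angle of the sun centre at sunrise/sunset, deg (34' refraction
#: plus 16' solar radius).
_SUNRISE_ZENITH_DEG = 90.833


def _fractional_year(when: dt.datetime) -> float:
    doy = when.timetuple().tm_yday
    hours = when.hour + when.minute / 60.0 + when.second / 3600.0
    return 2.0 * np.pi / 365.0 * (doy - 1 + (hours - 12.0) / 24.0)


def _declination(gamma: float) -> float:
    """Solar declination, radians."""
    return (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )


def _equation_of_time_min(gamma: float) -> float:
    """Equation of time, minutes (true minus mean solar time)."""
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )


def solar_elevation(latitude: float, longitude: float, when: dt.datetime) -> float:
    """Solar elevation angle above the horizon, degrees, at UTC time ``when``."""
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must be within [-90, 90] degrees")
    gamma = _fractional_year(when)
    decl = _declination(gamma)
    eqtime = _equation_of_time_min(gamma)
    minutes_utc = when.hour * 60.0 + when.minute + when.second / 60.0
    true_solar_min = minutes_utc + eqtime + 4.0 * longitude
    hour_angle = np.deg2rad(true_solar_min / 4.0 - 180.0)
    lat = np.deg2rad(latitude)
    sin_el = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(
        hour_angle
    )
    return float(np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0))))


@dataclass(frozen=True)
class SunTimes:
    """Sunrise/sunset bookkeeping for one site-date (UTC).

    ``sunrise``/``sunset`` are ``None`` during polar day and polar night;
    ``polar_day`` / ``polar_night`` flag which. ``solar_noon`` (sun highest)
    and ``solar_midnight`` (12 h away) are always defined.
    """

    date: dt.date
    sunrise: dt.datetime | None
    sunset: dt.datetime | None
    solar_noon: dt.datetime
    solar_midnight: dt.datetime
    polar_day: bool
    polar_night: bool

    @property
    def day_length_hours(self) -> float:
        if self.polar_day:
            return 24.0
        if self.polar_night:
            return 0.0
        return (self.sunset - self.sunrise).total_seconds() / 3600.0

    @property
    def night_length_hours(self) -> float:
        return 24.0 - self.day_length_hours


def sun_times(latitude: float, longitude: float, date: dt.date) -> SunTimes:
    """Sunrise, sunset, solar noon and solar midnight (UTC) for a site-date."""
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must be within [-90, 90] degrees")
    noon_guess = dt.datetime(date.year, date.month, date.day, 12)
    gamma = _fractional_year(noon_guess)
    decl = _declination(gamma)
    eqtime = _equation_of_time_min(gamma)

    noon_min = 720.0 - 4.0 * longitude - eqtime
    solar_noon = dt.datetime(date.year, date.month, date.day) + dt.timedelta(
        minutes=noon_min
    )
    solar_midnight = solar_noon + dt.timedelta(hours=12)

    lat = np.deg2rad(latitude)
    cos_ha0 = (
        np.cos(np.deg2rad(_SUNRISE_ZENITH_DEG)) / (np.cos(lat) * np.cos(decl))
        - np.tan(lat) * np.tan(decl)
    )
    if cos_ha0 < -1.0:  # sun never sets
        return SunTimes(date, None, None, solar_noon, solar_midnight, True, False)
    if cos_ha0 > 1.0:  # sun never rises
        return SunTimes(date, None, None, solar_noon, solar_midnight, False, True)

    ha0_min = 4.0 * np.rad2deg(np.arccos(cos_ha0))  # half day length, minutes
    sunrise = solar_noon - dt.timedelta(minutes=ha0_min)
    sunset = solar_noon + dt.timedelta(minutes=ha0_min)
    return SunTimes(date, sunrise, sunset, solar_noon, solar_midnight, False, False)
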