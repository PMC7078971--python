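"""Gas exchange from data: rating curve, night-time regression, K600-Q.

The night-time regression exploits the post-sunset window when GPP has
shut down: dO2/dt then depends only on ER (a constant) and reaeration,
so regressing the rate of O2 change on the saturation deficit
(O2sat - O2) gives KO2 as the slope, converted to K600 by Schmidt
scaling at the window-mean temperature. Because the night shifts and
shrinks through the high-latitude summer, each night is scanned with six
staggered candidate windows; windows with R^2 <= 0.7 are dropped and the
best remaining one is kept. Nights shorter than 2 h yield no estimate.
Retained nightly K600 values are regressed on discharge to build the
site relation that supplies each day's informed K prior.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import solar
from .gas_physics import kgas_to_k600, o2_saturation, schmidt_o2

__all__ = [
    "RatingCurve",
    "NightWindow",
    "K600QRelation",
    "fit_rating_curve",
    "night_regression",
    "nightly_k600",
    "fit_k600_q",
]

#: Default filters for nightly estimates.
R2_MIN_NIGHT = 0.7
MIN_NIGHT_HOURS = 2.0
N_WINDOWS = 6
#: Rating-curve quality bar.
R2_MIN_RATING = 0.85


@dataclass(frozen=True)
class RatingCurve:
    """Linear depth-discharge rating Q = intercept + slope * depth."""

    intercept: float
    slope: float
    r2: float
    n: int
    r2_threshold: float = R2_MIN_RATING

    @property
    def meets_threshold(self) -> bool:
        return self.r2 > self.r2_threshold

    def discharge(self, depth):
        return self.intercept + self.slope * np.asarray(depth, dtype=float)


@dataclass(frozen=True)
class NightWindow:
    """One candidate night-time regression window and its fit."""

    start: dt.datetime
    end: dt.datetime
    n: int
    slope: float  # KO2, day^-1
    intercept: float
    r2: float
    k600: float  # slope converted by Schmidt scaling at window-mean T

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must follow start")


@dataclass(frozen=True)
class K600QRelation:
    """Site-level linear relation K600 = intercept + slope * Q.

    ``residual_sd`` is the SD of fit residuals and becomes the SD of the
    daily K prior; ``predict`` returns (mean, sd) for a discharge.
    """

    intercept: float
    slope: float
    residual_sd: float
    n: int
    r2: float
    stderr_slope: float

    def predict(self, Q) -> tuple:
        mean = self.intercept + self.slope * np.asarray(Q, dtype=float)
        return mean if mean.ndim else float(mean), self.residual_sd


def fit_rating_curve(depths, discharges) -> RatingCurve:
    """Ordinary least squares Q on depth from paired spot measurements."""
    depths = np.asarray(depths, dtype=float)
    discharges = np.asarray(discharges, dtype=float)
    if depths.size != discharges.size or depths.size < 3:
        raise ValueError("need at least 3 paired depth-discharge observations")
    if np.ptp(depths) == 0:
        raise ValueError("depth has no variation; rating curve is undetermined")
    res = stats.linregress(depths, discharges)
    return RatingCurve(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r2=float(res.rvalue**2),
        n=depths.size,
    )


def _binned_rate_and_deficit(
    o2: np.ndarray, deficit: np.ndarray, dt_days: float, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bin-mean O2 rates paired with the exactly matching deficit averages.

    With bins of ``m`` samples, the difference of consecutive bin means
    telescopes into a triangularly weighted sum of the one-step
    differences, and each one-step difference of the diel model is
    ER/z*dt + KO2*dt*deficit[t]. Pairing the binned rate with the same
    triangular weighting of the deficit therefore recovers slope = KO2
    with no discretization bias at any bin size (m=1 reduces to forward
    differences on the left-endpoint deficit). Binning averages down
    sensor noise, which pointwise differencing amplifies.
    """
    n_use = (o2.size // m) * m
    bins = o2[:n_use].reshape(-1, m).mean(axis=1)
    rate = np.diff(bins) / (m * dt_days)
    weights = np.minimum(np.arange(1, 2 * m), np.arange(2 * m - 1, 0, -1)).astype(float)
    weights /= m * m
    k = bins.size
    w_deficit = np.array(
        [weights @ deficit[i * m : i * m + 2 * m - 1] for i in range(k - 1)]
    )
    return rate, w_deficit


def night_regression(
    o2,
    o2sat,
    temperature,
    dt_days: float,
    start: dt.datetime,
    end: dt.datetime,
    index: pd.DatetimeIndex | None = None,
    n_bins: int = 6,
    min_rate_points: int = 3,
) -> NightWindow:
    """Regress the rate of O2 change on the O2 deficit over one night window.

    The deficit convention is (O2sat - O2), so the slope is +KO2 in
    day^-1 and the intercept is ER/z. The window is split into about
    ``n_bins`` bins whose mean-to-mean rates are regressed on the
    matching deficit averages (see :func:`_binned_rate_and_deficit`).
    With an index given, ``o2``/``o2sat``/``temperature`` span a longer
    record and the window [start, end] is extracted; otherwise they are
    taken to be the window itself.
    """
    o2 = np.asarray(o2, dtype=float)
    o2sat = np.asarray(o2sat, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if index is not None:
        mask = (index >= start) & (index <= end)
        o2, o2sat, temperature = o2[mask], o2sat[mask], temperature[mask]
    if o2.size < 4:
        raise ValueError("night window needs at least 4 points")
    m = max(1, o2.size // n_bins)
    rate, deficit = _binned_rate_and_deficit(o2, o2sat - o2, dt_days, m)
    if rate.size < min_rate_points or np.ptp(deficit) == 0:
        raise ValueError("night window too short or deficit has no variation")
    res = stats.linregress(deficit, rate)
    ko2 = float(res.slope)
    k600 = float(kgas_to_k600(max(ko2, 0.0), schmidt_o2(temperature.mean())))
    return NightWindow(
        start=start,
        end=end,
        n=int(o2.size),
        slope=ko2,
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        k600=k600,
    )


def candidate_windows(
    night_start: dt.datetime, night_end: dt.datetime, n_windows: int = N_WINDOWS
):
    """Six equal, overlapping windows whose union covers the whole night.

    Each window spans two thirds of the night; starts are evenly spaced
    from sunset to sunrise minus the window length. Long overlapping
    windows keep enough leverage for the regression while still letting
    the scheme skip a corrupted end of the night.
    """
    night = night_end - night_start
    length = night * 2 / 3
    span = night - length
    return [
        (night_start + i * span / (n_windows - 1), night_start + i * span / (n_windows - 1) + length)
        for i in range(n_windows)
    ]


def nightly_k600(
    series_frame: pd.DataFrame,
    date: dt.date,
    latitude: float,
    longitude: float,
    r2_min: float = R2_MIN_NIGHT,
    min_night_hours: float = MIN_NIGHT_HOURS,
    n_windows: int = N_WINDOWS,
) -> NightWindow | None:
    """Best night-window K600 for the night following ``date``, or None.

    The night runs from this date's sunset to the next sunrise. No
    estimate is returned during polar day, for nights shorter than
    ``min_night_hours``, or when every candidate window has
    R^2 <= ``r2_min``. Among retained windows the highest R^2 wins
    (ties: longer window).
    """
    tonight = solar.sun_times(latitude, longitude, date)
    tomorrow = solar.sun_times(latitude, longitude, date + dt.timedelta(days=1))
    if tonight.polar_day or tonight.sunset is None or tomorrow.sunrise is None:
        return None
    night_start, night_end = tonight.sunset, tomorrow.sunrise
    if (night_end - night_start).total_seconds() / 3600.0 < min_night_hours:
        return None

    idx = series_frame.index
    dt_days = (idx[1] - idx[0]).total_seconds() / 86400.0
    o2 = series_frame["o2"].to_numpy()
    o2sat = o2_saturation(
        series_frame["temperature"].to_numpy(), series_frame["pressure"].to_numpy()
    )
    temp = series_frame["temperature"].to_numpy()

    best: NightWindow | None = None
    for start, end in candidate_windows(night_start, night_end, n_windows):
        mask = (idx >= start) & (idx <= end)
        # the window must lie inside the record, not hang off its edge
        expected = (end - start).total_seconds() / 86400.0 / dt_days
        if mask.sum() < max(4, int(0.9 * expected)):
            continue
        try:
            # demand >=5 regression points so the R^2 bar has teeth
            win = night_regression(
                o2[mask], o2sat[mask], temp[mask], dt_days, start, end,
                min_rate_points=5,
            )
        except ValueError:
            continue
        if win.r2 <= r2_min or win.slope <= 0:
            continue
        if (
            best is None
            or win.r2 > best.r2
            or (win.r2 == best.r2 and (win.end - win.start) > (best.end - best.start))
        ):
            best = win
    return best


def fit_k600_q(k600_values, discharges) -> K600QRelation:
    """Linear K600-discharge relation from nightly estimates.

    Its ``predict`` supplies the (mean, SD) pair used as the daily K600
    prior, with SD the residual SD around the line.
    """
    k600_values = np.asarray(k600_values, dtype=float)
    discharges = np.asarray(discharges, dtype=float)
    if k600_values.size != discharges.size or k600_values.size < 3:
        raise ValueError("need at least 3 (K600, Q) pairs")
    res = stats.linregress(discharges, k600_values)
    pred = res.intercept + res.slope * discharges
    resid = k600_values - pred
    dof = max(k600_values.size - 2, 1)
    return K600QRelation(
        intercept=float(res.intercept),
        slope=float(res.slope),
        residual_sd=float(np.sqrt((resid @ resid) / dof)),
        n=int(k600_values.size),
        r2=float(res.rvalue**2),
        stderr_slope=float(res.stderr),
    )
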