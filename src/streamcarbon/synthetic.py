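"""Seeded virtual sensor deployments with known ground truth.

Emulates what a summer deployment in a high-latitude stream records:
10-minute O2, hourly-resolution-like temperature and pCO2, water depth
tied to a discharge rating, PAR from clear-sky solar geometry (including
midnight sun above the Arctic circle), and barometric pressure fixed by
site elevation. Dissolved O2 follows the same diel recursion the
metabolism model inverts (GPP distributed with PAR, constant ER, KO2
exchange); dissolved CO2 mirrors it mole-for-mole (respiration produces
what photosynthesis consumes) plus optional groundwater CO2 input
uncoupled from O2, and exchanges with a fixed-ppm atmosphere.

Every stochastic element flows from one integer seed, so a deployment is
bit-reproducible and each day's generating parameters are returned in a
truth ledger for recovery experiments.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .gas_physics import (
    barometric_pressure,
    co2_molar_to_ppm,
    co2_ppm_to_molar,
    k600_to_kgas,
    o2_saturation,
    schmidt_co2,
    schmidt_o2,
)
from .metabolism import o2_forward

__all__ = [
    "TrueParams",
    "SensorSeries",
    "DeploymentConfig",
    "simulate_par",
    "simulate_temperature",
    "simulate_o2",
    "simulate_co2",
    "simulate_discharge",
    "simulate_deployment",
    "recovery_experiment",
]

SENSOR_COLUMNS = (
    "o2",
    "pco2",
    "temperature",
    "depth",
    "par",
    "pressure",
    "discharge",
)


@dataclass(frozen=True)
class TrueParams:
    """Generating parameters of one simulated day.

    ``gpp_daily`` / ``er_daily`` in g O2 m^-2 day^-1 (ER <= 0), ``k600``
    in day^-1, ``depth`` in m, ``noise_sd`` the iid Gaussian O2 sensor
    noise in g m^-3, ``co2_groundwater_flux`` a constant external CO2
    input in g C m^-2 day^-1 (>= 0).
    """

    gpp_daily: float
    er_daily: float
    k600: float
    depth: float
    noise_sd: float = 0.0
    co2_groundwater_flux: float = 0.0

    def __post_init__(self) -> None:
        if self.gpp_daily < 0:
            raise ValueError("gpp_daily must be >= 0")
        if self.er_daily > 0:
            raise ValueError("er_daily must be <= 0 (consumption)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.noise_sd < 0 or self.co2_groundwater_flux < 0:
            raise ValueError("noise_sd and groundwater flux must be >= 0")


@dataclass
class SensorSeries:
    """One site's aligned sensor time series plus site metadata.

    ``frame`` is indexed by UTC timestamp at a uniform step and carries
    the columns o2 (g m^-3), pco2 (ppm), temperature (degC), depth (m),
    par (umol m^-2 s^-1), pressure (atm) and discharge (m^3 s^-1).
    """

    frame: pd.DataFrame
    site_id: str = "site"
    latitude: float = 68.35
    longitude: float = 18.8
    elevation: float = 400.0
    timestep_min: float = 10.0

    def __post_init__(self) -> None:
        missing = [c for c in SENSOR_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sensor frame missing columns: {missing}")
        deltas = np.diff(self.frame.index.view("int64"))
        if deltas.size and not (deltas == deltas[0]).all():
            raise ValueError("sensor timestamps must be uniformly spaced")
        if deltas.size:
            step_min = deltas[0] / 60e9
            if abs(step_min - self.timestep_min) > 1e-9:
                raise ValueError("frame spacing disagrees with timestep_min")
        for col in ("o2", "pco2", "depth", "par"):
            if (self.frame[col] < 0).any():
                raise ValueError(f"negative values in column {col!r}")

    @property
    def dt_days(self) -> float:
        return self.timestep_min / 1440.0

    def days(self):
        """Iterate (date, day_frame) over complete days."""
        steps = int(round(1440.0 / self.timestep_min))
        for date, grp in self.frame.groupby(self.frame.index.date):
            if len(grp) == steps:
                yield date, grp

    def to_csv(self, path) -> None:
        self.frame.rename_axis("timestamp").to_csv(path, date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_csv(cls, path, **metadata) -> "SensorSeries":
        frame = pd.read_csv(path, index_col="timestamp", parse_dates=True)
        return cls(frame=frame, **metadata)


@dataclass(frozen=True)
class DeploymentConfig:
    """Study conditions for a virtual deployment.

    Defaults describe a small, clearly heterotrophic subarctic stream in
    late summer: GPP well below |ER|, persistent CO2 supersaturation,
    discharge-dependent K600, modest O2 sensor noise.
    """

    site_id: str = "SYN1"
    latitude: float = 68.35
    longitude: float = 18.8
    elevation: float = 400.0
    start_date: dt.date = dt.date(2016, 8, 1)
    n_days: int = 10
    timestep_min: float = 10.0
    par_max: float = 1500.0  # clear-sky noon PAR, umol m^-2 s^-1
    temp_mean: float = 8.0
    temp_amplitude: float = 2.0
    # Discharge: lognormal AR(1) day-to-day around base_discharge.
    base_discharge: float = 0.10  # m^3 s^-1
    discharge_ar: float = 0.7
    discharge_log_sd: float = 0.15
    spate_days: tuple = ()
    spate_magnitude: float = 0.4  # peak fractional Q increase within a spate day
    depth_at_base: float = 0.30  # m at base_discharge (linear rating through 0)
    # K600 = k600_intercept + k600_q_slope * Q + Normal(0, k600_resid_sd)
    k600_intercept: float = 2.0
    k600_q_slope: float = 100.0  # day^-1 per m^3 s^-1
    k600_resid_sd: float = 1.0
    # Daily metabolic rates, g O2 m^-2 day^-1
    gpp_mean: float = 0.8
    gpp_sd: float = 0.3
    er_mean: float = -5.0
    er_sd: float = 1.0
    o2_noise_sd: float = 0.02  # g m^-3, iid Gaussian (optical DO logger precision)
    pco2_noise_sigma: float = 0.02  # multiplicative lognormal
    co2_groundwater_flux: float = 0.0  # g C m^-2 day^-1
    atm_co2_ppm: float = 380.0
    seed: int | None = None


def _day_index(date: dt.date, timestep_min: float) -> pd.DatetimeIndex:
    steps = int(round(1440.0 / timestep_min))
    if abs(steps * timestep_min - 1440.0) > 1e-9:
        raise ValueError("timestep must divide one day evenly")
    start = dt.datetime(date.year, date.month, date.day)
    return pd.date_range(start, periods=steps, freq=pd.Timedelta(minutes=timestep_min))


def simulate_par(
    latitude: float,
    date: dt.date,
    timestep_min: float = 10.0,
    longitude: float = 0.0,
    par_max: float = 1500.0,
) -> pd.Series:
    """Clear-sky PAR over one day: par_max * sin(solar elevation), else 0."""
    idx = _day_index(date, timestep_min)
    elev = np.array(
        [solar.solar_elevation(latitude, longitude, ts.to_pydatetime()) for ts in idx]
    )
    par = par_max * np.sin(np.deg2rad(np.clip(elev, 0.0, None)))
    return pd.Series(par, index=idx, name="par")


def simulate_temperature(
    date: dt.date,
    timestep_min: float = 10.0,
    mean: float = 8.0,
    amplitude: float = 2.0,
) -> pd.Series:
    """Sinusoidal diel water temperature, coolest at 05:00, warmest at 17:00."""
    idx = _day_index(date, timestep_min)
    hours = idx.hour + idx.minute / 60.0
    temp = mean + amplitude * np.sin(2.0 * np.pi * (hours - 11.0) / 24.0)
    return pd.Series(np.asarray(temp), index=idx, name="temperature")


def simulate_o2(
    params: TrueParams,
    par,
    temp,
    dt_days: float,
    pressure: float = 1.0,
    o2_init: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One day of dissolved O2 from the diel recursion plus sensor noise.

    The noise-free path is exactly the metabolism model's forward
    recursion (shared code); KO2 is obtained from k600 by Schmidt scaling
    at the day-mean temperature. ``o2_init`` defaults to the steady-state
    heterotrophic deficit below saturation.
    """
    par = np.asarray(par, dtype=float)
    temp = np.asarray(temp, dtype=float)
    o2sat = o2_saturation(temp, pressure)
    ko2 = float(k600_to_kgas(params.k600, schmidt_o2(temp.mean())))
    if o2_init is None:
        deficit = params.er_daily / (params.depth * ko2) if ko2 > 0 else 0.0
        o2_init = float(o2sat[0] + deficit)
    clean = o2_forward(
        params.gpp_daily,
        params.er_daily,
        ko2,
        params.depth,
        par,
        o2sat,
        dt_days,
        o2_init,
    )
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        clean = clean + rng.normal(0.0, params.noise_sd, clean.size)
    return np.clip(clean, 0.0, None)


def simulate_co2(
    params: TrueParams,
    par,
    temp,
    dt_days: float,
    atm_ppm: float = 380.0,
    co2_init_molar: float | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One day of water pCO2 (ppm) mirroring the O2 dynamics mole for mole.

    Per step, NEP removes/adds CO2 at -1x the molar O2 source, a constant
    groundwater flux adds CO2, and KCO2 relaxes the concentration toward
    equilibrium with ``atm_ppm``. Optional multiplicative lognormal
    sensor noise. Returns pCO2 in ppm.
    """
    par = np.asarray(par, dtype=float)
    temp = np.asarray(temp, dtype=float)
    n = par.size
    kco2 = float(k600_to_kgas(params.k600, schmidt_co2(temp.mean())))
    ceq = co2_ppm_to_molar(np.full(n, atm_ppm), temp)  # mol m^-3

    par_sum = par.sum()
    light = par / par_sum if par_sum > 0 else np.zeros(n)
    # molar NEP source per step (positive = CO2 produced), mol m^-3
    o2_source = (
        params.gpp_daily / params.depth
    ) * light + params.er_daily * dt_days / params.depth
    co2_source = -o2_source / 32.0
    gw = params.co2_groundwater_flux * dt_days / (12.0 * params.depth)

    if co2_init_molar is None:
        # supersaturated steady state supported by ER and groundwater
        daily_source = (
            -params.er_daily / 32.0 + params.co2_groundwater_flux / 12.0
        ) / params.depth
        offset = daily_source / kco2 if kco2 > 0 else 0.0
        co2_init_molar = float(ceq[0] + offset)

    conc = np.empty(n)
    conc[0] = co2_init_molar
    for t in range(1, n):
        conc[t] = max(
            0.0,
            conc[t - 1]
            + co2_source[t - 1]
            + gw
            + kco2 * (ceq[t - 1] - conc[t - 1]) * dt_days,
        )
    ppm = co2_molar_to_ppm(conc, temp)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        ppm = ppm * rng.lognormal(0.0, noise_sigma, n)
    return np.asarray(ppm)


def simulate_discharge(
    config: DeploymentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-timestep discharge (m^3 s^-1): daily log-AR(1) + optional spates.

    Daily values follow an AR(1) on log Q around the base flow and are
    linearly interpolated to the timestep; a spate day gets a triangular
    intra-day surge peaking at (1 + spate_magnitude) x.
    """
    steps = int(round(1440.0 / config.timestep_min))
    logq = np.empty(config.n_days + 1)
    logq[0] = 0.0
    for d in range(1, config.n_days + 1):
        logq[d] = config.discharge_ar * logq[d - 1] + rng.normal(
            0.0, config.discharge_log_sd
        )
    daily_q = config.base_discharge * np.exp(logq)
    x_nodes = np.arange(config.n_days + 1) * steps
    x = np.arange(config.n_days * steps)
    q = np.interp(x, x_nodes, daily_q)
    for d in config.spate_days:
        sl = slice(d * steps, (d + 1) * steps)
        ramp = 1.0 + config.spate_magnitude * np.bartlett(steps)
        q[sl] = q[sl] * ramp
    return q


def simulate_deployment(
    config: DeploymentConfig, seed: int | None = None
) -> tuple[SensorSeries, pd.DataFrame]:
    """Generate a full multi-day deployment and its ground-truth ledger.

    Returns the :class:`SensorSeries` and a per-day DataFrame with the
    generating gpp/er/k600/ko2/depth/noise/groundwater values. The same
    seed reproduces the series bit for bit.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    pressure = float(barometric_pressure(1.0, config.elevation))
    steps = int(round(1440.0 / config.timestep_min))
    dt_days = config.timestep_min / 1440.0

    q = simulate_discharge(config, rng)
    rating_slope = config.base_discharge / config.depth_at_base  # Q per m depth
    depth = q / rating_slope

    frames = []
    truth_rows = []
    o2_prev = None
    co2_prev_molar = None
    for d in range(config.n_days):
        date = config.start_date + dt.timedelta(days=d)
        par = simulate_par(
            config.latitude, date, config.timestep_min, config.longitude, config.par_max
        )
        temp = simulate_temperature(
            date, config.timestep_min, config.temp_mean, config.temp_amplitude
        )
        sl = slice(d * steps, (d + 1) * steps)
        q_day = q[sl]
        depth_day = depth[sl]
        k600 = max(
            0.1,
            config.k600_intercept
            + config.k600_q_slope * q_day.mean()
            + rng.normal(0.0, config.k600_resid_sd),
        )
        params = TrueParams(
            gpp_daily=max(0.0, rng.normal(config.gpp_mean, config.gpp_sd)),
            er_daily=min(0.0, rng.normal(config.er_mean, config.er_sd)),
            k600=k600,
            depth=float(depth_day.mean()),
            noise_sd=config.o2_noise_sd,
            co2_groundwater_flux=config.co2_groundwater_flux,
        )
        o2 = simulate_o2(
            params,
            par.to_numpy(),
            temp.to_numpy(),
            dt_days,
            pressure,
            o2_init=o2_prev,
            rng=rng,
        )
        pco2 = simulate_co2(
            params,
            par.to_numpy(),
            temp.to_numpy(),
            dt_days,
            atm_ppm=config.atm_co2_ppm,
            co2_init_molar=co2_prev_molar,
            noise_sigma=config.pco2_noise_sigma,
            rng=rng,
        )
        o2_prev = float(o2[-1])
        co2_prev_molar = float(
            co2_ppm_to_molar(pco2[-1], temp.to_numpy()[-1])
        )
        frames.append(
            pd.DataFrame(
                {
                    "o2": o2,
                    "pco2": pco2,
                    "temperature": temp.to_numpy(),
                    "depth": depth_day,
                    "par": par.to_numpy(),
                    "pressure": pressure,
                    "discharge": q_day,
                },
                index=par.index,
            )
        )
        truth_rows.append(
            {
                "date": date,
                "gpp": params.gpp_daily,
                "er": params.er_daily,
                "nep": params.gpp_daily + params.er_daily,
                "k600": params.k600,
                "ko2": float(
                    k600_to_kgas(params.k600, schmidt_o2(temp.to_numpy().mean()))
                ),
                "depth": params.depth,
                "discharge": float(q_day.mean()),
                "noise_sd": params.noise_sd,
                "co2_groundwater_flux": params.co2_groundwater_flux,
            }
        )

    series = SensorSeries(
        frame=pd.concat(frames),
        site_id=config.site_id,
        latitude=config.latitude,
        longitude=config.longitude,
        elevation=config.elevation,
        timestep_min=config.timestep_min,
    )
    truth = pd.DataFrame(truth_rows).set_index("date")
    return series, truth


def recovery_experiment(
    n_days: int = 20,
    seed: int = 0,
    noise_sd: float = 0.02,
    n_iter: int = 30_000,
    n_keep: int = 20_000,
    gpp_range: tuple = (0.5, 3.0),
    er_range: tuple = (-8.0, -1.0),
    k600_range: tuple = (5.0, 60.0),
    k_prior_rel_sd: float = 0.10,
    level: float = 0.95,
    latitude: float = 68.35,
    longitude: float = 18.8,
    depth: float = 0.3,
) -> pd.DataFrame:
    """Simulate independent site-days and refit them; score the recovery.

    Each day draws (GPP, ER, K600) uniformly from the given ranges,
    generates a noisy diel O2 curve, and refits it by Metropolis with an
    informed K prior (mean at truth, relative SD ``k_prior_rel_sd``, the
    quality a decent site K600-discharge relation delivers). Returns one
    row per day-parameter with truth, posterior mean and the
    ``level`` credible bounds, for coverage and accuracy summaries.
    """
    from .metabolism import MetabPriors, metropolis_fit

    ss = np.random.SeedSequence([seed, 714])
    rng = np.random.default_rng(ss)
    date = dt.date(2016, 8, 15)
    par = simulate_par(latitude, date, 10.0, longitude).to_numpy()
    temp = simulate_temperature(date, 10.0, mean=8.0, amplitude=2.0).to_numpy()
    pressure = float(barometric_pressure(1.0, 400.0))
    o2sat = o2_saturation(temp, pressure)
    dt_days = 10.0 / 1440.0
    lo = (1.0 - level) / 2.0
    q_lo, q_hi = round(lo, 3), round(1.0 - lo, 3)

    rows = []
    for day in range(n_days):
        truth = TrueParams(
            gpp_daily=float(rng.uniform(*gpp_range)),
            er_daily=float(rng.uniform(*er_range)),
            k600=float(rng.uniform(*k600_range)),
            depth=depth,
            noise_sd=noise_sd,
        )
        ko2_true = float(k600_to_kgas(truth.k600, schmidt_o2(temp.mean())))
        o2 = simulate_o2(truth, par, temp, dt_days, pressure, rng=rng)
        priors = MetabPriors(
            ko2_mean=ko2_true, ko2_sd=max(k_prior_rel_sd * ko2_true, 1e-3)
        )
        fit = metropolis_fit(
            o2, par, o2sat, depth, dt_days, priors,
            n_iter=n_iter, n_keep=n_keep,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for name, true_val, mean in (
            ("gpp", truth.gpp_daily, fit.gpp_mean),
            ("er", truth.er_daily, fit.er_mean),
            ("ko2", ko2_true, fit.ko2_mean),
        ):
            lo_q = fit.quantiles[name][q_lo]
            hi_q = fit.quantiles[name][q_hi]
            rows.append(
                {
                    "day": day,
                    "param": name,
                    "truth": true_val,
                    "posterior_mean": mean,
                    "ci_lo": lo_q,
                    "ci_hi": hi_q,
                    "covered": bool(lo_q <= true_val <= hi_q),
                    "rel_err": abs(mean - true_val) / abs(true_val),
                }
            )
    return pd.DataFrame(rows)
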