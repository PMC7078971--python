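"""End-to-end orchestration: sensors in, daily carbon budget out.

Chains the stages in the order a field campaign would: estimate the gas
exchange-discharge relation from night-time regressions, fit each day's
metabolism with the relation as the K prior, quality-filter the fitted
days, compute CO2 evasion and its diel metrics, and summarize per site.
Everything is deterministic for a fixed seed and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fluxes as flx
from . import k600 as k6
from . import metabolism as metab
from . import qc as qcmod
from .gas_physics import k600_to_kgas, o2_saturation, o2_to_carbon, schmidt_o2
from .synthetic import SensorSeries

__all__ = ["SiteConfig", "PipelineResult", "run_pipeline", "report", "cross_site_means"]

log = logging.getLogger("streamcarbon")


@dataclass(frozen=True)
class SiteConfig:
    """Pipeline settings for one site; defaults are the method's canon.

    QC thresholds (MAE 0.2 g m^-3, 10% depth range), night-regression
    filters (R^2 > 0.7, night >= 2 h), rating bar (R^2 > 0.85) and the
    MCMC schedule (150,000 iterations, last 100,000 kept).
    """

    site_id: str = "site"
    latitude: float = 68.35
    longitude: float = 18.8
    elevation: float = 400.0
    timestep_min: float = 10.0
    mae_max: float = 0.2
    depth_range_max_pct: float = 10.0
    night_r2_min: float = 0.7
    min_night_hours: float = 2.0
    rating_r2_min: float = 0.85
    n_iter: int = 150_000
    n_keep: int = 100_000
    atm_co2_ppm: float = 380.0
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SiteConfig":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class PipelineResult:
    daily: pd.DataFrame
    qc_table: pd.DataFrame
    k600_relation: k6.K600QRelation | None
    k600_estimates: pd.DataFrame
    fits: dict = field(repr=False, default_factory=dict)


def _day_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % 2**31)


def estimate_k600_relation(
    series: SensorSeries, config: SiteConfig
) -> tuple[k6.K600QRelation | None, pd.DataFrame]:
    """Nightly K600 estimates for every day, then the K600-Q regression."""
    rows = []
    for date, day_frame in series.days():
        win = k6.nightly_k600(
            series.frame,
            date,
            series.latitude,
            series.longitude,
            r2_min=config.night_r2_min,
            min_night_hours=config.min_night_hours,
        )
        if win is not None:
            rows.append(
                {
                    "date": date,
                    "k600": win.k600,
                    "r2": win.r2,
                    "discharge": float(day_frame["discharge"].mean()),
                }
            )
    estimates = pd.DataFrame(rows)
    relation = None
    if len(estimates) >= 3:
        relation = k6.fit_k600_q(
            estimates["k600"].to_numpy(), estimates["discharge"].to_numpy()
        )
    return relation, estimates


def run_pipeline(
    config: SiteConfig,
    series: SensorSeries,
    k600_relation: k6.K600QRelation | None = None,
) -> PipelineResult:
    """Run the whole inference chain for one site.

    A K600-discharge relation is estimated from the record's nights
    unless one is supplied (short records may have too few usable
    nights). Raises ``ValueError`` when neither is available.
    """
    required = set(("o2", "pco2", "temperature", "depth", "par", "pressure", "discharge"))
    missing = required - set(series.frame.columns)
    if missing:
        raise ValueError(f"sensor series missing columns: {sorted(missing)}")

    estimates = pd.DataFrame()
    if k600_relation is None:
        k600_relation, estimates = estimate_k600_relation(series, config)
        if k600_relation is None:
            raise ValueError(
                "fewer than 3 usable nights for the K600-discharge relation; "
                "supply k600_relation explicitly"
            )
    log.info("%s: K600-Q relation n=%d", config.site_id, k600_relation.n)

    dt_days = series.dt_days
    fits: dict = {}
    depth_by_day: dict = {}
    flux_by_day: dict = {}
    for i, (date, day) in enumerate(series.days()):
        temp = day["temperature"].to_numpy()
        o2sat = o2_saturation(temp, day["pressure"].to_numpy())
        q_mean = float(day["discharge"].mean())
        k600_mean, k600_sd = k600_relation.predict(q_mean)
        sc = schmidt_o2(temp.mean())
        scale = float(k600_to_kgas(1.0, sc))
        priors = metab.MetabPriors(
            ko2_mean=float(k600_mean) * scale,
            ko2_sd=max(float(k600_sd) * scale, 1e-6),
        )
        fit = metab.metropolis_fit(
            day["o2"].to_numpy(),
            day["par"].to_numpy(),
            o2sat,
            float(day["depth"].mean()),
            dt_days,
            priors,
            n_iter=config.n_iter,
            n_keep=config.n_keep,
            seed=_day_seed(config.seed, i),
            temperature_mean=float(temp.mean()),
        )
        fits[date] = fit
        depth_by_day[date] = day["depth"].to_numpy()
        # per-timestep K600 from the relation and the concurrent discharge
        k600_series, _ = k600_relation.predict(day["discharge"].to_numpy())
        flux_by_day[date] = flx.daily_flux_record(
            day,
            k600=np.maximum(k600_series, 0.0),
            latitude=series.latitude,
            longitude=series.longitude,
            atm_ppm=config.atm_co2_ppm,
        )

    thresholds = qcmod.QCThresholds(
        mae_max=config.mae_max, depth_range_max_pct=config.depth_range_max_pct
    )
    kept, qc_table = qcmod.apply_qc(fits, depth_by_day, thresholds)
    for _, row in qc_table[~qc_table["keep"]].iterrows():
        log.info("%s: day %s discarded (%s)", config.site_id, row["day"], row["violated"])
    log.info(
        "%s: %d of %d days kept by QC", config.site_id, len(kept), len(fits)
    )

    rows = []
    for date, fit in fits.items():
        cfit = metab.daily_rates_to_carbon(fit)
        fr = flux_by_day[date]
        keep = date in kept
        rows.append(
            {
                "site": config.site_id,
                "date": date,
                "gpp_gC": cfit.gpp_mean,
                "er_gC": cfit.er_mean,
                "nep_gC": cfit.nep_mean,
                "gpp_sd_gC": cfit.gpp_sd,
                "er_sd_gC": cfit.er_sd,
                "k600": fit.k600_mean,
                "ko2": fit.ko2_mean,
                "evasion_gC": fr.mean_evasion,
                "delta_co2_ppm": fr.delta_co2,
                "diel_evasion_change_gC": fr.diel_evasion_change,
                "noon_evasion_gC": fr.noon_evasion,
                "midnight_evasion_gC": fr.midnight_evasion,
                "mae": fit.mae,
                "acceptance_rate": fit.acceptance_rate,
                "qc_keep": keep,
            }
        )
    daily = pd.DataFrame(rows)
    return PipelineResult(
        daily=daily,
        qc_table=qc_table,
        k600_relation=k600_relation,
        k600_estimates=estimates,
        fits=fits,
    )


def report(daily: pd.DataFrame, qc_only: bool = True) -> pd.DataFrame:
    """Per-site summary of the daily results table.

    For each site: number of QC-kept days, means and 0.05-0.95 quantiles
    (linear-interpolation definition) of NEP, GPP, ER and evasion
    (g C m^-2 day^-1), mean noon/midnight evasion, and the median
    NEP-to-evasion percentage (-NEP / evasion x 100).
    """
    frame = daily[daily["qc_keep"]] if qc_only and "qc_keep" in daily else daily
    if frame.empty:
        raise ValueError("no days to summarize")
    out = []
    for site, grp in frame.groupby("site"):
        row = {"site": site, "n_days": len(grp)}
        for col, name in [
            ("nep_gC", "nep"),
            ("gpp_gC", "gpp"),
            ("er_gC", "er"),
            ("evasion_gC", "evasion"),
        ]:
            vals = grp[col].to_numpy()
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_q05"] = float(np.quantile(vals, 0.05))
            row[f"{name}_q95"] = float(np.quantile(vals, 0.95))
        row["noon_evasion"] = float(grp["noon_evasion_gC"].mean())
        row["midnight_evasion"] = float(grp["midnight_evasion_gC"].mean())
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = -grp["nep_gC"].to_numpy() / grp["evasion_gC"].to_numpy() * 100.0
        row["nep_evasion_pct_median"] = float(np.nanmedian(frac))
        out.append(row)
    return pd.DataFrame(out)


def cross_site_means(
    site_table: pd.DataFrame,
    columns=("er_mean", "gpp_mean", "evasion_mean"),
    weight_col: str = "n_days",
) -> dict:
    """Day-count-weighted cross-site averages of per-site mean columns."""
    w = site_table[weight_col].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    return {
        col: float(np.average(site_table[col].to_numpy(dtype=float), weights=w))
        for col in columns
    }
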