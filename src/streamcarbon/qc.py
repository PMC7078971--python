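"""Day-level quality control of fitted metabolism days.

Two automated rules, applied per day with strict inequalities:

* model fit: mean absolute error between observed and posterior-mean
  modelled O2 larger than 0.2 g m^-3 discards the day;
* stationarity: the within-day depth range exceeding 10% of the daily
  mean depth discards the day (depth is the proxy for K600, which the
  diel model assumes constant over the day).

A day is kept only if every rule passes; the report table names the
violated rule for each discarded day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QCThresholds", "QCReport", "mae", "depth_stability", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    mae_max: float = 0.2  # g O2 m^-3, strict
    depth_range_max_pct: float = 10.0  # % of daily mean depth, strict


@dataclass(frozen=True)
class QCReport:
    """Per-day QC outcome."""

    day: object
    mae: float
    depth_range_pct: float
    mae_ok: bool
    depth_ok: bool

    @property
    def keep(self) -> bool:
        return self.mae_ok and self.depth_ok

    @property
    def violated(self) -> str:
        rules = []
        if not self.mae_ok:
            rules.append("mae")
        if not self.depth_ok:
            rules.append("depth_change")
        return "+".join(rules) if rules else ""


def mae(observed, modelled) -> float:
    """Mean absolute error between observed and modelled series."""
    observed = np.asarray(observed, dtype=float)
    modelled = np.asarray(modelled, dtype=float)
    if observed.shape != modelled.shape:
        raise ValueError("series must have equal length")
    return float(np.mean(np.abs(observed - modelled)))


def depth_stability(depth) -> float:
    """Within-day depth variability: 100 * (max - min) / mean, %."""
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("depths must be positive")
    return float(100.0 * np.ptp(depth) / depth.mean())


def apply_qc(
    day_fits: dict,
    depth_by_day: dict,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[dict, pd.DataFrame]:
    """Filter a {day: DayFit} mapping by both rules.

    ``depth_by_day`` maps each day to its depth series. Returns the kept
    fits and a QC table (one row per day: metrics, per-rule flags, the
    overall keep flag and the violated rule names). Idempotent: the kept
    set passes unchanged through a second application.
    """
    kept = {}
    rows = []
    for day, fit in day_fits.items():
        range_pct = depth_stability(depth_by_day[day])
        rep = QCReport(
            day=day,
            mae=fit.mae,
            depth_range_pct=range_pct,
            mae_ok=fit.mae <= thresholds.mae_max,
            depth_ok=range_pct <= thresholds.depth_range_max_pct,
        )
        if rep.keep:
            kept[day] = fit
        rows.append(
            {
                "day": day,
                "mae": rep.mae,
                "depth_range_pct": rep.depth_range_pct,
                "mae_ok": rep.mae_ok,
                "depth_ok": rep.depth_ok,
                "keep": rep.keep,
                "violated": rep.violated,
            }
        )
    return kept, pd.DataFrame(rows)
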