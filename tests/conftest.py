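import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import streamcarbon as sc
from streamcarbon.gas_physics import o2_saturation

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

DT_DAYS = 10.0 / 1440.0


@pytest.fixture(scope="session")
def standard_day():
    """One deterministic synthetic day of forcing (145 samples at 10 min)."""
    n = 145
    t = np.arange(n) / 144.0
    par = np.maximum(0.0, np.sin((t - 0.25) * 2 * np.pi)) * 1200.0
    temp = 8.0 + 2.0 * np.sin((t - 0.6) * 2 * np.pi)
    o2sat = o2_saturation(temp, 0.95)
    return {"par": par, "temp": temp, "o2sat": o2sat, "dt": 1.0 / 144.0, "z": 0.3}


@pytest.fixture(scope="session")
def august_deployment():
    """A 10-day late-August deployment with real nights, default noise."""
    cfg = sc.DeploymentConfig(n_days=10, start_date=dt.date(2016, 8, 10), seed=11)
    series, truth = sc.simulate_deployment(cfg, seed=11)
    return cfg, series, truth


@pytest.fixture(scope="session")
def noisefree_deployment():
    """A noise-free 6-day deployment for exact-recovery checks."""
    cfg = sc.DeploymentConfig(
        n_days=6,
        start_date=dt.date(2016, 8, 10),
        seed=5,
        o2_noise_sd=0.0,
        pco2_noise_sigma=0.0,
        discharge_log_sd=0.0,
        k600_resid_sd=0.0,
        gpp_sd=0.0,
        er_sd=0.0,
    )
    series, truth = sc.simulate_deployment(cfg, seed=5)
    return cfg, series, truth
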