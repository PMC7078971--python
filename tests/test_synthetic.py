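"""Solar geometry and the synthetic deployment generator."""

import datetime as dt

import numpy as np
import pytest

import streamcarbon as sc
from streamcarbon import solar
from streamcarbon.gas_physics import co2_ppm_to_molar, o2_saturation
from streamcarbon.metabolism import o2_forward
from streamcarbon.synthetic import (
    DeploymentConfig,
    TrueParams,
    simulate_co2,
    simulate_deployment,
    simulate_o2,
    simulate_par,
    simulate_temperature,
)

DT = 10.0 / 1440.0


class TestSolar:
    def test_midnight_sun_above_arctic_circle(self):
        st = solar.sun_times(68.35, 18.8, dt.date(2016, 6, 21))
        assert st.polar_day and st.day_length_hours == 24.0

    def test_polar_night_in_winter(self):
        assert solar.sun_times(68.35, 18.8, dt.date(2016, 12, 21)).polar_night

    def test_equator_equinox_half_day(self):
        st = solar.sun_times(0.0, 0.0, dt.date(2016, 3, 20))
        assert st.day_length_hours == pytest.approx(12.0, abs=0.3)

    def test_night_reaches_two_hours_in_late_july(self):
        # at the study latitude usable nights only begin in late July
        july20 = solar.sun_times(68.35, 18.8, dt.date(2016, 7, 20))
        july28 = solar.sun_times(68.35, 18.8, dt.date(2016, 7, 28))
        assert july20.night_length_hours < 2.0 < july28.night_length_hours

    def test_elevation_peaks_at_solar_noon(self):
        st = solar.sun_times(68.35, 18.8, dt.date(2016, 8, 15))
        at = lambda t: solar.solar_elevation(68.35, 18.8, t)
        assert at(st.solar_noon) > at(st.solar_noon + dt.timedelta(hours=3))
        assert at(st.solar_noon) > at(st.solar_noon - dt.timedelta(hours=3))


class TestPar:
    def test_midnight_sun_par_always_positive(self):
        par = simulate_par(68.35, dt.date(2016, 6, 21), 10.0, longitude=18.8)
        assert (par > 0).all()

    def test_equator_equinox_half_day_of_light(self):
        par = simulate_par(0.0, dt.date(2016, 3, 20), 10.0)
        frac = (par > 0).mean()
        assert 0.45 < frac < 0.55

    def test_daily_sum_positive_and_finite(self):
        par = simulate_par(68.35, dt.date(2016, 8, 20), 10.0, longitude=18.8)
        assert 0 < par.sum() < np.inf


class TestO2Simulation:
    def test_no_processes_constant_series(self, standard_day):
        p = TrueParams(gpp_daily=0.0, er_daily=0.0, k600=0.0, depth=0.3)
        o2 = simulate_o2(p, standard_day["par"], standard_day["temp"], DT, o2_init=9.0)
        np.testing.assert_allclose(o2, 9.0)

    def test_pure_reaeration_monotone_approach_to_saturation(self, standard_day):
        p = TrueParams(gpp_daily=0.0, er_daily=0.0, k600=10.0, depth=0.3)
        temp = np.full(145, 8.0)
        sat = float(o2_saturation(8.0, 1.0))
        o2 = simulate_o2(p, np.zeros(145), temp, DT, o2_init=sat - 2.0)
        assert np.all(np.diff(o2) > 0)
        assert np.all(o2 < sat)
        assert o2[-1] == pytest.approx(sat, abs=0.2)

    def test_single_reaeration_step_value(self):
        # O2=9, O2sat=10, KO2=10/day, dt=1/144 -> 9 + 10*1*(1/144)
        out = o2_forward(0.0, 0.0, 10.0, 0.5, np.zeros(2), np.full(2, 10.0), 1 / 144, 9.0)
        assert out[1] == pytest.approx(9.0694, abs=1e-4)

    def test_noise_free_simulation_equals_forward_model(self, standard_day):
        p = TrueParams(gpp_daily=2.0, er_daily=-5.0, k600=15.0, depth=0.3)
        o2 = simulate_o2(p, standard_day["par"], standard_day["temp"], DT, pressure=0.95)
        ko2 = sc.k600_to_kgas(p.k600, sc.schmidt_o2(standard_day["temp"].mean()))
        direct = o2_forward(
            p.gpp_daily, p.er_daily, float(ko2), p.depth,
            standard_day["par"], standard_day["o2sat"], DT, o2[0],
        )
        np.testing.assert_allclose(o2, direct, rtol=1e-12)


class TestCO2Simulation:
    def test_equilibrium_stays_at_atmospheric(self, standard_day):
        p = TrueParams(gpp_daily=0.0, er_daily=0.0, k600=10.0, depth=0.3)
        ppm = simulate_co2(p, standard_day["par"], np.full(145, 8.0), DT, atm_ppm=380.0)
        np.testing.assert_allclose(ppm, 380.0, rtol=1e-9)

    def test_heterotrophy_keeps_water_supersaturated(self, standard_day):
        p = TrueParams(gpp_daily=0.0, er_daily=-5.0, k600=10.0, depth=0.3)
        ppm = simulate_co2(p, standard_day["par"], standard_day["temp"], DT, atm_ppm=380.0)
        assert (ppm > 380.0).all()

    def test_molar_conservation_without_exchange(self, standard_day):
        # no gas exchange, no groundwater: O2/32 + CO2 is conserved
        p = TrueParams(gpp_daily=2.0, er_daily=-2.5, k600=0.0, depth=0.5)
        o2 = simulate_o2(p, standard_day["par"], standard_day["temp"], DT, o2_init=9.0)
        ppm = simulate_co2(
            p, standard_day["par"], standard_day["temp"], DT,
            co2_init_molar=0.05,
        )
        co2 = np.array(
            [co2_ppm_to_molar(v, t) for v, t in zip(ppm, standard_day["temp"])]
        )
        total = o2 / 32.0 + co2
        np.testing.assert_allclose(total, total[0], rtol=1e-9)

    def test_groundwater_flux_decouples_co2_from_o2(self, standard_day):
        # with groundwater CO2 the evaded carbon must exceed |NEP|
        p0 = TrueParams(gpp_daily=0.5, er_daily=-4.0, k600=12.0, depth=0.3)
        pg = TrueParams(
            gpp_daily=0.5, er_daily=-4.0, k600=12.0, depth=0.3,
            co2_groundwater_flux=1.0,
        )
        ppm0 = simulate_co2(p0, standard_day["par"], standard_day["temp"], DT)
        ppmg = simulate_co2(pg, standard_day["par"], standard_day["temp"], DT)
        assert ppmg.mean() > ppm0.mean()


class TestDeployment:
    def test_same_seed_bitwise_identical(self):
        cfg = DeploymentConfig(n_days=3, start_date=dt.date(2016, 8, 10))
        s1, t1 = simulate_deployment(cfg, seed=42)
        s2, t2 = simulate_deployment(cfg, seed=42)
        assert s1.frame.equals(s2.frame)
        assert t1.equals(t2)

    def test_different_seed_differs(self):
        cfg = DeploymentConfig(n_days=2, start_date=dt.date(2016, 8, 10))
        s1, _ = simulate_deployment(cfg, seed=1)
        s2, _ = simulate_deployment(cfg, seed=2)
        assert not s1.frame["o2"].equals(s2.frame["o2"])

    def test_noise_free_day_refit_recovers_rates(self, noisefree_deployment):
        # least-squares refit with K fixed at truth recovers GPP and ER to 1%
        from scipy.optimize import least_squares

        cfg, series, truth = noisefree_deployment
        date, day = next(iter(series.days()))
        row = truth.loc[date]
        o2 = day["o2"].to_numpy()
        par = day["par"].to_numpy()
        o2sat = o2_saturation(day["temperature"].to_numpy(), day["pressure"].to_numpy())

        def resid(theta):
            model = o2_forward(
                theta[0], theta[1], row["ko2"], row["depth"], par, o2sat, DT, o2[0]
            )
            return o2 - model

        fit = least_squares(resid, x0=[1.0, -3.0])
        assert fit.x[0] == pytest.approx(row["gpp"], rel=0.01, abs=1e-3)
        assert fit.x[1] == pytest.approx(row["er"], rel=0.01)

    def test_truth_ledger_matches_config_statistics(self, august_deployment):
        cfg, series, truth = august_deployment
        assert len(truth) == cfg.n_days
        assert (truth["gpp"] >= 0).all()
        assert (truth["er"] <= 0).all()
        assert (truth["k600"] > 0).all()

    def test_csv_round_trip(self, tmp_path, august_deployment):
        _, series, _ = august_deployment
        path = tmp_path / "sensors.csv"
        series.to_csv(path)
        back = sc.SensorSeries.from_csv(path, timestep_min=10.0)
        np.testing.assert_allclose(
            back.frame["o2"].to_numpy(), series.frame["o2"].to_numpy(), rtol=1e-9
        )

    def test_validation_rejects_ragged_clock(self, august_deployment):
        _, series, _ = august_deployment
        bad = series.frame.iloc[[0, 1, 2, 5, 9]]
        with pytest.raises(ValueError):
            sc.SensorSeries(frame=bad, timestep_min=10.0)


def test_temperature_diel_cycle_amplitude():
    temp = simulate_temperature(dt.date(2016, 8, 10), 10.0, mean=8.0, amplitude=2.0)
    assert temp.mean() == pytest.approx(8.0, abs=0.01)
    assert temp.max() - temp.min() == pytest.approx(4.0, abs=0.05)
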