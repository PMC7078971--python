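"""Forward diel O2 model, posterior density and the Metropolis fit."""

import numpy as np
import pytest

from streamcarbon.metabolism import (
    DayFit,
    MetabPriors,
    daily_rates_to_carbon,
    log_posterior,
    metropolis_fit,
    o2_forward,
)

DT = 1.0 / 144.0


def _simulated_obs(standard_day, gpp, er, ko2, noise=0.0, seed=0, o2_init=None):
    d = standard_day
    if o2_init is None:
        o2_init = d["o2sat"][0] - 0.5
    clean = o2_forward(gpp, er, ko2, d["z"], d["par"], d["o2sat"], d["dt"], o2_init)
    if noise:
        clean = clean + np.random.default_rng(seed).normal(0, noise, clean.size)
    return clean


class TestForwardModel:
    def test_all_zero_parameters_constant(self, standard_day):
        d = standard_day
        out = o2_forward(0.0, 0.0, 0.0, d["z"], d["par"], d["o2sat"], d["dt"], 8.5)
        np.testing.assert_allclose(out, 8.5)

    def test_dark_respiration_step_decrement(self):
        # ER*dt/z = -4.8/(144*0.5) = -0.0667 g m^-3 per step
        out = o2_forward(0.0, -4.8, 0.0, 0.5, np.zeros(4), np.full(4, 10.0), DT, 9.0)
        np.testing.assert_allclose(np.diff(out), -0.0667, atol=1e-4)

    def test_refit_of_generated_series_is_identical(self, standard_day):
        d = standard_day
        a = o2_forward(2.0, -5.0, 15.0, d["z"], d["par"], d["o2sat"], d["dt"], 9.0)
        b = o2_forward(2.0, -5.0, 15.0, d["z"], d["par"], d["o2sat"], d["dt"], 9.0)
        np.testing.assert_allclose(a, b, rtol=1e-15)

    def test_depth_must_be_positive(self, standard_day):
        d = standard_day
        with pytest.raises(ValueError):
            o2_forward(1.0, -5.0, 10.0, 0.0, d["par"], d["o2sat"], d["dt"], 9.0)

    def test_gpp_without_light_rejected(self):
        with pytest.raises(ValueError):
            o2_forward(1.0, 0.0, 0.0, 0.3, np.zeros(10), np.full(10, 10.0), DT, 9.0)


class TestLogPosterior:
    def test_flat_likelihood_maximized_at_prior_means(self, standard_day):
        from scipy.optimize import minimize

        d = standard_day
        obs = _simulated_obs(d, 2.0, -5.0, 15.0)
        pri = MetabPriors(ko2_mean=15.0, ko2_sd=2.0)
        # enormous observation error makes the likelihood flat in theta
        neg = lambda th: -log_posterior(
            (th[0], th[1], th[2], 1e4), obs, d["par"], d["o2sat"], d["z"], d["dt"], pri
        )
        res = minimize(neg, x0=[0.0, -3.0, 14.0], method="Nelder-Mead")
        np.testing.assert_allclose(res.x, [1.0, -5.0, 15.0], atol=0.05)

    def test_noise_free_grid_search_peaks_at_truth(self, standard_day):
        d = standard_day
        truth = (2.0, -5.0, 15.0)
        obs = _simulated_obs(d, *truth)
        pri = MetabPriors(ko2_mean=15.0, ko2_sd=2.0)
        grid = [
            (g, e, k)
            for g in (1.0, 2.0, 3.0)
            for e in (-6.0, -5.0, -4.0)
            for k in (10.0, 15.0, 20.0)
        ]
        scores = {
            th: log_posterior(
                (*th, 0.05), obs, d["par"], d["o2sat"], d["z"], d["dt"], pri
            )
            for th in grid
        }
        assert max(scores, key=scores.get) == truth

    def test_density_falls_moving_away_from_optimum(self, standard_day):
        d = standard_day
        obs = _simulated_obs(d, 2.0, -5.0, 15.0)
        pri = MetabPriors(ko2_mean=15.0, ko2_sd=2.0)
        at = lambda g, e, k: log_posterior(
            (g, e, k, 0.05), obs, d["par"], d["o2sat"], d["z"], d["dt"], pri
        )
        base = at(2.0, -5.0, 15.0)
        for deltas in ([0.2, 0, 0], [0, 0.3, 0], [0, 0, 1.0]):
            seq = [
                at(2.0 + s * deltas[0], -5.0 + s * deltas[1], 15.0 + s * deltas[2])
                for s in (1, 2, 3)
            ]
            assert base > seq[0] > seq[1] > seq[2]

    def test_out_of_support(self, standard_day):
        d = standard_day
        obs = _simulated_obs(d, 2.0, -5.0, 15.0)
        pri = MetabPriors(ko2_mean=15.0, ko2_sd=2.0)
        assert log_posterior((1, -5, -1.0, 0.1), obs, d["par"], d["o2sat"], d["z"], d["dt"], pri) == -np.inf
        assert log_posterior((1, -5, 15.0, 0.0), obs, d["par"], d["o2sat"], d["z"], d["dt"], pri) == -np.inf


class TestMetropolisFit:
    def test_zero_noise_tight_k_prior_recovers_truth(self, standard_day):
        d = standard_day
        obs = _simulated_obs(d, 2.0, -5.0, 15.0)
        pri = MetabPriors(ko2_mean=15.0, ko2_sd=1e-6)
        fit = metropolis_fit(
            obs, d["par"], d["o2sat"], d["z"], d["dt"], pri,
            n_iter=15000, n_keep=8000, seed=2,
        )
        assert fit.gpp_mean == pytest.approx(2.0, rel=0.01)
        assert fit.er_mean == pytest.approx(-5.0, rel=0.01)
        assert fit.ko2_mean == pytest.approx(15.0, rel=0.01)
        assert fit.nep_mean == pytest.approx(fit.gpp_mean + fit.er_mean, rel=1e-9)

    def test_seed_reproducibility_bitwise(self, standard_day):
        d = standard_day
        obs = _simulated_obs(d, 2.0, -5.0, 15.0, noise=0.05, seed=5)
        pri = MetabPriors(ko2_mean=15.0, ko2_sd=1.5)
        kw = dict(n_iter=6000, n_keep=3000, seed=9, return_draws=True)
        f1 = metropolis_fit(obs, d["par"], d["o2sat"], d["z"], d["dt"], pri, **kw)
        f2 = metropolis_fit(obs, d["par"], d["o2sat"], d["z"], d["dt"], pri, **kw)
        np.testing.assert_array_equal(f1.draws, f2.draws)
        assert f1.gpp_mean == f2.gpp_mean

    def test_acceptance_rate_within_bounds_after_tuning(self, standard_day):
        d = standard_day
        obs = _simulated_obs(d, 2.0, -5.0, 15.0, noise=0.05, seed=1)
        pri = MetabPriors(ko2_mean=15.0, ko2_sd=1.5)
        fit = metropolis_fit(
            obs, d["par"], d["o2sat"], d["z"], d["dt"], pri,
            n_iter=20000, n_keep=10000, seed=3,
        )
        assert 0.1 <= fit.acceptance_rate <= 0.6
        assert not fit.accept_warning

    def test_equifinality_guard_broad_k_prior_widens_posterior(self, standard_day):
        d = standard_day
        obs = _simulated_obs(d, 2.0, -5.0, 15.0, noise=0.05, seed=8)
        informed = MetabPriors(ko2_mean=15.0, ko2_sd=0.8)
        broad = informed.widened(10.0)
        kw = dict(n_iter=25000, n_keep=12000, seed=4)
        f_inf = metropolis_fit(obs, d["par"], d["o2sat"], d["z"], d["dt"], informed, **kw)
        f_broad = metropolis_fit(obs, d["par"], d["o2sat"], d["z"], d["dt"], broad, **kw)
        assert f_broad.ko2_sd > f_inf.ko2_sd

    def test_posterior_mae_bounded_by_noise(self, standard_day):
        d = standard_day
        noise = 0.05
        obs = _simulated_obs(d, 2.0, -5.0, 15.0, noise=noise, seed=6)
        pri = MetabPriors(ko2_mean=15.0, ko2_sd=1.0)
        fit = metropolis_fit(
            obs, d["par"], d["o2sat"], d["z"], d["dt"], pri,
            n_iter=15000, n_keep=8000, seed=5,
        )
        assert fit.mae <= 2.0 * noise

    def test_gpp_posterior_mass_below_zero_is_negligible(self, standard_day):
        d = standard_day
        obs = _simulated_obs(d, 1.5, -5.0, 15.0, noise=0.02, seed=7)
        pri = MetabPriors(ko2_mean=15.0, ko2_sd=1.0)
        fit = metropolis_fit(
            obs, d["par"], d["o2sat"], d["z"], d["dt"], pri,
            n_iter=15000, n_keep=8000, seed=6, return_draws=True,
        )
        assert (fit.draws[:, 0] < 0).mean() < 0.01

    def test_invalid_schedule_rejected(self, standard_day):
        d = standard_day
        obs = _simulated_obs(d, 2.0, -5.0, 15.0)
        pri = MetabPriors(ko2_mean=15.0, ko2_sd=1.0)
        with pytest.raises(ValueError):
            metropolis_fit(obs, d["par"], d["o2sat"], d["z"], d["dt"], pri,
                           n_iter=1000, n_keep=2000)


class TestCarbonConversion:
    def _fit(self, gpp=0.56, er=-7.0):
        q = {0.025: 0.0, 0.05: 0.0, 0.5: 0.0, 0.95: 0.0, 0.975: 0.0}
        return DayFit(
            gpp_mean=gpp, gpp_sd=0.1, er_mean=er, er_sd=0.2,
            ko2_mean=12.0, ko2_sd=0.5, sigma_mean=0.05,
            nep_mean=gpp + er, nep_sd=0.2, k600_mean=11.0,
            quantiles={"gpp": dict(q), "er": dict(q), "nep": dict(q),
                       "ko2": dict(q), "sigma": dict(q)},
            mae=0.02, acceptance_rate=0.3, n_kept=1000, accept_warning=False,
        )

    def test_table_magnitudes(self):
        fit = daily_rates_to_carbon(self._fit())
        assert fit.gpp_mean == pytest.approx(0.21, abs=0.005)
        assert fit.er_mean == pytest.approx(-2.63, abs=0.005)
        assert fit.units == "g C m-2 d-1"

    def test_nep_additivity_preserved(self):
        fit = daily_rates_to_carbon(self._fit(gpp=1.2, er=-4.0))
        assert fit.nep_mean == pytest.approx(fit.gpp_mean + fit.er_mean, rel=1e-12)

    def test_idempotent(self):
        once = daily_rates_to_carbon(self._fit())
        twice = daily_rates_to_carbon(once)
        assert twice.gpp_mean == once.gpp_mean
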