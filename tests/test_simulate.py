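"""Synthetic-data generators: determinism, parameter validation, and
moment agreement with the generative model."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import farrec
from farrec.simulate import recruitment_mean


class TestDeterminism:
    def test_every_generator_reproduces_under_fixed_seed(self):
        p = farrec.ClimateSimParams(n_years_obs=10, n_models=2, n_years_pi=10,
                                    n_years_proj=5, seed=3)
        a, b = farrec.simulate_climate(p), farrec.simulate_climate(p)
        pd.testing.assert_series_equal(a.observed, b.observed)
        for ma, mb in zip(a.models, b.models):
            pd.testing.assert_series_equal(ma.preindustrial, mb.preindustrial)
            pd.testing.assert_series_equal(ma.projection, mb.projection)

        rp = farrec.RecruitSimParams(seed=4)
        far = np.linspace(0, 1, 12)
        pd.testing.assert_series_equal(
            farrec.simulate_recruitment(far, rp),
            farrec.simulate_recruitment(far, rp),
        )
        sp = farrec.SeineSimParams(n_years=2, n_bays=2, n_sites_per_bay=2,
                                   sets_per_site_year=2, seed=5)
        pd.testing.assert_frame_equal(
            farrec.simulate_seine(sp), farrec.simulate_seine(sp)
        )
        trend = np.arange(6.0)
        pd.testing.assert_frame_equal(
            farrec.simulate_survey_panel(trend, [1, 0.5], [0.1, 0.1],
                                         [0.2, 0.2], seed=6),
            farrec.simulate_survey_panel(trend, [1, 0.5], [0.1, 0.1],
                                         [0.2, 0.2], seed=6),
        )


class TestClimate:
    def test_invalid_params_rejected_by_name(self):
        with pytest.raises(ValueError, match="ar1_coef"):
            farrec.ClimateSimParams(ar1_coef=1.2)
        with pytest.raises(ValueError, match="noise_sd"):
            farrec.ClimateSimParams(noise_sd=0.0)
        with pytest.raises(ValueError, match="n_years_pi"):
            farrec.ClimateSimParams(n_years_pi=1)
        with pytest.raises(ValueError, match="trend_obs"):
            farrec.ClimateSimParams(trend_obs=float("nan"))

    def test_no_forcing_null_centers_far_near_floor(self):
        ens = farrec.simulate_climate(
            farrec.ClimateSimParams(n_years_obs=50, trend_obs=0.0,
                                    trend_proj=0.0, seed=9)
        )
        tab = farrec.build_far_table(ens, "hindcast")
        # equal population distributions: median raw FAR at/below 0
        assert tab["far"].median() < 0.2

    def test_final_decade_exceedance_matches_monte_carlo(self):
        """Frequency of final-decade observed anomalies above the
        preindustrial 95th percentile matches direct Monte Carlo of the same
        generative process."""
        p = farrec.ClimateSimParams(n_years_obs=60, seed=13)
        n_rep = 150
        freq = np.empty(n_rep)
        for r in range(n_rep):
            ens = farrec.simulate_climate(
                farrec.ClimateSimParams(n_years_obs=60, seed=1000 + r)
            )
            pre_all = np.concatenate(
                [m.preindustrial.to_numpy() for m in ens.models]
            )
            q95 = np.quantile(pre_all, 0.95)
            last = ens.observed.iloc[-10:].to_numpy()
            freq[r] = np.mean(last >= q95)
        # direct Monte Carlo of the generative model: trend + stationary AR(1)
        rng = np.random.default_rng(99)
        t = np.arange(p.n_years_obs, dtype=float)
        t -= t.mean()
        stat_sd = p.noise_sd / np.sqrt(1 - p.ar1_coef**2)
        n_mc = 4000
        noise = np.empty((n_mc, 10))
        for r in range(n_mc):
            x = rng.normal(0, stat_sd)
            path = []
            for i in range(p.n_years_obs):
                x = p.ar1_coef * x + rng.normal(0, p.noise_sd)
                path.append(x)
            noise[r] = np.array(path[-10:])
        pre_mc = rng.normal(0, stat_sd, (n_mc, 60 * 5))
        q95_mc = np.quantile(pre_mc, 0.95, axis=1)
        mc_freq = np.mean(noise + p.trend_obs * t[-10:] >= q95_mc[:, None])
        se = np.sqrt(freq.var() / n_rep + 0.25 / n_mc)
        assert abs(freq.mean() - mc_freq) < 4 * se + 0.02


class TestRecruitment:
    def test_far_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            farrec.simulate_recruitment(
                np.array([0.5, 1.2]), farrec.RecruitSimParams(seed=0)
            )

    def test_threshold_below_cutoff_mean_response_is_flat(self):
        p = farrec.RecruitSimParams(far_effect_shape="threshold", seed=0)
        far = np.linspace(0, 0.9, 10)
        np.testing.assert_array_equal(recruitment_mean(far, p), np.zeros(10))

    def test_null_effect_gives_slope_ci_containing_zero(self):
        import statsmodels.api as sm

        p = farrec.RecruitSimParams(
            far_effect_shape="linear", effect_size=0.0, resid_sd=0.5, seed=1
        )
        far = np.linspace(0, 1, 50)
        y = farrec.simulate_recruitment(far, p)
        fit = sm.OLS(y.to_numpy(), sm.add_constant(far)).fit()
        lo, hi = fit.conf_int()[1]
        assert lo <= 0.0 <= hi

    def test_linear_effect_recovered_by_ols_within_three_ses(self):
        import statsmodels.api as sm

        p = farrec.RecruitSimParams(
            far_effect_shape="linear", effect_size=-2.0, resid_sd=0.1, seed=2
        )
        far = np.linspace(0, 1, 50)
        y = farrec.simulate_recruitment(far, p)
        fit = sm.OLS(y.to_numpy(), sm.add_constant(far)).fit()
        assert abs(fit.params[1] - (-2.0)) < 3 * fit.bse[1]

    def test_standardized_output_has_unit_moments(self):
        p = farrec.RecruitSimParams(seed=3)
        y = farrec.simulate_recruitment(np.linspace(0, 1, 40), p,
                                        standardize=True)
        assert y.mean() == pytest.approx(0.0, abs=1e-12)
        assert y.std(ddof=1) == pytest.approx(1.0, rel=1e-12)


class TestSeine:
    def test_counts_are_nonnegative_integers(self, seine_small):
        counts = seine_small["count"]
        assert (counts >= 0).all()
        assert counts.dtype.kind == "i"

    def test_certain_zero_inflation_yields_all_zero_counts(self):
        p = farrec.SeineSimParams(
            n_years=2, n_bays=2, n_sites_per_bay=2, sets_per_site_year=3,
            zero_prob_intercept=40.0, zero_covariate_scale=0.0, seed=1,
        )
        assert (farrec.simulate_seine(p)["count"] == 0).all()

    def test_no_random_effects_removes_between_bay_variance(self):
        p = farrec.SeineSimParams(
            n_years=3, n_bays=6, n_sites_per_bay=3, sets_per_site_year=10,
            bay_sd=0.0, site_sd=0.0, temp_effect=0.0, doy_effect=0.0,
            ssb_effect=0.0, zero_prob_intercept=-30.0, seed=2,
        )
        d = farrec.simulate_seine(p)
        log_means = np.log(d.groupby("bay")["count"].mean())
        p2 = farrec.SeineSimParams(
            n_years=3, n_bays=6, n_sites_per_bay=3, sets_per_site_year=10,
            bay_sd=1.0, site_sd=0.0, temp_effect=0.0, doy_effect=0.0,
            ssb_effect=0.0, zero_prob_intercept=-30.0, seed=2,
        )
        d2 = farrec.simulate_seine(p2)
        log_means2 = np.log(d2.groupby("bay")["count"].mean())
        assert log_means.var() < 0.05
        assert log_means2.var() > 4 * log_means.var()

    def test_moments_match_analytic_zinb_values(self):
        """Sample mean and zero fraction at homogeneous (pi, mu, shape) agree
        with E[y] = (1-pi)*mu and P(0) = pi + (1-pi)*(k/(k+mu))^k within
        Monte-Carlo error at n >= 5000."""
        p = farrec.SeineSimParams(
            n_years=5, n_bays=10, n_sites_per_bay=10, sets_per_site_year=10,
            zero_prob_intercept=0.0, mean_intercept=2.0, temp_effect=0.0,
            doy_effect=0.0, ssb_effect=0.0, bay_sd=0.0, site_sd=0.0,
            shape=1.5, seed=3,
        )
        d = farrec.simulate_seine(p)
        n = len(d)
        assert n >= 5000
        pi, mu, k = 0.5, np.exp(2.0), 1.5
        ey = (1 - pi) * mu
        vary = (1 - pi) * mu * (1 + mu / k) + pi * (1 - pi) * mu**2
        p0 = pi + (1 - pi) * (k / (k + mu)) ** k
        assert abs(d["count"].mean() - ey) < 3 * np.sqrt(vary / n)
        assert abs((d["count"] == 0).mean() - p0) < 3 * np.sqrt(p0 * (1 - p0) / n)

    def test_nonpositive_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            farrec.SeineSimParams(shape=0.0)


class TestSurveyPanel:
    def test_zero_noise_unit_loadings_reproduce_trend(self):
        trend = np.sin(np.arange(12.0))
        panel = farrec.simulate_survey_panel(
            trend, [1, 1, 1], [0, 0, 0], [0, 0, 0], seed=0
        )
        for col in panel:
            np.testing.assert_allclose(panel[col].to_numpy(), trend)

    def test_zero_loading_series_uncorrelated_with_trend(self):
        rng = np.random.default_rng(1)
        trend = np.cumsum(rng.normal(0, 1, 200))
        panel = farrec.simulate_survey_panel(
            trend, [0.8, 0.0], [0.3, 0.3], [0, 0], seed=2
        )
        r_loaded = np.corrcoef(panel["series_1"], trend)[0, 1]
        r_null = np.corrcoef(panel["series_2"], trend)[0, 1]
        assert r_loaded > 0.9
        assert abs(r_null) < 0.25

    def test_negative_obs_sd_rejected(self):
        with pytest.raises(ValueError, match="obs_sd"):
            farrec.simulate_survey_panel(
                np.arange(5.0), [1.0], [-0.1], [0.0], seed=0
            )

    def test_missingness_rate_applied_per_series(self):
        trend = np.zeros(2000)
        panel = farrec.simulate_survey_panel(
            trend, [1, 1], [1, 1], [0.0, 0.3], seed=3
        )
        assert panel["series_1"].isna().mean() == 0.0
        assert panel["series_2"].isna().mean() == pytest.approx(0.3, abs=0.04)
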