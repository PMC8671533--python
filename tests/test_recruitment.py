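"""Recruitment-FAR spline models, measurement-error variant, LOOIC, Bayesian
R², failure classification, and the seine-to-assessment bridge."""

import numpy as np
import pandas as pd
import pytest

import farrec
from farrec.recruitment import (
    _make_gam_logp,
    _make_gam_me_logp,
    bayes_r2,
    bridge_recent_recruitment,
    classify_failure,
    fit_far_gam,
    fit_far_gam_me,
    loo_compare,
)
from farrec.splines import ThinPlateBasis
from tests.conftest import finite_difference_grad


class TestThinPlateBasis:
    def test_rejects_oversized_basis(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="too large"):
            ThinPlateBasis(x, 9)
        with pytest.raises(ValueError, match="distinct"):
            ThinPlateBasis(np.repeat([0.1, 0.5, 0.9], 5), 5)

    def test_k5_represents_smooth_curves(self):
        x = np.linspace(0, 1, 60)
        y = np.sin(2 * np.pi * x)
        b = ThinPlateBasis(x, 5)
        coef = np.linalg.lstsq(b.design(x), y, rcond=None)[0]
        assert np.max(np.abs(b.design(x) @ coef - y)) < 0.1

    def test_design_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 25)
        b = ThinPlateBasis(x, 5)
        pts = np.array([0.21, 0.55, 0.83])
        h = 1e-6
        num = (b.design(pts + h) - b.design(pts - h)) / (2 * h)
        np.testing.assert_allclose(b.design_grad(pts), num, rtol=1e-4,
                                   atol=1e-6)

    def test_affine_rescaling_of_covariate_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 30)
        y = np.sin(3 * x) + rng.normal(0, 0.1, 30)
        grid = np.linspace(0.05, 0.95, 11)
        curves = []
        for a, c in [(1.0, 0.0), (5.0, -2.0)]:
            b = ThinPlateBasis(a * x + c, 5)
            coef = np.linalg.lstsq(b.design(a * x + c), y, rcond=None)[0]
            curves.append(b.design(a * grid + c) @ coef)
        np.testing.assert_allclose(curves[0], curves[1], atol=1e-8)


class TestGamLogPosteriors:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        n = 12
        x = rng.uniform(0.1, 0.9, n)
        y = -x + rng.normal(0, 0.2, n)
        basis = ThinPlateBasis(x, 3)
        logp, spec, _ = _make_gam_logp(y, basis, x)
        theta = rng.normal(0, 0.3, spec.size)
        np.testing.assert_allclose(
            logp(theta)[1], finite_difference_grad(logp, theta),
            rtol=1e-4, atol=1e-5,
        )
        logp_me, spec_me = _make_gam_me_logp(y, basis, x, np.full(n, 0.05), 3)
        theta = rng.normal(0, 0.3, spec_me.size)
        np.testing.assert_allclose(
            logp_me(theta)[1], finite_difference_grad(logp_me, theta),
            rtol=1e-4, atol=1e-4,
        )


class TestFitFarGam:
    def test_constant_series_yields_flat_curve(self):
        rng = np.random.default_rng(4)
        far = rng.uniform(0.05, 0.95, 30)
        y = np.zeros(30) + rng.normal(0, 0.05, 30)
        fit = fit_far_gam(pd.Series(y), pd.Series(far), k=3,
                          n_warmup=300, n_draws=300, seed=1)
        grid = np.linspace(0.1, 0.9, 9)
        curves = fit.predict_curve(grid)
        # pointwise CIs everywhere include the flat level
        lo, hi = np.quantile(curves, [0.025, 0.975], axis=0)
        assert np.all(lo < 0.1) and np.all(hi > -0.1)
        assert np.ptp(curves.mean(axis=0)) < 0.2

    def test_linear_truth_recovered_across_far_range(self):
        rng = np.random.default_rng(5)
        far = rng.uniform(0.02, 0.98, 50)
        y = -2.0 * (far - far.mean()) + rng.normal(0, 0.1, 50)
        fit = fit_far_gam(pd.Series(y), pd.Series(far), k=3,
                          n_warmup=300, n_draws=300, seed=2)
        grid = np.linspace(0.1, 0.9, 17)
        mean_curve = fit.predict_curve(grid).mean(axis=0)
        np.testing.assert_allclose(
            mean_curve, -2.0 * (grid - far.mean()), atol=0.2
        )

    def test_threshold_truth_low_far_vs_high_far_contrast(self):
        rng = np.random.default_rng(6)
        far = np.concatenate(
            [rng.uniform(0.05, 0.9, 40), rng.uniform(0.985, 0.9999, 8)]
        )
        y = np.where(far >= 0.98, -2.0, 0.0) + rng.normal(0, 0.5, 48)
        fit = fit_far_gam(pd.Series(y), pd.Series(far), k=3,
                          n_warmup=300, n_draws=300, seed=3)
        c_low = fit.predict_curve(np.array([0.5]))[:, 0]
        c_high = fit.predict_curve(np.array([0.999]))[:, 0]
        assert np.mean(c_high < c_low) >= 0.95

    def test_oversized_basis_rejected(self):
        y = pd.Series(np.zeros(4))
        with pytest.raises(ValueError, match="k="):
            fit_far_gam(y, pd.Series([0.1, 0.3, 0.5, 0.7]), k=3)


class TestMeasurementError:
    def test_zero_se_falls_back_to_error_free_fit(self):
        rng = np.random.default_rng(7)
        far = rng.uniform(0.05, 0.95, 25)
        y = -far + rng.normal(0, 0.2, 25)
        fit = fit_far_gam_me(pd.Series(y), pd.Series(far),
                             pd.Series(np.zeros(25)), k=3, seed=4)
        assert not fit.measurement_error

    def test_small_se_limit_matches_error_free_curve(self):
        rng = np.random.default_rng(8)
        far = rng.uniform(0.05, 0.95, 35)
        y = -2.0 * (far - far.mean()) + rng.normal(0, 0.2, 35)
        plain = fit_far_gam(pd.Series(y), pd.Series(far), k=3,
                            n_warmup=400, n_draws=400, seed=5)
        me = fit_far_gam_me(pd.Series(y), pd.Series(far),
                            pd.Series(np.full(35, 1e-3)), k=3,
                            n_warmup=400, n_draws=400, seed=5)
        grid = np.linspace(0.1, 0.9, 9)
        diff = np.abs(plain.predict_curve(grid).mean(axis=0)
                      - me.predict_curve(grid).mean(axis=0))
        assert diff.max() < 0.05

    def test_large_se_attenuates_the_slope(self):
        """Classical measurement-error attenuation: with noisy FAR the
        fitted response is no steeper than the error-free fit."""
        rng = np.random.default_rng(9)
        far = rng.uniform(0.1, 0.9, 40)
        y = -2.0 * (far - far.mean()) + rng.normal(0, 0.2, 40)
        plain = fit_far_gam(pd.Series(y), pd.Series(far), k=3,
                            n_warmup=400, n_draws=400, seed=6)
        noisy = fit_far_gam_me(pd.Series(y), pd.Series(far),
                               pd.Series(np.full(40, 0.15)), k=3,
                               n_warmup=400, n_draws=400, seed=6)
        grid = np.array([0.2, 0.8])
        slope = lambda f: np.diff(f.predict_curve(grid).mean(axis=0))[0] / 0.6
        assert abs(slope(noisy)) <= abs(slope(plain)) + 0.15

    def test_heteroscedastic_se_widens_that_years_latent_posterior(self):
        rng = np.random.default_rng(10)
        far = rng.uniform(0.2, 0.8, 20)
        se = np.full(20, 0.01)
        se[7] = 0.3
        y = -far + rng.normal(0, 0.2, 20)
        fit = fit_far_gam_me(pd.Series(y), pd.Series(far), pd.Series(se),
                             k=3, n_warmup=400, n_draws=400, seed=7)
        sds = fit.latent_far_draws().std(axis=0)
        others = np.delete(sds, 7)
        assert sds[7] > 5 * others.max()

    def test_me_predictive_variance_not_smaller_than_error_free(self):
        rng = np.random.default_rng(11)
        far = rng.uniform(0.1, 0.9, 30)
        y = -2.0 * (far - far.mean()) + rng.normal(0, 0.3, 30)
        plain = fit_far_gam(pd.Series(y), pd.Series(far), k=3,
                            n_warmup=400, n_draws=400, seed=8)
        me = fit_far_gam_me(pd.Series(y), pd.Series(far),
                            pd.Series(np.full(30, 0.1)), k=3,
                            n_warmup=400, n_draws=400, seed=8)
        est = pd.DataFrame({"year": np.arange(30), "mean": far, "se": 0.1})
        years = list(range(30))
        v_plain = farrec.predict_distribution(plain, est, years, seed=1).var()
        v_me = farrec.predict_distribution(me, est, years, seed=1).var()
        assert v_me >= 0.8 * v_plain


class TestModelComparison:
    @staticmethod
    def _fit(seed, with_noise_cov=False):
        rng = np.random.default_rng(42)
        far = rng.uniform(0.05, 0.95, 30)
        ssb = rng.normal(0, 1, 30)  # irrelevant to the response
        y = -2.0 * (far - far.mean()) + rng.normal(0, 0.3, 30)
        kwargs = dict(k=3, n_warmup=400, n_draws=400, seed=seed)
        if with_noise_cov:
            return fit_far_gam(pd.Series(y), pd.Series(far),
                               ssb=pd.Series(ssb), **kwargs)
        return fit_far_gam(pd.Series(y), pd.Series(far), **kwargs)

    def test_duplicate_fit_has_zero_delta(self):
        fit = self._fit(1)
        tab = loo_compare({"a": fit, "b": fit}).set_index("model")
        assert tab.loc["b", "delta_looic"] == pytest.approx(0.0, abs=1e-9)

    def test_irrelevant_covariate_does_not_win_by_more_than_noise(self):
        """Adding a pure-noise SSB smooth must not beat the simpler model by
        more than ~2 SEs of the LOOIC difference."""
        simple = self._fit(2)
        rich = self._fit(3, with_noise_cov=True)
        tab = loo_compare({"far": simple, "far+ssb": rich}).set_index("model")
        delta = tab.loc["far", "looic"] - tab.loc["far+ssb", "looic"]
        se = np.hypot(tab.loc["far", "se"], tab.loc["far+ssb", "se"])
        assert delta <= 2 * 2 * se  # LOOIC = -2 elpd: 2*SE on that scale

    def test_mismatched_observation_sets_rejected(self):
        fit_a = self._fit(4)
        rng = np.random.default_rng(1)
        far = rng.uniform(0.1, 0.9, 20)
        fit_b = fit_far_gam(pd.Series(-far + rng.normal(0, 0.2, 20)),
                            pd.Series(far), k=3, n_warmup=200, n_draws=200,
                            seed=5)
        with pytest.raises(ValueError, match="observations"):
            loo_compare({"a": fit_a, "b": fit_b})


class TestBayesR2:
    def test_in_unit_interval_for_every_draw(self):
        fit = TestModelComparison._fit(6)
        r2 = bayes_r2(fit)
        assert np.all((r2["draws"] >= 0) & (r2["draws"] <= 1))

    def test_near_one_when_residual_variance_vanishes(self):
        rng = np.random.default_rng(12)
        far = rng.uniform(0.05, 0.95, 40)
        y = -2.0 * (far - far.mean()) + rng.normal(0, 0.01, 40)
        fit = fit_far_gam(pd.Series(y), pd.Series(far), k=3,
                          n_warmup=300, n_draws=300, seed=9)
        assert bayes_r2(fit)["median"] > 0.95

    def test_near_zero_for_null_signal(self):
        rng = np.random.default_rng(13)
        far = rng.uniform(0.05, 0.95, 40)
        y = rng.normal(0, 1.0, 40)
        fit = fit_far_gam(pd.Series(y), pd.Series(far), k=3,
                          n_warmup=300, n_draws=300, seed=10)
        assert bayes_r2(fit)["median"] < 0.25

    def test_matches_analytic_signal_to_noise_split(self):
        """Signal and noise variance 1:1 -> posterior median R² near 0.5."""
        rng = np.random.default_rng(14)
        n = 200
        far = rng.uniform(0.0, 1.0, n)
        signal = -2.0 * (far - far.mean())  # variance ~ 4*var(U(0,1)) = 1/3
        noise_sd = np.sqrt(signal.var())
        y = signal + rng.normal(0, noise_sd, n)
        fit = fit_far_gam(pd.Series(y), pd.Series(far), k=3,
                          n_warmup=300, n_draws=300, seed=11)
        assert bayes_r2(fit)["median"] == pytest.approx(0.5, abs=0.1)


class TestFailureClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [(-1.01, True), (-1.0, False), (0.3, False), (-5.0, True)],
    )
    def test_strict_threshold(self, value, expected):
        assert classify_failure(value) is expected

    def test_vectorized(self):
        out = classify_failure(np.array([-2.0, -1.0, 0.0]))
        np.testing.assert_array_equal(out, [True, False, False])


class TestBridge:
    def test_proportional_overlap_extrapolates_exactly(self):
        years = np.arange(2006, 2018)
        index = pd.Series(np.linspace(1, 4, 12), index=years)
        assessment = 2.0 * index + 1.0
        out = bridge_recent_recruitment(
            pd.concat([index, pd.Series([5.0, 6.0], index=[2018, 2019])]),
            assessment, (2006, 2017), [2018, 2019],
        )
        np.testing.assert_allclose(out["prediction"], [11.0, 13.0])

    def test_predictive_se_exceeds_residual_se(self):
        rng = np.random.default_rng(15)
        years = np.arange(2006, 2017)
        x = pd.Series(rng.normal(0, 1, 11), index=years)
        y = 0.8 * x + rng.normal(0, 0.5, 11)
        x_full = pd.concat([x, pd.Series([0.5], index=[2020])])
        out = bridge_recent_recruitment(x_full, y, (2006, 2016), [2020])
        resid_sd = (y - y.mean()).std()
        import statsmodels.api as sm

        fit = sm.OLS(y.to_numpy(),
                     sm.add_constant(x.to_numpy())).fit()
        assert out["se"].iloc[0] > np.sqrt(fit.mse_resid)

    def test_short_overlap_rejected(self):
        x = pd.Series([1.0, 2.0], index=[2006, 2007])
        y = pd.Series([1.0, 2.0], index=[2006, 2007])
        with pytest.raises(ValueError, match="overlap"):
            bridge_recent_recruitment(x, y, (2006, 2007), [2010])
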