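"""Attribution: anomaly standardization, exceedance counting, FAR, and the
beta ensemble model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import farrec
from farrec.attribution import CLAMP_HI, CLAMP_LO


class TestStandardize:
    def test_z_scores_match_direct_computation(self):
        raw = pd.Series(np.arange(1.0, 11.0), index=range(2000, 2010))
        out = farrec.standardize_anomalies(raw, (2000, 2009), (2000, 2009))
        expected = (raw - raw.mean()) / raw.std(ddof=1)
        np.testing.assert_allclose(out.to_numpy(), expected.to_numpy())

    def test_center_window_value_maps_to_zero(self):
        raw = pd.Series([1.0, 2.0, 3.0, 6.0], index=range(2000, 2004))
        out = farrec.standardize_anomalies(raw, (2000, 2002), (2000, 2003))
        assert out.loc[2001] == pytest.approx(0.0)  # raw equals window mean

    def test_constant_series_zero_sd_raises_naming_window(self):
        raw = pd.Series([2.0] * 5, index=range(2000, 2005))
        with pytest.raises(ValueError, match="zero SD"):
            farrec.standardize_anomalies(raw, (2000, 2004), (2000, 2004))

    def test_disjoint_window_raises(self):
        raw = pd.Series([1.0, 2.0], index=[2000, 2001])
        with pytest.raises(ValueError, match="does not overlap"):
            farrec.standardize_anomalies(raw, (1900, 1950), (2000, 2001))


class TestExceedance:
    def test_boundary_cases_and_exhaustive_count(self):
        sample = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        assert farrec.exceedance_probability(-2.0, sample) == 1.0
        assert farrec.exceedance_probability(2.0, sample) == 0.0
        assert farrec.exceedance_probability(0.6, sample) == pytest.approx(0.2)

    def test_tie_counts_as_exceedance(self):
        sample = np.array([0.0, 1.0])
        assert farrec.exceedance_probability(1.0, sample) == pytest.approx(0.5)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="empty"):
            farrec.exceedance_probability(0.0, np.array([]))


class TestComputeFar:
    def test_equal_risk_clamps_to_floor(self):
        s = np.array([-1.0, 0.0, 1.0])
        assert farrec.compute_far(0.0, s, s) == CLAMP_LO

    def test_anomaly_beyond_preindustrial_resets_to_0p9999(self):
        pre = np.array([-1.0, 0.0, 1.0])
        cur = np.array([0.5, 1.5, 2.5])
        assert farrec.compute_far(2.5, pre, cur) == CLAMP_HI

    def test_hand_counted_example(self):
        pre = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        cur = np.array([-0.5, 0.0, 0.6, 1.2])
        # p_pre = 1/5, p_cur = 2/4 -> 1 - 0.4 = 0.6
        assert farrec.compute_far(0.6, pre, cur) == pytest.approx(0.6)

    def test_zero_current_probability_raises(self):
        with pytest.raises(ValueError, match="focal year"):
            farrec.compute_far(5.0, np.array([0.0]), np.array([0.0, 1.0]))

    @settings(max_examples=200, deadline=None)
    @given(
        pre=st.lists(st.floats(-3, 3), min_size=1, max_size=20),
        cur=st.lists(st.floats(-3, 3), min_size=1, max_size=20),
        anom_ix=st.integers(0, 19),
    )
    def test_agrees_with_exhaustive_counting_oracle(self, pre, cur, anom_ix):
        pre = np.asarray(pre)
        cur = np.asarray(cur)
        anomaly = cur[anom_ix % len(cur)]  # member of current sample
        got = farrec.compute_far(anomaly, pre, cur)
        p_pre = sum(1 for v in pre if v >= anomaly) / len(pre)
        p_cur = sum(1 for v in cur if v >= anomaly) / len(cur)
        expected = min(max(1 - p_pre / p_cur, CLAMP_LO), CLAMP_HI)
        assert got == pytest.approx(expected)

    def test_monotone_in_focal_anomaly_at_fixed_current_probability(self):
        """With empirical step probabilities, FAR is monotone non-decreasing
        in the focal anomaly wherever the current-sample exceedance count is
        unchanged (raising the anomaly can only shed preindustrial
        exceedances there)."""
        rng = np.random.default_rng(5)
        pre = rng.normal(0, 1, 15)
        cur = np.sort(rng.normal(0.5, 1, 12))
        # probe within each half-open interval of constant current count
        for lo, hi in zip(cur[:-1], cur[1:]):
            probes = lo + (hi - lo) * np.array([1e-9, 0.25, 0.5, 0.75, 0.999])
            fars = [farrec.compute_far(a, pre, cur) for a in probes]
            assert np.all(np.diff(fars) >= -1e-12)


class TestFarTable:
    def test_one_row_per_year_model(self, small_ensemble):
        tab = farrec.build_far_table(small_ensemble, "hindcast")
        n_years = len(small_ensemble.observed)
        assert len(tab) == n_years * len(small_ensemble.models)
        assert set(tab.columns) >= {"year", "model_id", "far", "p_pre", "p_cur"}

    def test_identical_distributions_give_floor_far(self):
        obs = pd.Series(np.linspace(-1, 1, 20), index=range(2000, 2020))
        m = farrec.ModelRealizations(
            "m1", preindustrial=pd.Series(obs.to_numpy()), projection=obs.copy()
        )
        ens = farrec.ClimateEnsemble(observed=obs, models=[m])
        tab = farrec.build_far_table(ens, "hindcast")
        # p_pre == p_cur exactly for every anomaly -> raw FAR 0 -> clamp_lo
        assert np.all(tab["far"] == CLAMP_LO)

    def test_strong_trend_saturates_late_years(self):
        ens = farrec.simulate_climate(
            farrec.ClimateSimParams(
                n_years_obs=60, trend_obs=0.1, noise_sd=0.4, n_models=5,
                seed=19,
            )
        )
        tab = farrec.build_far_table(ens, "hindcast")
        late = tab[tab["year"] >= tab["year"].max() - 3]
        assert late["far"].median() > 0.9

    def test_unknown_period_rejected(self, small_ensemble):
        with pytest.raises(ValueError, match="period"):
            farrec.build_far_table(small_ensemble, "forecast")


class TestBetaEnsembleModel:
    def test_rejects_values_outside_open_interval(self):
        tab = pd.DataFrame(
            {"year": [2000, 2000], "model_id": ["a", "b"], "far": [0.5, 1.0]}
        )
        with pytest.raises(ValueError, match="clamping"):
            farrec.fit_far_model(tab)

    def test_degenerate_replicates_recover_constant_mean(self):
        rng = np.random.default_rng(0)
        rows = [
            {"year": 2000 + i, "model_id": f"m{j}",
             "far": float(np.clip(rng.normal(0.5, 0.02), 0.01, 0.99))}
            for i in range(5) for j in range(8)
        ]
        est = farrec.fit_far_model(
            pd.DataFrame(rows), n_warmup=300, n_draws=300, seed=1
        )
        assert np.all(np.abs(est.table["mean"] - 0.5) < 0.05)

    def test_clamped_years_estimated_near_one_with_narrow_intervals(self):
        rows = [
            {"year": 2000 + i, "model_id": f"m{j}", "far": 0.9999}
            for i in range(4) for j in range(5)
        ]
        est = farrec.fit_far_model(
            pd.DataFrame(rows), n_warmup=300, n_draws=300, seed=2
        )
        assert np.all(est.table["mean"] > 0.95)
        assert np.all(est.table["ci95_hi"] - est.table["ci95_lo"] < 0.2)

    def test_posterior_means_inside_unit_interval_and_intervals_nested(
        self, small_ensemble
    ):
        tab = farrec.build_far_table(small_ensemble, "hindcast")
        est = farrec.fit_far_model(tab, n_warmup=300, n_draws=300, seed=3)
        t = est.table
        assert np.all((t["mean"] > 0) & (t["mean"] < 1))
        assert np.all(t["ci80_lo"] >= t["ci90_lo"] - 1e-12)
        assert np.all(t["ci90_lo"] >= t["ci95_lo"] - 1e-12)
        assert np.all(t["ci80_hi"] <= t["ci90_hi"] + 1e-12)
        assert np.all(t["ci90_hi"] <= t["ci95_hi"] + 1e-12)

    def test_no_forcing_null_far_has_no_trend(self, null_ensemble):
        """Under zero forcing the posterior year-mean FAR shows no trend
        (OLS slope CI across years spans 0)."""
        import statsmodels.api as sm

        tab = farrec.build_far_table(null_ensemble, "hindcast")
        est = farrec.fit_far_model(tab, n_warmup=300, n_draws=300, seed=4)
        X = sm.add_constant(est.table["year"].to_numpy(dtype=float))
        fit = sm.OLS(est.table["mean"].to_numpy(), X).fit()
        lo, hi = fit.conf_int()[1]
        assert lo <= 0.0 <= hi
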