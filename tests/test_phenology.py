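"""Hierarchical binomial GAM: likelihood mode vs direct optimizer oracle,
degenerate data, shrinkage limits, empty regions, and interval calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from snowphen import PhenologyGAM, SyntheticConfig, expected_proportion_curve, generate_dataset
from snowphen.phenology import McmcConfig, _split_rhat


def _obs_frame(doy, states, region="northern"):
    return pd.DataFrame({
        "day_of_year": np.asarray(doy, dtype=int),
        "region": region,
        "state": states,
    })


def _toy_year(rng, n=400, p_fun=None, region="northern"):
    doy = rng.integers(60, 305, size=n)
    if p_fun is None:
        p_fun = lambda d: 0.4 * expit((d - 143) / 6.0) * expit(-(d - 227) / 8.0)
    states = np.where(rng.random(n) < p_fun(doy), "likely_breeding", "nonbreeding")
    return _obs_frame(doy, states, region)


class TestFitBasics:
    def test_no_observations_rejected(self):
        with pytest.raises(ValueError):
            PhenologyGAM(_obs_frame([], []), 2015)

    def test_unknown_region_rejected(self, rng):
        with pytest.raises(ValueError, match="atlantis"):
            PhenologyGAM(_toy_year(rng, region="atlantis"), 2015)

    def test_all_nonbreeding_is_degenerate_and_low(self, rng):
        """With 500 nonbreeding observations the curve posterior stays
        below the 5% threshold everywhere."""
        doy = rng.integers(60, 305, size=500)
        obs = _obs_frame(doy, ["nonbreeding"] * 500)
        model = PhenologyGAM(obs, 2015, regions=("northern",))
        assert model.degenerate
        res = model.fit(seed=1)
        curve = res.curve("northern")
        assert curve.mean.max() < 0.05

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            PhenologyGAM(_toy_year(rng), 2015, regions=("northern",)).fit(method="nuts")

    def test_region_absent_from_fit_rejected(self, rng):
        res = PhenologyGAM(_toy_year(rng), 2015, regions=("northern",)).fit(seed=1)
        with pytest.raises(ValueError, match="southern"):
            res.curve("southern")

    def test_curve_values_in_unit_interval(self, rng):
        res = PhenologyGAM(_toy_year(rng), 2015, regions=("northern",)).fit(seed=1)
        c = expected_proportion_curve(res, "northern")
        assert (c.draws > 0).all() and (c.draws < 1).all()
        assert len(c.grid) == 245

    def test_zero_coefficients_give_half(self, rng):
        """Inverse-logit of a zero linear predictor is 0.5 everywhere."""
        res = PhenologyGAM(_toy_year(rng), 2015, regions=("northern",)).fit(seed=1)
        res.coef_draws[:] = 0.0
        c = res.curve("northern")
        np.testing.assert_allclose(c.draws, 0.5)


class TestOracles:
    def test_pirls_matches_direct_optimizer(self, rng):
        """Penalized-likelihood mode agrees with scipy optimizing the same
        objective to 1e-4 on the coefficients."""
        obs = _toy_year(rng, n=300)
        model = PhenologyGAM(obs, 2015, regions=("northern",))
        s_diag = model._penalty_diag(np.log([5.0, 5.0]))
        beta_hat, H, ok = model._pirls(s_diag)
        assert ok

        def objective(b):
            eta = model._X @ b
            return -(np.sum(model.y * eta - np.logaddexp(0, eta))
                     - 0.5 * np.sum(s_diag * b * b))

        direct = minimize(objective, np.zeros(model._X.shape[1]), method="BFGS",
                          options={"gtol": 1e-10, "maxiter": 2000})
        np.testing.assert_allclose(beta_hat, direct.x, atol=1e-4)

    def test_infinite_penalty_limit_is_constant_frequency(self, rng):
        """With one region and penalty -> infinity the fitted curve tends to
        the constant logit of the overall likely-breeding frequency."""
        obs = _toy_year(rng, n=600)
        model = PhenologyGAM(obs, 2015, regions=("northern",),
                             deviation_prior_sd=1e-4)
        s_diag = model._penalty_diag(np.log([1e8, 1e8]))
        beta_hat, _, ok = model._pirls(s_diag)
        assert ok
        grid = np.arange(60.0, 305.0)
        X = model._build_design(grid, np.zeros(len(grid), dtype=int))
        p = expit(X @ beta_hat)
        freq = model.y.mean()
        np.testing.assert_allclose(p, freq, atol=0.01)

    def test_empty_region_inherits_global_shape(self, rng):
        """A region with no observations gets a deviation smoother shrunk
        to ~0, so its curve tracks the other regions' shared shape."""
        obs = pd.concat([_toy_year(rng, region="northern"),
                         _toy_year(rng, region="eastern")], ignore_index=True)
        model = PhenologyGAM(obs, 2015, regions=("northern", "eastern", "southern"))
        res = model.fit(seed=1)
        m = model._m
        south_block = res.beta_hat[1 + m + 3 + 2 * m:1 + m + 3 + 3 * m]
        assert np.abs(south_block).max() < 0.5
        south = res.curve("southern").mean
        north = res.curve("northern").mean
        # same rise-fall shape: peak within days of the data-bearing regions
        assert abs(np.argmax(south) - np.argmax(north)) < 30


class TestRecoveryAndCalibration:
    def test_single_year_crossing_recovery(self):
        """Planted start 140 / end 230 at 400 obs/region is recovered
        within +/- 5 days from the fitted curve."""
        import dataclasses

        from snowphen.metrics import season_metrics
        cfg = dataclasses.replace(
            SyntheticConfig(), years=(2015,), regions=("northern", "eastern"),
            temp_region_offsets=(0.0, 0.0), melt50_region_offsets=(0.0, 0.0),
            n_obs_per_region_year=400, sd_year=0.0, sd_region=0.0, sd_resid=0.0,
            baseline_start_day=140.0, baseline_end_day=230.0,
            beta_T_start=0.0, beta_P_start=0.0, beta_T_end=0.0)
        ds = generate_dataset(cfg, seed=21)
        res = PhenologyGAM(ds.observations, 2015,
                           regions=("northern", "eastern")).fit(seed=5)
        for region in ("northern", "eastern"):
            sm = season_metrics(res.curve(region))
            assert sm.start_day == pytest.approx(140, abs=5)
            assert sm.end_day == pytest.approx(230, abs=5)

    def test_posterior_interval_covers_tau_at_true_start(self):
        """Across >= 20 simulated year x region fits, the 95% interval of
        p(true_start) covers tau at roughly the nominal rate."""
        ds = generate_dataset(seed=3)
        years = sorted(set(ds.observations["year"]))[:5]
        covered = total = 0
        for year in years:
            grp = ds.observations[ds.observations["year"] == year]
            res = PhenologyGAM(grp, year).fit(seed=year)
            for region in res.regions:
                tr = ds.truth.query("year == @year and region == @region").iloc[0]
                c = res.curve(region)
                i = int(round(tr.true_start)) - 60
                lo, hi = np.quantile(c.draws[:, i], [0.025, 0.975])
                covered += int(lo <= 0.05 <= hi)
                total += 1
        assert total == 20
        assert covered / total >= 0.75  # nominal 0.95 minus Monte-Carlo slack


class TestMcmcMode:
    def test_small_budget_run_shapes_and_determinism(self, rng):
        obs = _toy_year(rng, n=150)
        model = PhenologyGAM(obs, 2015, regions=("northern",))
        cfg = McmcConfig(chains=4, iterations=120, thin=2)
        res1 = model.fit(method="mcmc", mcmc=cfg, seed=99)
        res2 = model.fit(method="mcmc", mcmc=cfg, seed=99)
        assert res1.coef_draws.shape[0] >= 1000
        np.testing.assert_allclose(res1.coef_draws, res2.coef_draws)
        assert np.isfinite(res1.rhat_max)

    def test_split_rhat_detects_disagreement(self, rng):
        good = rng.normal(size=(4, 500, 2))
        assert _split_rhat(good).max() < 1.05
        bad = good.copy()
        bad[0] += 5.0
        assert _split_rhat(bad).max() > 1.5
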