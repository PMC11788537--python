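"""Mixed-effect climate models and trend fits: GLS-vs-OLS oracle, the
standardized/unstandardized identity, additivity, and recovery."""

import numpy as np
import pandas as pd
import pytest

from snowphen import (
    BreedingEffectsModel,
    TemperatureTrend,
    breeding_season_mean_temp,
    fit_trend,
)


def _panel(rng, n_years=16, beta_T=-6.0, beta_P=2.0, sd_year=4.0, sd_region=3.0,
           sd_resid=3.0, interaction=0.0):
    years = np.arange(2006, 2006 + n_years)
    regions = ["northern", "eastern", "southern", "western"]
    u = dict(zip(years, rng.normal(0, sd_year, n_years)))
    v = dict(zip(regions, rng.normal(0, sd_region, len(regions))))
    rows = []
    for y in years:
        for r in regions:
            T = rng.normal(6.0, 1.5)
            P = float(rng.integers(2, 13))
            M = rng.normal(150.0, 10.0)
            start = (142.0 + beta_T * (T - 6.0) + beta_P * (P - 7.0)
                     + interaction * (T - 6.0) * (P - 7.0)
                     + u[y] + v[r] + rng.normal(0, sd_resid))
            rows.append({"year": y, "region": r, "start": start,
                         "temp": T, "pdays": P, "melt": M})
    return pd.DataFrame(rows)


class TestModelContracts:
    def test_too_few_rows_rejected(self, rng):
        df = _panel(rng).head(6)
        with pytest.raises(ValueError):
            BreedingEffectsModel(df, "start", ["temp"])

    def test_zero_variance_covariate_named(self, rng):
        df = _panel(rng)
        df["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            BreedingEffectsModel(df, "start", ["temp", "flat"])

    def test_incomplete_rows_dropped(self, rng):
        df = _panel(rng)
        df.loc[:4, "temp"] = np.nan
        model = BreedingEffectsModel(df, "start", ["temp", "pdays"])
        assert len(model.data) == len(df) - 5

    def test_interaction_must_use_model_covariates(self, rng):
        with pytest.raises(ValueError):
            BreedingEffectsModel(_panel(rng), "start", ["temp"],
                                 interaction=("temp", "pdays"))


class TestOracles:
    def test_zero_variance_gls_equals_ols(self, rng):
        """With random-effect variances forced to zero the GLS point
        estimates match ordinary least squares to 1e-6."""
        df = _panel(rng)
        model = BreedingEffectsModel(df, "start", ["temp", "pdays", "melt"])
        V = model._marginal_V(1.0, 0.0, 0.0)
        beta, _ = model._gls(V)
        ols, *_ = np.linalg.lstsq(model.X_std, model.y, rcond=None)
        np.testing.assert_allclose(beta, ols, atol=1e-6)

    def test_standardized_equals_unstandardized_times_sd(self, rng):
        """Identity for every term of an interaction-free fit, to 1e-6
        relative."""
        df = _panel(rng)
        res = BreedingEffectsModel(df, "start", ["temp", "pdays", "melt"]).fit("reml")
        for j, cov in enumerate(res.model.covariates, start=1):
            np.testing.assert_allclose(
                res.beta_std[j], res.beta_raw[j] * res.model.x_sd[cov], rtol=1e-6)

    def test_raw_parameterization_reproduces_fitted_values(self, rng):
        """The two parameterizations are the same model: identical linear
        predictions."""
        df = _panel(rng)
        model = BreedingEffectsModel(df, "start", ["temp", "pdays"],
                                     interaction=("temp", "pdays"))
        res = model.fit("reml")
        X_raw = np.column_stack([
            np.ones(len(model.data)), model.data["temp"], model.data["pdays"],
            model.data["temp"] * model.data["pdays"]])
        np.testing.assert_allclose(
            model.X_std @ res.beta_std, X_raw @ res.beta_raw, atol=1e-8)


class TestEffects:
    def test_effect_per_unit_slope_times_delta(self, rng):
        res = BreedingEffectsModel(_panel(rng), "start", ["temp", "pdays"]).fit("reml")
        est1, lo1, hi1 = res.effect_per_unit("temp", 1.0)
        est2, lo2, hi2 = res.effect_per_unit("temp", -10.0)
        assert est2 == pytest.approx(-10 * est1)
        est0, lo0, hi0 = res.effect_per_unit("temp", 0.0)
        assert (est0, lo0, hi0) == (0.0, 0.0, 0.0)
        assert lo1 <= est1 <= hi1

    def test_effect_at_mean_of_interacting_covariate(self, rng):
        df = _panel(rng, interaction=-0.6)
        res = BreedingEffectsModel(df, "start", ["temp", "pdays"],
                                   interaction=("temp", "pdays")).fit("reml")
        est, _, _ = res.effect_per_unit("temp", 1.0)
        slope = (res.beta_raw[1]
                 + res.beta_raw[-1] * res.model.x_mean["pdays"])
        assert est == pytest.approx(slope)

    def test_identical_scenarios_zero_contrast(self, rng):
        res = BreedingEffectsModel(_panel(rng), "start", ["temp", "pdays"]).fit("reml")
        scn = {"temp": 6.0, "pdays": 7.0}
        est, lo, hi = res.scenario_contrast(scn, scn)
        assert (est, lo, hi) == (0.0, 0.0, 0.0)

    def test_additive_model_contrast_sums_effects(self, rng):
        """Without an interaction, a joint contrast equals the sum of
        per-covariate effects (exact linear algebra)."""
        res = BreedingEffectsModel(_panel(rng), "start", ["temp", "pdays"]).fit("reml")
        a = {"temp": 4.0, "pdays": 12.0}
        b = {"temp": 8.0, "pdays": 4.0}
        joint, _, _ = res.scenario_contrast(a, b)
        t_eff, _, _ = res.effect_per_unit("temp", a["temp"] - b["temp"])
        p_eff, _, _ = res.effect_per_unit("pdays", a["pdays"] - b["pdays"])
        assert joint == pytest.approx(t_eff + p_eff, abs=1e-8)

    def test_planted_contrast_recovered_within_interval(self, rng):
        """Cold+wet vs warm+dry contrast covers the constructed truth."""
        df = _panel(rng, beta_T=-6.0, beta_P=2.5)
        res = BreedingEffectsModel(df, "start", ["temp", "pdays"]).fit("reml")
        a = {"temp": df.temp.min(), "pdays": df.pdays.max()}
        b = {"temp": df.temp.max(), "pdays": df.pdays.min()}
        truth = -6.0 * (a["temp"] - b["temp"]) + 2.5 * (a["pdays"] - b["pdays"])
        est, lo, hi = res.scenario_contrast(a, b)
        assert lo <= truth <= hi

    def test_bayes_mode_agrees_with_reml(self, rng):
        df = _panel(rng)
        model = BreedingEffectsModel(df, "start", ["temp", "pdays"])
        r1 = model.fit("reml")
        r2 = model.fit("bayes", iterations=1200, seed=4)
        np.testing.assert_allclose(r2.beta_std, r1.beta_std, atol=0.5)
        assert r2.draws_std is not None and len(r2.draws_std) >= 1000


class TestTrend:
    def test_planted_slope_total_change(self):
        years = np.arange(2006, 2022)
        res = TemperatureTrend(years, 5.0 + 0.1 * (years - 2006)).fit()
        assert res.slope == pytest.approx(0.1, abs=1e-10)
        assert res.total_change == pytest.approx(1.5, abs=1e-9)

    def test_flat_series(self):
        years = np.arange(2006, 2022)
        res = TemperatureTrend(years, np.full(16, 4.2)).fit()
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.total_change == pytest.approx(0.0, abs=1e-10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            TemperatureTrend([2006, 2007], [1.0, 2.0])

    def test_frame_interface(self):
        df = pd.DataFrame({"year": [2006, 2010, 2014, 2018],
                           "temp": [1.0, 1.4, 1.8, 2.2]})
        res = fit_trend(df)
        assert res.slope == pytest.approx(0.1)
        assert res.span_years == 12


class TestSeasonMeanTemp:
    def _climate(self):
        doy = np.arange(60, 305)
        return pd.DataFrame({
            "year": 2015, "region": "northern", "day_of_year": doy,
            "temp_mean": doy / 10.0, "precip_sum": 0.0})

    def test_constant_series(self):
        clim = self._climate().assign(temp_mean=5.0)
        assert breeding_season_mean_temp(clim, 2015, "northern", 139, 231) == 5.0

    def test_arithmetic_sequence_mean(self):
        """Season (139, 231) over temps doy/10 averages to 18.5."""
        assert breeding_season_mean_temp(
            self._climate(), 2015, "northern", 139, 231) == pytest.approx(18.5)

    def test_undefined_season_is_nan(self):
        assert np.isnan(breeding_season_mean_temp(
            self._climate(), 2015, "northern", np.nan, 231))

    def test_shrinking_toward_peak_raises_mean(self):
        """For a unimodal temperature curve, narrowing the season around
        the warm peak increases the seasonal mean."""
        doy = np.arange(60, 305)
        clim = pd.DataFrame({
            "year": 2015, "region": "northern", "day_of_year": doy,
            "temp_mean": 10 - ((doy - 197) / 40.0) ** 2, "precip_sum": 0.0})
        wide = breeding_season_mean_temp(clim, 2015, "northern", 121, 243)
        narrow = breeding_season_mean_temp(clim, 2015, "northern", 180, 215)
        assert narrow > wide
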