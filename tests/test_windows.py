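"""Sliding-window scan: enumeration vs brute force, Pearson/SE oracles,
affine invariance, selection rules and null calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from snowphen import (
    WindowSpec,
    correlation_scan,
    enumerate_windows,
    pearson_with_se,
    scan_heatmap_table,
    select_best_window,
    window_summary,
)


class TestEnumeration:
    def test_ten_day_range_brute_force(self):
        """Range of 10 days, min length 7, step 2: exactly {(1,7), (1,9),
        (3,9)} in relative days."""
        wins = enumerate_windows((1, 10), min_len=7, step=2)
        assert {(w.open_day, w.close_day) for w in wins} == {(1, 7), (1, 9), (3, 9)}

    def test_matches_brute_force_pair_enumeration(self):
        lo, hi, min_len, step = 91, 181, 7, 2
        wins = {(w.open_day, w.close_day) for w in
                enumerate_windows((lo, hi), min_len, step)}
        brute = {(o, c)
                 for o in range(lo, hi + 1) for c in range(lo, hi + 1)
                 if (o - lo) % step == 0 and (c - lo) % step == 0
                 and c - o + 1 >= min_len}
        assert wins == brute

    def test_minimum_length_boundary(self):
        lengths = {w.length for w in enumerate_windows((1, 20), min_len=7, step=2)}
        assert 7 in lengths and 6 not in lengths and min(lengths) == 7

    def test_short_range_empty(self):
        assert enumerate_windows((1, 5), min_len=7) == []

    def test_paper_style_precip_window_length(self):
        assert WindowSpec(109, 119).length == 11  # Apr 19 - Apr 29


class TestWindowSummary:
    def _climate(self, temps, precip):
        n = len(temps)
        return pd.DataFrame({
            "year": 2015, "region": "northern",
            "day_of_year": np.arange(100, 100 + n),
            "temp_mean": temps, "precip_sum": precip,
        })

    def test_mean_temperature(self):
        clim = self._climate(np.arange(1.0, 8.0), np.zeros(7))
        out = window_summary(clim, WindowSpec(100, 106), "mean_temperature")
        assert out["value"].iloc[0] == 4.0

    def test_precipitation_days_at_least_1mm(self):
        clim = self._climate(np.zeros(7), [0, 0.9, 1.0, 2.3, 0, 0, 0])
        out = window_summary(clim, WindowSpec(100, 106), "precipitation_days")
        assert out["value"].iloc[0] == 2

    def test_missing_days_dropped(self):
        clim = self._climate(np.arange(7.0), np.zeros(7)).drop(index=[3])
        out = window_summary(clim, WindowSpec(100, 106), "mean_temperature")
        assert out.empty

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            window_summary(self._climate([1.0], [0.0]), WindowSpec(100, 100), "wind")


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r, se, n = pearson_with_se(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-7)
        assert n == 10

    def test_closed_form_se_at_zero_r(self):
        """r = 0, n = 64 -> SE = sqrt(1/62) ~ 0.1270."""
        assert np.sqrt((1 - 0.0**2) / (64 - 2)) == pytest.approx(0.1270, abs=5e-4)

    def test_matches_from_scratch_formula(self, rng):
        """Oracle: r agrees with an explicit covariance/SD computation to
        1e-12 on random vectors."""
        for _ in range(50):
            x, y = rng.normal(size=(2, 40))
            r, se, n = pearson_with_se(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            r_ref = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert r == pytest.approx(r_ref, abs=1e-12)
            assert se == pytest.approx(np.sqrt((1 - r_ref**2) / 38), abs=1e-12)

    @given(a=st.floats(0.1, 5), b=st.floats(-10, 10),
           c=st.floats(-5, -0.1))
    def test_affine_invariance_and_sign_flip(self, a, b, c):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 30))
        r0, _, _ = pearson_with_se(x, y)
        r_pos, _, _ = pearson_with_se(a * x + b, y)
        r_neg, _, _ = pearson_with_se(c * x + b, y)
        assert r_pos == pytest.approx(r0, abs=1e-9)
        assert r_neg == pytest.approx(-r0, abs=1e-9)


def _synthetic_scan_inputs(rng, n_years=16, signal_window=(125, 161), beta=-6.0,
                           noise_sd=5.0):
    """Daily temperatures + responses driven by one planted window."""
    regions = ("northern", "eastern", "southern", "western")
    rows, resp = [], []
    for year in range(2006, 2006 + n_years):
        for region in regions:
            doy = np.arange(91, 182)
            temps = rng.normal(5.0, 1.0) + rng.normal(0, 2.0, len(doy))
            # AR-ish smoothing so windows are locally distinct
            temps = np.convolve(temps, np.ones(15) / 15, mode="same")
            rows.append(pd.DataFrame({
                "year": year, "region": region, "day_of_year": doy,
                "temp_mean": temps, "precip_sum": 0.0}))
            sel = (doy >= signal_window[0]) & (doy <= signal_window[1])
            resp.append({"year": year, "region": region,
                         "start": 142 + beta * temps[sel].mean()
                         + rng.normal(0, noise_sd)})
    return pd.concat(rows, ignore_index=True), pd.DataFrame(resp)


class TestScanAndSelection:
    def test_scan_row_per_window_and_heatmap(self, rng):
        climate, metrics = _synthetic_scan_inputs(rng, n_years=6)
        wins = enumerate_windows((91, 121), min_len=7, step=2)
        scan = correlation_scan(metrics, climate, wins, "mean_temperature", "start")
        assert len(scan) == len(wins)
        heat = scan_heatmap_table(scan)
        assert set(zip(heat["open"], heat["close"])) == {
            (w.open_day, w.close_day) for w in wins}
        certain = scan[scan["certain"]]
        assert (certain["r"].abs() > 1.96 * certain["se_r"]).all()

    def test_zero_variance_window_omitted(self, rng):
        climate, metrics = _synthetic_scan_inputs(rng, n_years=4)
        climate.loc[climate["day_of_year"] <= 101, "temp_mean"] = 3.0
        wins = [WindowSpec(91, 99), WindowSpec(101, 111)]
        scan = correlation_scan(metrics, climate, wins, "mean_temperature", "start")
        assert set(zip(scan["open"], scan["close"])) == {(101, 111)}

    def test_single_certain_entry_selected(self):
        scan = pd.DataFrame({
            "open": [91, 95], "close": [101, 105], "length": [11, 11],
            "r": [0.9, 0.3], "se_r": [0.1, 0.3], "n": [20, 20],
            "certain": [True, False]})
        spec, row = select_best_window(scan)
        assert (spec.open_day, spec.close_day) == (91, 101)

    def test_tie_breaks_shorter_then_earlier(self):
        scan = pd.DataFrame({
            "open": [91, 95, 93], "close": [105, 103, 101], "length": [15, 9, 9],
            "r": [0.8, 0.8, -0.8], "se_r": [0.05] * 3, "n": [30] * 3,
            "certain": [True] * 3})
        spec, _ = select_best_window(scan)
        assert (spec.open_day, spec.close_day) == (93, 101)

    def test_no_certain_entries_flagged(self):
        scan = pd.DataFrame({
            "open": [91], "close": [101], "length": [11],
            "r": [0.1], "se_r": [0.3], "n": [10], "certain": [False]})
        spec, row = select_best_window(scan)
        assert spec is None and row is None

    def test_planted_window_recovered(self, rng):
        """The selected window substantially overlaps a planted causal
        window under a strong planted slope."""
        hits = 0
        for _ in range(10):
            climate, metrics = _synthetic_scan_inputs(rng, noise_sd=3.0)
            wins = enumerate_windows((91, 181), min_len=7, step=2)
            scan = correlation_scan(metrics, climate, wins, "mean_temperature", "start")
            spec, _ = select_best_window(scan)
            if spec is not None and spec.overlap_days(WindowSpec(125, 161)) >= 0.5 * spec.length:
                hits += 1
        assert hits >= 8
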