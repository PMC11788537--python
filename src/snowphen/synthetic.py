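"""Seeded synthetic observation + climate generator with known ground truth.

The generator emulates the study design that the pipeline targets: 16 years
(2006-2021) x 4 biogeographic regions, ~200 citizen-science observations
per region-year over March-October (~12,800 rows in total), a minority
likely-breeding state following a seasonal double-logistic probability
curve, daily temperature with a seasonal cycle, an autocorrelated weather
component and a warming trend, Bernoulli-Gamma precipitation, and monotone
snow-cover decline curves with planted 50%-crossing day and 95%->5% span.

True season start and end per year x region are constructed linearly from
window-summarized climate::

    start_{y,r} = mu_S + bT_s * meanTemp(W_T_start) + bP_s * precipDays(W_P_start)
                  + u_year + v_region + eps
    end_{y,r}   = mu_E + bT_e * meanTemp(W_T_end) + u'_year + v'_region + eps'

(window covariates centered at their realized means so the baselines are
the mean start/end days), and the observation-state curve p(d) is anchored
so that it crosses the detection threshold tau exactly at the true start
and end.  Ground truth is therefore defined in precisely the metric the
downstream estimators compute, making recovery error attributable to
estimation rather than definitional mismatch.

The autocorrelated weather component is what makes the *location* of the
causal windows identifiable: a purely annual temperature anomaly would
correlate equally with every candidate window.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import fsolve
from scipy.special import expit

from .data_model import (
    DEFAULT_CODE_LADDER,
    DEFAULT_CUT,
    DEFAULT_REGIONS,
    CodeMap,
    LIKELY_BREEDING,
    NONBREEDING,
    SeasonWindow,
)

logger = logging.getLogger("snowphen")

_LN19 = np.log(19.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the generator (defaults = study scale)."""

    years: tuple = tuple(range(2006, 2022))
    regions: tuple = DEFAULT_REGIONS
    n_obs_per_region_year: int = 200

    # true phenology (days of year; windows inclusive doy intervals)
    baseline_start_day: float = 142.0
    baseline_end_day: float = 230.0
    beta_T_start: float = -6.0        # days per degC in W_T_start
    beta_P_start: float = 2.5         # days per precipitation day in W_P_start
    beta_T_end: float = -1.8          # days per degC in W_T_end
    W_T_start: tuple = (125, 161)     # May 5 - Jun 10
    W_P_start: tuple = (109, 119)     # Apr 19 - Apr 29
    W_T_end: tuple = (165, 181)       # Jun 14 - Jun 30
    sd_year: float = 5.0              # random-intercept SD across years (days)
    sd_region: float = 5.0            # random-intercept SD across regions (days)
    sd_resid: float = 3.0             # residual SD of true start/end (days)

    # observation-state curve
    p_max: float = 0.35               # plateau probability of likely_breeding
    rise_scale: float = 5.0           # days, logistic rise scale
    fall_scale: float = 7.0           # days, logistic fall scale
    tau: float = 0.05                 # threshold the curve crosses at start/end
    summer_bulge: float = 0.0         # 0 = uniform effort; >0 weights mid-season

    # climate process
    domain: tuple = (60, 304)         # Mar 1 - Oct 31 day-of-year span
    temp_base: float = 2.0            # degC annual mean at station elevation
    temp_amplitude: float = 8.0       # degC seasonal half-range
    temp_peak_doy: float = 197.0      # mid-July
    temp_region_offsets: tuple = (-1.0, -0.5, 1.5, 0.0)
    temp_trend: float = 0.0533        # degC per year warming trend
    year_anomaly_sd: float = 0.3      # annual offset beyond the trend
    weather_sd: float = 1.5           # SD of the AR(1) weather component
    weather_corr_days: float = 15.0   # e-folding correlation length (days)
    daily_noise_sd: float = 2.0      # iid daily noise on top
    precip_prob: float = 0.45         # daily occurrence probability
    precip_shape: float = 0.9         # Gamma shape of wet-day amounts
    precip_scale: float = 6.0         # Gamma scale (mm)
    snow_max: float = 0.95            # seasonal maximum cover fraction
    melt50_base: float = 150.0        # mean planted 50%-crossing day
    melt50_region_offsets: tuple = (6.0, 3.0, -8.0, 0.0)
    melt50_sd: float = 12.0           # between-year SD of the 50% day
    melt_span_base: float = 45.0      # mean 95%->5% melt span (days)
    melt_span_sd: float = 8.0

    code_map: CodeMap = field(default_factory=CodeMap)

    def validate(self) -> None:
        if not self.years:
            raise ValueError("no years configured")
        if not (0.0 <= self.p_max <= 1.0):
            raise ValueError("p_max must be in [0, 1]")
        if 0.0 < self.p_max <= self.tau:
            raise ValueError("p_max <= tau: season undetectable by construction")
        if self.baseline_start_day >= self.baseline_end_day:
            raise ValueError("baseline start must precede baseline end")
        if self.n_obs_per_region_year <= 0:
            raise ValueError("observation effort must be positive")
        if not (0.5 < self.snow_max <= 1.0):
            raise ValueError("snow_max must be in (0.5, 1] for a defined melt timing")


def _doy_grid(config: SyntheticConfig) -> np.ndarray:
    return np.arange(config.domain[0], config.domain[1] + 1)


def _dates_for_year(year: int, config: SyntheticConfig) -> pd.DatetimeIndex:
    return pd.date_range(dt.date(year, 3, 1), dt.date(year, 10, 31), freq="D")


def generate_climate(config: SyntheticConfig, seed) -> pd.DataFrame:
    """Daily climate per region x year: temperature (seasonal sinusoid +
    regional offset + trend + annual anomaly + AR(1) weather + daily noise),
    Bernoulli-Gamma precipitation, and a monotone snow-cover decline with
    planted 50% day and 95%->5% span."""
    config.validate()
    rng = np.random.default_rng(seed)
    y0 = min(config.years)
    rho = float(np.exp(-1.0 / config.weather_corr_days))
    innov_sd = config.weather_sd * np.sqrt(1 - rho**2)
    frames = []
    for year in config.years:
        anomaly = rng.normal(0.0, config.year_anomaly_sd)
        for r_i, region in enumerate(config.regions):
            dates = _dates_for_year(year, config)
            n = len(dates)
            doy = dates.dayofyear.to_numpy()
            seasonal = (config.temp_base
                        + config.temp_amplitude
                        * np.cos(2 * np.pi * (doy - config.temp_peak_doy) / 365.0))
            weather = np.empty(n)
            weather[0] = rng.normal(0.0, config.weather_sd)
            eps = rng.normal(0.0, innov_sd, n)
            for i in range(1, n):
                weather[i] = rho * weather[i - 1] + eps[i]
            temp = (seasonal + config.temp_region_offsets[r_i]
                    + config.temp_trend * (year - y0) + anomaly + weather
                    + rng.normal(0.0, config.daily_noise_sd, n))
            wet = rng.random(n) < config.precip_prob
            amounts = rng.gamma(config.precip_shape, config.precip_scale, n)
            precip = np.where(wet, amounts, 0.0)
            d50 = (config.melt50_base + config.melt50_region_offsets[r_i]
                   + rng.normal(0.0, config.melt50_sd))
            span = max(10.0, config.melt_span_base + rng.normal(0.0, config.melt_span_sd))
            snow = snow_decline_curve(doy, config.snow_max, d50, span)
            frames.append(pd.DataFrame({
                "region": region, "date": dates, "year": year,
                "day_of_year": doy, "temp_mean": temp, "precip_sum": precip,
                "snow_cover_fraction": snow,
            }))
    out = pd.concat(frames, ignore_index=True)
    out["temp_mean"] = out["temp_mean"].round(6)
    out["precip_sum"] = out["precip_sum"].round(6)
    out["date"] = out["date"].dt.date
    return out

def snow_decline_curve(doy: np.ndarray, max_cover: float, d50: float,
                       span: float) -> np.ndarray:
    """Monotone logistic snow decline hitting absolute 0.5 cover at ``d50``
    with a 95%->5%-of-max span of ``span`` days.

    Values are rounded to 6 decimals so the planted crossing day is exact
    under a <= 0.5 comparison despite floating-point anchoring error.
    """
    k = span / (2.0 * _LN19)
    a = d50 - k * np.log(2.0 * max_cover - 1.0)
    return np.round(max_cover * expit(-(np.asarray(doy, float) - a) / k), 6)


def _window_mean_temp(climate: pd.DataFrame, window: tuple) -> pd.Series:
    sel = climate[(climate["day_of_year"] >= window[0])
                  & (climate["day_of_year"] <= window[1])]
    return sel.groupby(["year", "region"])["temp_mean"].mean()


def _window_precip_days(climate: pd.DataFrame, window: tuple, mm: float = 1.0) -> pd.Series:
    sel = climate[(climate["day_of_year"] >= window[0])
                  & (climate["day_of_year"] <= window[1])]
    return sel.groupby(["year", "region"])["precip_sum"].apply(lambda s: float((s >= mm).sum()))


def generate_truth(config: SyntheticConfig, climate: pd.DataFrame, seed) -> pd.DataFrame:
    """Planted true start/end per year x region from window-summarized
    climate plus year/region random intercepts and residual noise.

    Window covariates are centered at their realized across-sample means so
    that the configured baselines are the expected start/end days.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    tw_s = _window_mean_temp(climate, config.W_T_start)
    pw_s = _window_precip_days(climate, config.W_P_start)
    tw_e = _window_mean_temp(climate, config.W_T_end)
    u_start = dict(zip(config.years, rng.normal(0, config.sd_year, len(config.years))))
    u_end = dict(zip(config.years, rng.normal(0, config.sd_year, len(config.years))))
    v_start = dict(zip(config.regions, rng.normal(0, config.sd_region, len(config.regions))))
    v_end = dict(zip(config.regions, rng.normal(0, config.sd_region, len(config.regions))))
    season = SeasonWindow()
    # hard bounds the breeding-evidence rule imposes: evidence before May 1 /
    # after Aug 31 never counts, so a detectable season is confined to the
    # window (1-day interior margin keeps the tau-crossing strictly inside)
    season_lo = float(dt.date(2001, *season.start).timetuple().tm_yday + 1)
    season_hi = float(dt.date(2001, *season.end).timetuple().tm_yday - 1)
    rows = []
    for year in config.years:
        for region in config.regions:
            key = (year, region)
            t_s = tw_s[key] - tw_s.mean()
            p_s = pw_s[key] - pw_s.mean()
            t_e = tw_e[key] - tw_e.mean()
            start = (config.baseline_start_day + config.beta_T_start * t_s
                     + config.beta_P_start * p_s + u_start[year] + v_start[region]
                     + rng.normal(0, config.sd_resid))
            end = (config.baseline_end_day + config.beta_T_end * t_e
                   + u_end[year] + v_end[region] + rng.normal(0, config.sd_resid))
            rows.append({
                "year": year, "region": region,
                "latent_start": start, "latent_end": end,
                "true_start": float(np.clip(start, season_lo, season_hi)),
                "true_end": float(np.clip(end, season_lo, season_hi)),
                "window_temp_start": float(tw_s[key]),
                "window_precip_days_start": float(pw_s[key]),
                "window_temp_end": float(tw_e[key]),
            })
    truth = pd.DataFrame(rows)
    n_clip = int(((truth["latent_start"] != truth["true_start"])
                  | (truth["latent_end"] != truth["true_end"])).sum())
    if n_clip:
        logger.warning("truth: %d of %d seasons clipped to the May-Aug window",
                       n_clip, len(truth))
    lo, hi = config.domain
    bad = truth[(truth["true_start"] >= truth["true_end"])
                | (truth["true_start"] < lo) | (truth["true_end"] > hi)]
    if len(bad):
        b = bad.iloc[0]
        raise ValueError(
            f"configuration produced invalid true season for {b['region']} "
            f"{int(b['year'])}: start {b['true_start']:.1f}, end {b['true_end']:.1f}")
    return truth


def state_probability_curve(doy, true_start: float, true_end: float,
                            config: SyntheticConfig) -> np.ndarray:
    """Double-logistic p(d) anchored so p crosses tau exactly at the true
    start and end days (zero when p_max == 0)."""
    doy = np.asarray(doy, dtype=float)
    if config.p_max == 0.0:
        return np.zeros_like(doy)
    sr, sf, pm, tau = config.rise_scale, config.fall_scale, config.p_max, config.tau

    def curve(d, a_r, a_f):
        return pm * expit((d - a_r) / sr) * expit(-(d - a_f) / sf)

    # separated-anchor initial guess, refined jointly
    a_r0 = true_start + sr * np.log((pm - tau) / tau)
    a_f0 = true_end - sf * np.log((pm - tau) / tau)
    sol = fsolve(lambda ab: [curve(true_start, *ab) - tau, curve(true_end, *ab) - tau],
                 [a_r0, a_f0], full_output=False)
    return curve(doy, sol[0], sol[1])


def generate_observations(truth: pd.DataFrame, config: SyntheticConfig,
                          seed) -> pd.DataFrame:
    """Effort-weighted observation dates with Bernoulli(p(d)) states and
    breeding codes consistent with the states.

    Likely-breeding rows receive a random code at or above the map's cut
    point; nonbreeding rows get either no code or a code below the cut.
    The probability curve is zeroed outside the season window so that codes
    and dates always reclassify to the generated state.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    cmap = config.code_map
    season = SeasonWindow()
    cut = cmap.cut_rank
    hi_codes = cmap.ladder[cut:]
    lo_codes = cmap.ladder[:cut]
    rows = []
    for rec in truth.itertuples():
        dates = _dates_for_year(rec.year, config)
        n = config.n_obs_per_region_year
        weights = np.ones(len(dates))
        if config.summer_bulge > 0:
            mid = 0.5 * (len(dates) - 1)
            weights += config.summer_bulge * np.exp(
                -0.5 * ((np.arange(len(dates)) - mid) / (0.25 * len(dates))) ** 2)
        idx = rng.choice(len(dates), size=n, p=weights / weights.sum())
        obs_dates = dates[np.sort(idx)]
        doy = obs_dates.dayofyear.to_numpy()
        p = state_probability_curve(doy, rec.true_start, rec.true_end, config)
        in_season = np.array([season.contains(d.date()) for d in obs_dates])
        p = np.where(in_season, p, 0.0)
        likely = rng.random(n) < p
        codes = np.empty(n, dtype=object)
        for i, lb in enumerate(likely):
            if lb:
                codes[i] = hi_codes[rng.integers(len(hi_codes))]
            elif rng.random() < 0.5 and lo_codes:
                codes[i] = lo_codes[rng.integers(len(lo_codes))]
            else:
                codes[i] = None
        for d, dy, c, lb in zip(obs_dates, doy, codes, likely):
            rows.append({
                "date": d.date(), "year": rec.year, "day_of_year": int(dy),
                "region": rec.region, "breeding_code": c,
                "state": LIKELY_BREEDING if lb else NONBREEDING,
            })
    return pd.DataFrame(rows)


@dataclass
class SyntheticDataset:
    """A complete seeded study: climate, planted truth, observations."""

    config: SyntheticConfig
    climate: pd.DataFrame
    truth: pd.DataFrame
    observations: pd.DataFrame


def generate_dataset(config: SyntheticConfig | None = None, seed=0) -> SyntheticDataset:
    """Generate climate -> truth -> observations from one master seed."""
    config = config or SyntheticConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_climate, s_truth, s_obs = ss.spawn(3)
    climate = generate_climate(config, s_climate)
    truth = generate_truth(config, climate, s_truth)
    obs = generate_observations(truth, config, s_obs)
    return SyntheticDataset(config=config, climate=climate, truth=truth, observations=obs)
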