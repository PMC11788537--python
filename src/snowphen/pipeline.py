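"""End-to-end orchestration: simulate -> phenology -> metrics -> snow ->
window scan -> effects -> trend, under one config and one master seed.

Every analysis constant (season window, threshold, window search ranges,
precipitation-day threshold, snow thresholds, sampler budgets) lives in
:class:`RunConfig`; stage code reads them from the config, nothing is
hard-coded.  A run writes tidy CSV outputs plus a JSON manifest with the
config hash, seed, per-stage warnings and a checksum for every file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effects as eff
from . import metrics as met
from . import snow as sno
from . import windows as win
from .basis import build_cyclic_basis
from .data_model import DEFAULT_REGIONS, read_climate, read_observations, write_climate, write_observations
from .phenology import PhenologyGAM
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("snowphen")


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    output_dir: str = "snowphen_run"
    observations_path: str | None = None   # None -> simulate
    climate_path: str | None = None
    regions: tuple = DEFAULT_REGIONS
    years: tuple = tuple(range(2006, 2022))

    tau: float = 0.05
    tau_ladder: tuple = met.DEFAULT_TAU_LADDER
    point_rule: str = met.DEFAULT_POINT_RULE

    window_range_start: tuple = win.DEFAULT_SEARCH_RANGES["start"]
    window_range_end: tuple = win.DEFAULT_SEARCH_RANGES["end"]
    window_min_len: int = win.MIN_WINDOW_LENGTH
    window_step: int = win.WINDOW_STEP
    precip_day_mm: float = win.PRECIP_DAY_MM

    snow_timing_threshold: float = 0.5
    snow_hi: float = 0.95
    snow_lo: float = 0.05

    n_knots: int = 12
    domain: tuple = (60, 304)
    gam_method: str = "laplace"          # or "mcmc"
    gam_draws: int = 1000
    lmm_method: str = "reml"             # or "bayes"
    lmm_chains: int = 4
    lmm_iterations: int = 2000
    interaction_rule_level: float = 0.80  # keep interaction if this interval excludes 0
    trend_region: str = "eastern"

    seed: int = 0
    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim:
            cfg.simulate = SyntheticConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()})
        return cfg

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, (tuple, list)):
                return [enc(x) for x in o]
            return o
        return hashlib.sha256(json.dumps(enc(self), sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Human-readable violations; empty list means the config is usable."""
    v = []
    if not config.years:
        v.append("no years configured")
    if not (0 < config.tau < 1):
        v.append(f"tau {config.tau} outside (0, 1)")
    for name, rng in (("start", config.window_range_start), ("end", config.window_range_end)):
        if rng[1] <= rng[0]:
            v.append(f"window range for {name} ends before it starts: {rng}")
        elif rng[1] - rng[0] + 1 < config.window_min_len:
            v.append(f"window range for {name} shorter than min window length")
    if config.precip_day_mm < 0:
        v.append("negative precipitation-day threshold")
    if not (0 < config.snow_lo < config.snow_hi <= 1):
        v.append("snow thresholds must satisfy 0 < lo < hi <= 1")
    if config.window_step < 1:
        v.append("window step must be >= 1")
    if config.n_knots < 4:
        v.append("n_knots must be >= 4")
    if config.trend_region not in config.regions:
        v.append(f"trend region {config.trend_region!r} not in region set")
    if config.point_rule not in ("draw_median", "mean_curve"):
        v.append(f"unknown point rule {config.point_rule!r}")
    return v


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record):
        self.records.append(self.format(record))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Any stage failure raises with the stage name attached; outputs written
    so far remain on disk as the resumable checkpoint.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    collector.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(collector)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": [], "files": {}, "warnings": []}
    stage = "init"
    rng_root = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ["simulate", "gam", "lmm"], rng_root.spawn(3))}

    def record(path: Path):
        manifest["files"][path.name] = _sha256(path)

    try:
        # -- simulate / load ------------------------------------------------
        stage = "simulate"
        if config.observations_path is None or config.climate_path is None:
            ds = generate_dataset(config.simulate, seed=seeds["simulate"])
            obs, climate = ds.observations, ds.climate
            write_observations(obs, out / "observations.csv")
            write_climate(climate, out / "climate.csv")
            ds.truth.to_csv(out / "truth.csv", index=False, float_format="%.6f")
            for f in ("observations.csv", "climate.csv", "truth.csv"):
                record(out / f)
        else:
            obs = read_observations(config.observations_path, regions=config.regions)
            climate = read_climate(config.climate_path, regions=config.regions)
        manifest["stages"].append(stage)

        # -- phenology -------------------------------------------------------
        stage = "fit-phenology"
        basis = build_cyclic_basis(tuple(map(float, config.domain)), config.n_knots)
        gam_seeds = seeds["gam"].spawn(len(set(obs["year"])))
        curves = []
        fit_meta = []
        for s, (year, grp) in zip(gam_seeds, obs.groupby("year")):
            res = PhenologyGAM(grp, int(year), basis=basis,
                               regions=config.regions).fit(
                method=config.gam_method, n_draws=config.gam_draws, seed=s)
            fit_meta.append({"year": int(year), "converged": res.converged,
                             "rhat_max": res.rhat_max, "degenerate": res.degenerate})
            curves += list(res.curves().values())
        pd.DataFrame(fit_meta).to_csv(out / "phenology_fits.csv", index=False)
        summary_rows = []
        for c in curves:
            lo, hi = c.quantile(0.025), c.quantile(0.975)
            summary_rows.append(pd.DataFrame({
                "year": c.year, "region": c.region, "doy": c.grid,
                "p_mean": c.mean, "p_lo95": lo, "p_hi95": hi}))
        pd.concat(summary_rows, ignore_index=True).to_csv(
            out / "phenology_curves.csv", index=False, float_format="%.5f")
        record(out / "phenology_fits.csv")
        record(out / "phenology_curves.csv")
        manifest["stages"].append(stage)

        # -- season metrics --------------------------------------------------
        stage = "metrics"
        mtab = met.metrics_table(curves, tau=config.tau, point_rule=config.point_rule)
        mtab.to_csv(out / "season_metrics.csv", index=False, float_format="%.2f")
        sens = met.threshold_sensitivity(curves, config.tau_ladder, config.tau,
                                         config.point_rule)
        sens.to_csv(out / "threshold_sensitivity.csv", index=False, float_format="%.4f")
        record(out / "season_metrics.csv")
        record(out / "threshold_sensitivity.csv")
        manifest["stages"].append(stage)

        # -- snowmelt ---------------------------------------------------------
        stage = "snow-metrics"
        snow_tab = sno.snowmelt_table(climate)
        snow_tab.to_csv(out / "snowmelt_metrics.csv", index=False, float_format="%.2f")
        record(out / "snowmelt_metrics.csv")
        manifest["stages"].append(stage)

        # -- window scans -----------------------------------------------------
        stage = "scan-windows"
        best = {}
        for response, day_range in (("start", config.window_range_start),
                                    ("end", config.window_range_end)):
            windows = win.enumerate_windows(day_range, config.window_min_len,
                                            config.window_step)
            for variable in win.VARIABLES:
                scan = win.correlation_scan(mtab, climate, windows, variable,
                                            response, config.precip_day_mm)
                name = f"scan_{response}_{variable}.csv"
                scan.to_csv(out / name, index=False, float_format="%.5f")
                record(out / name)
                spec, row = win.select_best_window(scan)
                if spec is None and not scan.empty:
                    # fall back to the strongest (uncertain) window; flagged
                    idx = scan["r"].abs().idxmax()
                    row = scan.loc[idx]
                    spec = win.WindowSpec(int(row["open"]), int(row["close"]))
                    logger.warning("no certain window for %s/%s; "
                                   "using strongest uncertain window", response, variable)
                best[(response, variable)] = (spec, row)
        pd.DataFrame([
            {"response": r, "variable": v,
             "open": s.open_day if s else np.nan,
             "close": s.close_day if s else np.nan,
             "r": row["r"] if row is not None else np.nan,
             "certain": bool(row["certain"]) if row is not None else False}
            for (r, v), (s, row) in best.items()
        ]).to_csv(out / "best_windows.csv", index=False, float_format="%.5f")
        record(out / "best_windows.csv")
        manifest["stages"].append(stage)

        # -- effects models ----------------------------------------------------
        stage = "fit-effects"
        lmm_seeds = seeds["lmm"].spawn(3)
        effects_results = fit_effects_suite(
            mtab, climate, snow_tab, best, config, lmm_seeds)
        coef_frames = []
        for response, res in effects_results.items():
            tab = res.coef_table()
            tab.insert(0, "response", response)
            coef_frames.append(tab)
            re_tab = res.random_effect_table()
            re_tab.insert(0, "response", response)
            coef_frames.append(re_tab)
        pd.concat(coef_frames, ignore_index=True).to_csv(
            out / "effects_coefficients.csv", index=False, float_format="%.4f")
        record(out / "effects_coefficients.csv")
        manifest["stages"].append(stage)

        # -- temperature trends -------------------------------------------------
        stage = "trend"
        trends = fit_trend_suite(mtab, climate, config)
        pd.DataFrame([
            {"series": t.series, "slope": t.slope, "slope_lo95": t.slope_lo95,
             "slope_hi95": t.slope_hi95, "total_change": t.total_change,
             "n_years": t.n_years}
            for t in trends.values()
        ]).to_csv(out / "temperature_trends.csv", index=False, float_format="%.5f")
        record(out / "temperature_trends.csv")
        manifest["stages"].append(stage)
    except Exception as e:
        logger.removeHandler(collector)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    logger.removeHandler(collector)
    manifest["warnings"] = collector.records
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _covariate_table(mtab: pd.DataFrame, climate: pd.DataFrame,
                     snow_tab: pd.DataFrame, best: dict,
                     config: RunConfig) -> pd.DataFrame:
    """Merge phenology metrics with window summaries and snowmelt metrics."""
    df = mtab[["year", "region", "start", "end", "duration"]].copy()

    def add(col, response, variable):
        spec, _ = best[(response, variable)]
        if spec is None:
            df[col] = np.nan
            return
        summ = win.window_summary(climate, spec, variable, config.precip_day_mm)
        df[col] = df.merge(summ, on=["year", "region"], how="left")["value"].to_numpy()

    add("temp_start_window", "start", "mean_temperature")
    add("pdays_start_window", "start", "precipitation_days")
    add("temp_end_window", "end", "mean_temperature")
    return df.merge(snow_tab[["year", "region", "melt_timing", "melt_duration"]],
                    on=["year", "region"], how="left")


def _maybe_drop_interaction(model_builder, data, response, covs, interaction,
                            config: RunConfig, seed):
    """Reproducible proxy for the visual interaction check: keep the
    interaction only if its standardized coefficient's 80% interval
    excludes zero."""
    model = eff.BreedingEffectsModel(data, response, covs, interaction=interaction)
    res = model.fit(method=config.lmm_method, chains=config.lmm_chains,
                    iterations=config.lmm_iterations, seed=seed)
    lam = np.zeros(len(res.names))
    lam[-1] = 1.0
    _, lo, hi = res._linear_ci(lam, raw=False, level=config.interaction_rule_level)
    if lo <= 0.0 <= hi:
        logger.info("%s: interaction dropped (80%% interval covers 0)", response)
        model = eff.BreedingEffectsModel(data, response, covs)
        res = model.fit(method=config.lmm_method, chains=config.lmm_chains,
                        iterations=config.lmm_iterations, seed=seed)
    return res


def fit_effects_suite(mtab, climate, snow_tab, best, config: RunConfig,
                      seeds) -> dict[str, eff.BreedingEffectsResults]:
    """The three effects models (start, end, duration), mirroring the
    published model structures."""
    data = _covariate_table(mtab, climate, snow_tab, best, config)
    out = {}
    out["start"] = _maybe_drop_interaction(
        eff.BreedingEffectsModel, data, "start",
        ["temp_start_window", "pdays_start_window", "melt_timing"],
        ("temp_start_window", "pdays_start_window"), config, seeds[0])
    end_model = eff.BreedingEffectsModel(
        data, "end", ["temp_end_window", "melt_timing", "melt_duration"])
    out["end"] = end_model.fit(method=config.lmm_method, chains=config.lmm_chains,
                               iterations=config.lmm_iterations, seed=seeds[1])
    out["duration"] = _maybe_drop_interaction(
        eff.BreedingEffectsModel, data, "duration",
        ["temp_start_window", "pdays_start_window", "temp_end_window"],
        ("temp_start_window", "pdays_start_window"), config, seeds[2])
    return out


def fit_trend_suite(mtab, climate, config: RunConfig) -> dict[str, eff.TrendResults]:
    """Year trends of breeding-season mean temperature and summer
    (May-Aug) mean temperature in the trend region."""
    region = config.trend_region
    rows_bs, rows_summer = [], []
    for year in sorted(set(climate["year"])):
        sel = mtab[(mtab["year"] == year) & (mtab["region"] == region)]
        if len(sel) and np.isfinite(sel.iloc[0]["start"]):
            t = eff.breeding_season_mean_temp(
                climate, year, region, sel.iloc[0]["start"], sel.iloc[0]["end"])
            if np.isfinite(t):
                rows_bs.append({"year": year, "temp": t})
        summer = climate[(climate["year"] == year) & (climate["region"] == region)
                         & (climate["day_of_year"] >= 121)
                         & (climate["day_of_year"] <= 243)]
        if len(summer):
            rows_summer.append({"year": year, "temp": float(summer["temp_mean"].mean())})
    return {
        "breeding_season_mean_temp": eff.fit_trend(
            pd.DataFrame(rows_bs), "breeding_season_mean_temp"),
        "may_aug_mean_temp": eff.fit_trend(
            pd.DataFrame(rows_summer), "may_aug_mean_temp"),
    }
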