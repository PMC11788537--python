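"""Mixed-effect climate-sensitivity models and temperature-trend fits.

Start, end, or duration of the breeding season (one value per year x
region) is regressed on climate summaries from the critical windows and on
snowmelt metrics, with crossed random intercepts for year and for
biogeographic region and an optional temperature x precipitation
interaction.

Coefficients are reported in two parameterizations: *standardized*
(predictors z-scored, response in days — comparable effect sizes) and
*unstandardized* (raw units: days/degC, days per precipitation day, days
per day of snowmelt shift).  The model is fitted once on the standardized
design; the unstandardized coefficients and their covariance follow by the
exact affine reparametrization, so for interaction-free models the identity
standardized = unstandardized * SD(x) holds to machine precision.

Fitting engines: posterior sampling on the marginal likelihood (random
intercepts integrated out analytically; default, mirroring the Bayesian
analysis convention of four chains of 2000 iterations) or REML via
statsmodels MixedLM with GLS coefficient extraction (fast mode).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("snowphen")


def _z(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    m, s = float(np.mean(x)), float(np.std(x, ddof=1))
    return (x - m) / s, m, s


class BreedingEffectsModel:
    """LMM for one phenology response with year + region random intercepts.

    Parameters
    ----------
    data : one row per year x region, columns: year, region, the response,
        and every covariate.  Incomplete rows are dropped with a warning.
    response : column name ("start", "end" or "duration" conventionally).
    covariates : fixed-effect columns, raw units.
    interaction : optional (a, b) pair of covariate names whose product is
        added as a fixed effect.
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 covariates: list[str], interaction: tuple[str, str] | None = None):
        cols = [response] + list(covariates)
        complete = data.dropna(subset=cols)
        if len(complete) < len(data):
            logger.warning("effects model %s: dropped %d incomplete rows",
                           response, len(data) - len(complete))
        if len(complete) < 10:
            raise ValueError(f"effects model {response}: fewer than 10 complete rows")
        for c in covariates:
            if np.std(complete[c].to_numpy(dtype=float), ddof=1) == 0:
                raise ValueError(f"zero-variance covariate: {c!r}")
        if interaction is not None:
            a, b = interaction
            if a not in covariates or b not in covariates:
                raise ValueError("interaction names must be among the covariates")
        self.data = complete.reset_index(drop=True)
        self.response = response
        self.covariates = list(covariates)
        self.interaction = tuple(interaction) if interaction else None
        self.y = self.data[response].to_numpy(dtype=float)
        self._build_designs()
        self._Zy = pd.get_dummies(self.data["year"]).to_numpy(dtype=float)
        self._Zr = pd.get_dummies(self.data["region"]).to_numpy(dtype=float)

    def _build_designs(self):
        n = len(self.data)
        raw = {c: self.data[c].to_numpy(dtype=float) for c in self.covariates}
        self.x_mean = {c: float(np.mean(v)) for c, v in raw.items()}
        self.x_sd = {c: float(np.std(v, ddof=1)) for c, v in raw.items()}
        zcols = {c: (raw[c] - self.x_mean[c]) / self.x_sd[c] for c in self.covariates}
        names = ["Intercept"] + self.covariates
        Xz = [np.ones(n)] + [zcols[c] for c in self.covariates]
        if self.interaction:
            a, b = self.interaction
            names.append(f"{a}:{b}")
            Xz.append(zcols[a] * zcols[b])
        self.names = names
        self.X_std = np.column_stack(Xz)
        # exact affine map standardized coefs -> raw-unit coefs
        p = len(names)
        T = np.zeros((p, p))
        T[0, 0] = 1.0
        for j, c in enumerate(self.covariates, start=1):
            T[j, j] = 1.0 / self.x_sd[c]
            T[0, j] = -self.x_mean[c] / self.x_sd[c]
        if self.interaction:
            a, b = self.interaction
            ia, ib = 1 + self.covariates.index(a), 1 + self.covariates.index(b)
            sab = self.x_sd[a] * self.x_sd[b]
            k = p - 1
            T[k, k] = 1.0 / sab
            T[ia, k] = -self.x_mean[b] / sab
            T[ib, k] = -self.x_mean[a] / sab
            T[0, k] = self.x_mean[a] * self.x_mean[b] / sab
        self._T = T

    # -- likelihood machinery ---------------------------------------------
    def _marginal_V(self, sigma2: float, tau_year: float, tau_region: float) -> np.ndarray:
        n = len(self.y)
        return (sigma2 * np.eye(n)
                + tau_year * self._Zy @ self._Zy.T
                + tau_region * self._Zr @ self._Zr.T)

    def _gls(self, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """GLS point estimate and covariance of the standardized coefs."""
        L = np.linalg.cholesky(V)
        Xw = np.linalg.solve(L, self.X_std)
        yw = np.linalg.solve(L, self.y)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        return beta, np.linalg.inv(XtX)

    def _log_marginal(self, beta: np.ndarray, sds: np.ndarray) -> float:
        sigma, sd_y, sd_r = sds
        V = self._marginal_V(sigma**2, sd_y**2, sd_r**2)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf
        resid = np.linalg.solve(L, self.y - self.X_std @ beta)
        return float(-np.sum(np.log(np.diag(L))) - 0.5 * resid @ resid)

    # -- fitting -----------------------------------------------------------
    def fit(self, method: str = "bayes", chains: int = 4, iterations: int = 2000,
            seed=None) -> "BreedingEffectsResults":
        if method == "reml":
            return self._fit_reml()
        if method == "bayes":
            return self._fit_bayes(chains, iterations, seed)
        raise ValueError(f"unknown fitting method {method!r}")

    def _fit_reml(self) -> "BreedingEffectsResults":
        import statsmodels.regression.mixed_linear_model as mlm

        df = self.data.copy()
        for j, nm in enumerate(self.names):
            df[f"_x{j}"] = self.X_std[:, j]
        df["_g"] = 1
        vc = {"year": "0 + C(year)", "region": "0 + C(region)"}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = mlm.MixedLM.from_formula(
                f"{self.response} ~ 0 + " + " + ".join(f"_x{j}" for j in range(len(self.names))),
                groups="_g", vc_formula=vc, data=df)
            mres = md.fit(reml=True, method="lbfgs")
        tau = {k: float(v) for k, v in zip(md.exog_vc.names, np.maximum(mres.vcomp, 0.0))}
        sigma2 = float(mres.scale)
        singular = min(tau.values()) < 1e-8 * sigma2
        if singular:
            logger.warning("effects model %s: near-singular random-effect structure",
                           self.response)
        V = self._marginal_V(sigma2, tau["year"], tau["region"])
        beta, cov = self._gls(V)
        return BreedingEffectsResults(
            model=self, beta_std=beta, cov_std=cov,
            re_sd={"year": np.sqrt(tau["year"]), "region": np.sqrt(tau["region"]),
                   "residual": np.sqrt(sigma2)},
            method="reml", draws_std=None, sd_draws=None,
            rhat_max=np.nan, singular=singular,
        )

    def _fit_bayes(self, chains: int, iterations: int, seed) -> "BreedingEffectsResults":
        import emcee

        from .phenology import _split_rhat

        rng = np.random.default_rng(seed)
        start = self._fit_reml()
        p = len(self.names)
        ndim = p + 3
        scale_y = float(np.std(self.y, ddof=1))

        def log_post(theta):
            beta, log_sds = theta[:p], theta[p:]
            if np.any(np.abs(log_sds) > 12):
                return -np.inf
            sds = np.exp(log_sds)
            ll = self._log_marginal(beta, sds)
            if not np.isfinite(ll):
                return -np.inf
            # weakly-informative: N(0, (20*sd_y)^2) on coefs; half-Student-t
            # with 3 df and scale 2.5*sd_y on the three SDs (the convention
            # of Bayesian regression defaults; log-scale Jacobian included)
            lp = -0.5 * np.sum((beta / (20 * scale_y)) ** 2)
            t_scale = 2.5 * scale_y
            lp += np.sum(-2.0 * np.log1p((sds / t_scale) ** 2 / 3.0) + log_sds)
            return ll + lp

        nwalkers = max(2 * ndim + 2, 4 * chains)
        nwalkers += (-nwalkers) % chains
        # parameter order: beta..., log(sigma), log(sd_year), log(sd_region)
        center = np.concatenate([
            start.beta_std,
            np.log(np.maximum([start.re_sd["residual"], start.re_sd["year"],
                               start.re_sd["region"]], 1e-2 * scale_y)),
        ])
        p0 = center + 0.05 * rng.standard_normal((nwalkers, ndim)) * np.maximum(
            np.abs(center), 0.5)
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post)
        sampler._random = np.random.RandomState(rng.integers(2**31 - 1))
        sampler.run_mcmc(p0, iterations, progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=iterations // 2)  # (steps, walkers, ndim)
        grouped = chain.reshape(chain.shape[0], chains, -1, ndim)
        grouped = grouped.transpose(1, 0, 2, 3).reshape(chains, -1, ndim)
        rhat_max = float(np.max(_split_rhat(grouped)))
        flat = chain.reshape(-1, ndim)
        draws_std = flat[:, :p]
        sd_draws = np.exp(flat[:, p:])  # columns: residual, year, region
        beta = draws_std.mean(axis=0)
        cov = np.cov(draws_std.T)
        if rhat_max >= 1.01:
            logger.warning("effects model %s: max R-hat %.3f >= 1.01",
                           self.response, rhat_max)
        return BreedingEffectsResults(
            model=self, beta_std=beta, cov_std=np.atleast_2d(cov),
            re_sd={"residual": float(np.median(sd_draws[:, 0])),
                   "year": float(np.median(sd_draws[:, 1])),
                   "region": float(np.median(sd_draws[:, 2]))},
            method="bayes", draws_std=draws_std, sd_draws=sd_draws,
            rhat_max=rhat_max, singular=False,
        )


@dataclass
class BreedingEffectsResults:
    """Fitted effects LMM: both coefficient parameterizations + predictions."""

    model: BreedingEffectsModel
    beta_std: np.ndarray
    cov_std: np.ndarray = field(repr=False)
    re_sd: dict
    method: str
    draws_std: np.ndarray | None = field(repr=False, default=None)
    sd_draws: np.ndarray | None = field(repr=False, default=None)
    rhat_max: float = np.nan
    singular: bool = False

    # -- parameterizations --------------------------------------------------
    @property
    def names(self) -> list[str]:
        return self.model.names

    @property
    def beta_raw(self) -> np.ndarray:
        return self.model._T @ self.beta_std

    @property
    def cov_raw(self) -> np.ndarray:
        T = self.model._T
        return T @ self.cov_std @ T.T

    @property
    def draws_raw(self) -> np.ndarray | None:
        if self.draws_std is None:
            return None
        return self.draws_std @ self.model._T.T

    def coef_draws(self, n: int = 4000, seed=None) -> np.ndarray:
        """Standardized-coefficient draws (posterior or Gaussian approx)."""
        if self.draws_std is not None:
            return self.draws_std
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(self.cov_std + 1e-12 * np.eye(len(self.beta_std)))
        return self.beta_std + rng.standard_normal((n, len(self.beta_std))) @ L.T

    def _linear_ci(self, lam: np.ndarray, raw: bool, level: float = 0.95):
        """Estimate + interval for a linear functional of the coefficients."""
        beta = self.beta_raw if raw else self.beta_std
        est = float(lam @ beta)
        if self.draws_std is not None:
            draws = (self.draws_raw if raw else self.draws_std) @ lam
            a = (1 - level) / 2
            return est, float(np.quantile(draws, a)), float(np.quantile(draws, 1 - a))
        cov = self.cov_raw if raw else self.cov_std
        se = float(np.sqrt(lam @ cov @ lam))
        zq = stats.norm.ppf(1 - (1 - level) / 2)
        return est, est - zq * se, est + zq * se

    def coef_table(self, level: float = 0.95) -> pd.DataFrame:
        """Standardized and unstandardized coefficients with intervals
        (the layout of the published effect tables)."""
        rows = []
        for j, nm in enumerate(self.names):
            lam = np.zeros(len(self.names))
            lam[j] = 1.0
            s, slo, shi = self._linear_ci(lam, raw=False, level=level)
            u, ulo, uhi = self._linear_ci(lam, raw=True, level=level)
            rows.append({"term": nm, "standardized": s, "std_lo95": slo, "std_hi95": shi,
                         "unstandardized": u, "unstd_lo95": ulo, "unstd_hi95": uhi})
        return pd.DataFrame(rows)

    def random_effect_table(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for j, nm in enumerate(["residual", "year", "region"]):
            if self.sd_draws is not None:
                a = (1 - level) / 2
                lo = float(np.quantile(self.sd_draws[:, j], a))
                hi = float(np.quantile(self.sd_draws[:, j], 1 - a))
            else:
                lo = hi = np.nan
            rows.append({"term": f"{nm} (SD)", "sd": self.re_sd[nm],
                         "lo95": lo, "hi95": hi})
        return pd.DataFrame(rows)

    # -- effects -------------------------------------------------------------
    def effect_per_unit(self, covariate: str, delta: float = 1.0,
                        level: float = 0.95) -> tuple[float, float, float]:
        """Response change (days) for a ``delta`` change in one covariate.

        For models with an interaction involving the covariate, the slope is
        evaluated at the sample mean of the interacting covariate.
        """
        if covariate not in self.model.covariates:
            raise ValueError(f"covariate {covariate!r} not in model")
        lam = np.zeros(len(self.names))
        lam[1 + self.model.covariates.index(covariate)] = 1.0
        if self.model.interaction and covariate in self.model.interaction:
            a, b = self.model.interaction
            other = b if covariate == a else a
            lam[len(self.names) - 1] = self.model.x_mean[other]
        est, lo, hi = self._linear_ci(lam * delta, raw=True, level=level)
        return est, lo, hi

    def scenario_contrast(self, scenario_a: dict, scenario_b: dict,
                          level: float = 0.95) -> tuple[float, float, float]:
        """Predicted response difference (a minus b), random effects at 0."""

        def design_row(scn: dict) -> np.ndarray:
            missing = set(self.model.covariates) - set(scn)
            if missing:
                raise ValueError(f"scenario missing covariates: {sorted(missing)}")
            row = [1.0] + [float(scn[c]) for c in self.model.covariates]
            if self.model.interaction:
                a, b = self.model.interaction
                row.append(float(scn[a]) * float(scn[b]))
            for c in self.model.covariates:
                x = self.model.data[c].to_numpy(dtype=float)
                if not (x.min() <= scn[c] <= x.max()):
                    logger.warning("scenario extrapolates %s=%g beyond observed "
                                   "range [%g, %g]", c, scn[c], x.min(), x.max())
            return np.array(row)

        lam = design_row(scenario_a) - design_row(scenario_b)
        return self._linear_ci(lam, raw=True, level=level)

    def summary(self) -> str:
        m = self.model
        tab = self.coef_table()
        ret = [
            f"Linear mixed-effects model: {m.response} ~ "
            + " + ".join(m.covariates)
            + (f" + {m.interaction[0]}:{m.interaction[1]}" if m.interaction else ""),
            f"  n = {len(m.y)} year x region rows; random intercepts: year, region",
            f"  method: {self.method}"
            + (f"   max R-hat: {self.rhat_max:.4f}" if np.isfinite(self.rhat_max) else ""),
            "",
            tab.to_string(index=False, float_format=lambda v: f"{v:8.3f}"),
            "",
            self.random_effect_table().to_string(
                index=False, float_format=lambda v: f"{v:8.3f}"),
        ]
        if self.singular:
            ret.append("  note: random-effect structure near-singular; SDs near 0")
        return "\n".join(ret)


# ---------------------------------------------------------------------------
# Temperature trends


@dataclass
class TrendResults:
    """Linear temperature trend across years."""

    series: str
    slope: float          # degC / year
    slope_lo95: float
    slope_hi95: float
    span_years: int       # last year - first year
    n_years: int

    @property
    def total_change(self) -> float:
        """Slope times the year span of the study period."""
        return self.slope * self.span_years

    @property
    def total_change_interval(self) -> tuple[float, float]:
        return self.slope_lo95 * self.span_years, self.slope_hi95 * self.span_years

    def summary(self) -> str:
        lo, hi = self.total_change_interval
        return (f"Temperature trend ({self.series}): "
                f"{self.slope:+.4f} degC/yr (95% CI {self.slope_lo95:+.4f} to "
                f"{self.slope_hi95:+.4f}); total change over {self.span_years} years: "
                f"{self.total_change:+.2f} degC ({lo:+.2f} to {hi:+.2f})")


class TemperatureTrend:
    """Gaussian linear model of an annual mean-temperature series on year."""

    def __init__(self, years, temps, series: str = "annual_mean_temp"):
        self.years = np.asarray(years, dtype=float)
        self.temps = np.asarray(temps, dtype=float)
        self.series = series
        if len(self.years) < 3:
            raise ValueError("trend needs at least 3 years")
        if np.std(self.years) == 0:
            raise ValueError("all observations in the same year")

    def fit(self) -> TrendResults:
        import statsmodels.api as sm

        X = sm.add_constant(self.years)
        res = sm.OLS(self.temps, X).fit()
        lo, hi = res.conf_int(alpha=0.05)[1]
        return TrendResults(
            series=self.series, slope=float(res.params[1]),
            slope_lo95=float(lo), slope_hi95=float(hi),
            span_years=int(self.years.max() - self.years.min()),
            n_years=len(self.years),
        )


def fit_trend(annual: pd.DataFrame, series: str = "annual_mean_temp") -> TrendResults:
    """Trend fit from a (year, temp) table."""
    return TemperatureTrend(annual["year"], annual["temp"], series).fit()


def breeding_season_mean_temp(climate: pd.DataFrame, year: int, region: str,
                              start_day: float, end_day: float) -> float:
    """Mean daily temperature over the breeding season [start, end] for one
    year x region; NaN when the season is undefined."""
    if not (np.isfinite(start_day) and np.isfinite(end_day)):
        return np.nan
    sel = climate[(climate["year"] == year) & (climate["region"] == region)
                  & (climate["day_of_year"] >= start_day)
                  & (climate["day_of_year"] <= end_day)]
    if sel.empty:
        return np.nan
    return float(sel["temp_mean"].mean())
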