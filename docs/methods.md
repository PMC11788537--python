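# Methods

This note documents the statistical choices in `snowphen`: the models, the
defaults and their units, the synthetic-data generator's assumptions, and
the numerical decisions a user re-fitting or extending the pipeline should
know about.

## Breeding states from citizen-science codes

Each record carries an ordinal breeding-evidence code (atlas-style ladder,
configurable via `CodeMap`). A record is *likely breeding* iff its code is
at or above the courtship cut point **and** its date falls in May 1–Aug 31;
records with no code, weaker codes, or out-of-season dates are
*nonbreeding*. The two states are exhaustive — records below the cut are
retained as nonbreeding rather than excluded, because the state is defined
as "evidence of probable breeding observed", not "breeding absent".
Day-of-year uses each record's own calendar; in leap years all dates after
Feb shift by one day, a discrepancy far below phenological noise.

## Phenology curves

One binomial GAM per year:

logit p(d, r) = α + f(d) + b_r + f_r(d),

with a shared global smoother f and per-region deviations (b_r, f_r).

* **Basis.** Cyclic cubic regression splines (value-at-knots
  parametrization; penalty = exact ∫f″², `S = D'B⁻¹D`), default 12 knots on
  day-of-year [60, 304] (Mar 1–Oct 31). Periodicity pins the curve level at
  both ends of the modelled window, where breeding evidence is structurally
  absent. The construction matches the mgcv-style cyclic basis (verified
  against patsy's implementation in the tests). The penalty null space
  (constants) is eigen-projected out so smoothers combine cleanly with
  explicit intercepts.
* **Smoothing.** Two hyperparameters — curvature of the global smoother and
  shared curvature of the region deviations — are chosen by maximizing the
  Laplace approximation to the marginal likelihood (empirical Bayes, the
  mgcv convention), optimized by Nelder–Mead with warm-started penalized
  IRLS inner solves.
* **Region-deviation amplitude is a fixed prior, not a selected
  hyperparameter.** With only four regions, marginal-likelihood selection
  of a deviation ridge systematically over-shrinks sparse, shift-type
  regional differences (a region breeding weeks later than the rest needs a
  large local deviation exactly where its data are least informative); we
  measured crossings biased toward the pooled curve by up to ~25 days, and
  the same behavior in an independent REML hierarchical-GAM fit of the same
  data. Deviations therefore get a fixed weakly-informative N(0, 2.5²)
  prior on the logit scale (`deviation_prior_sd`), the scale convention of
  Bayesian regression defaults; partial pooling is retained (fully
  independent per-region fits produce spurious tail crossings and were
  rejected).
* **Posterior draws.** Default: 1000 draws from the Gaussian (Laplace)
  approximation at the penalized MLE — fast and adequate for curve
  functionals. Reference mode: ensemble MCMC over the penalized posterior
  at the empirical-Bayes smoothing, with split-chain potential scale
  reduction; fits with max R̂ ≥ 1.01 are flagged non-converged. A weak
  N(0, 10²) prior on the intercept keeps degenerate years (single state
  observed) finite.

## Season metrics

Start = first grid day with p(d) > τ (τ = 0.05 default); end = first day
after the post-start maximum with p(d) < τ (anchoring after the peak makes
"drops below" unambiguous for mildly wiggly fits); duration = end − start.
Crossings are computed on the daily grid as integer days, per posterior
draw. The **point estimate is the median of per-draw crossings**; the
crossing of the posterior-mean curve is available (`point_rule=
"mean_curve"`) but is biased outward: averaging draws inflates the
low-probability tails (Jensen), moving low-threshold crossings ~2–4 days
early. Per-draw quantiles give the 95 % intervals either way. Starts are
undefined (flagged, not an exception) when most draws never exceed τ; ends
that never drop below τ are censored at the domain boundary and flagged.

The sensitivity analysis recomputes durations for τ ∈ {1 %, …, 12 %} and
reports each threshold's Pearson correlation with the 5 % reference
durations across year × region curves.

## Snowmelt metrics

Melt timing = first day after the day of seasonal maximum cover with
absolute cover ≤ 0.50 (undefined if the maximum never exceeds 0.50); melt
duration = days between the first post-peak days below 95 % and below 5 %
**of the seasonal maximum** — relative thresholds, because full cover is
not reached everywhere. "After snowmelt started" is operationalized as
"after the day of maximum cover", the unique unambiguous anchor in a daily
series. Ties at a threshold count as crossed (≤ / <); a `strict` flag flips
the comparison. Consequence of the definitions: duration is invariant to
rescaling the whole series, timing is not.

## Sliding-window scan

Windows of ≥ 7 days with both endpoints on a 2-day grid anchored at the
search-range start (Apr 1–Jun 30 for start; Apr 15–Aug 15 for end);
summaries are window-mean temperature or the count of days with ≥ 1 mm
precipitation. Pearson correlations are pooled over year × region points
(max n = 64; point estimates of start/end feed the scan — smoother
uncertainty enters later through the LMM stage). SE = √((1−r²)/(n−2)), the
standard large-sample form; *certain* ⇔ |r| > 1.96·SE. The best window is
the certain window with the largest |r| (ties → shorter, then earlier).
Because ~1000 windows are tested, the certainty filter is the multiplicity
control; its null behavior (per-window false-positive rate ≈ nominal under
an independent response) is checked by simulation in the acceptance suite.

## Effects models

Gaussian LMMs, one per response (start / end / duration), with crossed
random intercepts for year and region. Fixed effects: critical-window mean
temperature, critical-window precipitation days, snowmelt timing and/or
duration, and optionally a temperature × precipitation interaction —
retained only when the standardized interaction's 80 % interval excludes
zero (a reproducible proxy for a visual interaction check;
`interaction_rule_level`).

Coefficients are reported in two parameterizations computed from **one**
fit: standardized (z-scored predictors, response in days) and
unstandardized (raw units), linked by the exact affine reparametrization —
so standardized = unstandardized × SD(x) holds to machine precision for
every term of an interaction-free model. With an interaction, raw main
effects are slopes at zero of the other covariate; `effect_per_unit`
evaluates slopes at the interacting covariate's mean instead.

Engines: (1) default Bayesian — ensemble MCMC on the marginal likelihood
(random intercepts integrated out analytically), four chain-groups × 2000
iterations, flat-ish N(0, (20·SD(y))²) priors on coefficients and
half-Student-t(3, 2.5·SD(y)) priors on the three SDs (the reference-tooling
convention; the heavier tail matters — with only 4 regions it is what
keeps 95 % intervals at nominal frequentist coverage, where Wald/REML
intervals cover ~93 %); (2) REML via statsmodels MixedLM with GLS
coefficient extraction — fast, used widely in the tests.

Temperature trends are ordinary Gaussian linear models of annual mean
temperature on year; total change = slope × (last − first year).

## Synthetic-data generator

Defaults emulate the targeted study design: 16 years (2006–2021), 4
regions, 200 observations per region-year (12,800 rows), breeding
proportion plateau p_max = 0.35, τ = 0.05.

* **Climate.** Daily Mar 1–Oct 31 per region-year. Temperature = seasonal
  cosine (mean 2 °C, amplitude 8 °C, peak mid-July) + region offsets
  (−1…+1.5 °C) + 0.0533 °C/yr trend + annual anomaly (SD 0.3 °C) + an AR(1)
  "weather" component (SD 1.5 °C, 15-day correlation length) + daily noise
  (SD 2 °C). The AR(1) component is essential: a purely annual anomaly
  would correlate equally with every candidate window, leaving the causal
  window's *location* unidentifiable by construction. Precipitation:
  Bernoulli(0.45) × Gamma(0.9, 6 mm). Snow: monotone logistic decline
  anchored to hit absolute 0.5 cover exactly on the planted 50 % day with
  the planted 95 %→5 % span (values rounded to 6 decimals so the planted
  crossing is exact under ≤ comparisons); snow is generated independent of
  temperature.
* **Truth.** start = 142 − 6·meanTemp(days 125–161) + 2.5·precipDays(days
  109–119) + u_year + v_region + ε; end = 230 − 1.8·meanTemp(days 165–181)
  + u′ + v′ + ε′; SDs (days): year 5, region 5, residual 3; window
  covariates centered at their realized means. The planted windows are the
  published critical windows (May 5–Jun 10; Apr 19–29; Jun 14–30 in
  day-of-year), and the coefficient and SD magnitudes mirror the published
  effect tables. Latent seasons are clipped to May 2–Aug 30 (recorded both
  ways): evidence outside May–Aug never counts, so a detectable season
  cannot extend past the window — truths outside it would be undefined in
  the very metric the pipeline estimates.
* **Observations.** Uniform effort over Mar–Oct (configurable summer
  bulge), state ~ Bernoulli(p(d)) with a double-logistic p (rise scale 5 d,
  fall scale 7 d) anchored so p crosses τ **exactly** at the true start and
  end — ground truth is defined in precisely the metric downstream code
  computes, so recovery error is attributable to estimation. Codes are
  assigned consistently with states (likely rows get courtship-or-higher
  codes), so classification round-trips.

**What the generator does not emulate:** spatially explicit snow or
climate, observer-effort bursts and spatial bias, misidentified or
misclassified codes, double-brood bimodality in p(d), and snow–temperature
coupling. Passing recovery tests therefore demonstrate estimator
correctness under a well-specified data-generating process, not robustness
to these real-data features.

## Known limitations and measured behavior

* **Threshold-crossing recovery is information-limited.** At 200
  observations per region-year (~0.8/day), a ±5-day window around the 5 %
  crossing contains ~16 observations — binomial SE on p̂ alone is ~0.05.
  Measured start/end recovery MAE is ~4–8 days across generator seeds
  (mean-absolute error over the 64 year × region seasons), sitting at this
  information floor plus a residual hierarchical-shrinkage bias: year-level
  variation is recovered essentially unbiased (slope ≈ 0.95) while
  within-year region contrasts are shrunk to ~0.5–0.85 depending on seed.
* **Downstream attenuation.** Because region contrasts in the estimated
  start/end are partially pooled, pipeline-level regressions of *estimated*
  metrics on window climate recover roughly half the planted slope
  magnitude (e.g. ≈ −3 vs planted −6 days/°C). Slope inference on true or
  externally measured phenology (the replicate studies in the acceptance
  script) is unbiased with nominal interval coverage.
* Window selection among ~1000 highly correlated candidates has a ~9 %
  chance (measured) of picking a window overlapping the planted one by
  less than half its length, even at a planted slope of −6 days/°C.
* MCMC modes exist for reference but the shipped inference is approximate
  (Laplace for the GAM; ensemble sampling on the marginal likelihood for
  the LMM); fits report convergence flags and the pipeline warns rather
  than silently accepting non-converged fits.

## Problem sizes used by the test and acceptance runs

The acceptance computations use the full study scale (16 × 4 × 200
observations; 100 scan replicates; 50 Bayesian LMM replicates; 200 null
scans; 100 trend replicates). Unit tests use 2–5 year × 2 region scenarios
with 60–150 observations per region-year, chosen to exercise every code
path at interactive speeds.
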