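# snowphen

Breeding-season phenology of a high-elevation songbird (the white-winged
snowfinch, *Montifringilla nivalis*) estimated from citizen-science
breeding-evidence records, and the climate sensitivity of that phenology.
The package is a reusable pipeline for ecologists who have (a) opportunistic
bird observations carrying ordinal breeding codes and (b) daily climate
summaries per region: it estimates when the breeding season starts and ends
each year in each region, how long it lasts, and which temperature,
precipitation and snowmelt windows best explain the between-year variation.

## The model

**Phenology curves.** Observations are collapsed to a binary state —
*likely breeding* if the breeding code indicates courtship or stronger
evidence within May 1–Aug 31, else *nonbreeding*. For each year the package
fits a hierarchical binomial GAM over day of year *d* and region *r*:

    logit p(d, r) = α + f(d) + b_r + f_r(d)

where *f* is a cyclic cubic regression spline shared by all regions (the
cyclic constraint ties the March and October ends of the curve to a common
low level) and each region adds an intercept offset and a deviation
smoother shrunk toward zero. Smoothing is selected by Laplace-approximate
marginal likelihood; posterior curve draws come from the Gaussian
approximation at the penalized MLE (an MCMC mode with split-chain R̂ < 1.01
convergence checking is available).

**Season metrics.** The season start is the first day the expected
proportion of likely-breeding observations exceeds τ = 5 %; the end is the
first day after the post-start peak it drops below τ; duration = end −
start. Crossings are extracted per posterior draw (median = point estimate,
quantiles = credible intervals), and a sensitivity analysis re-derives
durations for τ = 1 %…12 %.

**Snowmelt.** From daily snow-cover fractions: melt timing = first day
after peak cover at ≤ 50 % absolute cover; melt duration = days between
95 % and 5 % of the seasonal maximum.

**Climate windows.** Candidate windows (≥ 7 days, endpoints on a 2-day
grid; Apr 1–Jun 30 for the start, Apr 15–Aug 15 for the end) are summarized
as mean temperature or number of precipitation days (≥ 1 mm). Each window
summary is correlated (Pearson *r*, SE = √((1−r²)/(n−2))) with the
phenology metric over pooled year × region points; only windows whose 95 %
interval excludes zero are kept, and the one with the largest |r| is the
critical window.

**Effects models.** Start, end and duration are regressed on critical-
window climate and snowmelt metrics in Gaussian LMMs with crossed random
intercepts for year and region, an optional temperature × precipitation
interaction, and both standardized (z-scored predictors) and unstandardized
(days/°C, days per precipitation day) coefficients. Linear models of annual
mean temperature on year quantify warming trends.

A seeded synthetic-data generator reproduces the study design (16 years ×
4 regions, ~12,800 observations) with known planted truth — true season
days constructed linearly from window climate — so every stage has a
parameter-recovery test surface.

## Worked example

```python
from snowphen import RunConfig, run_all

manifest = run_all(RunConfig(output_dir="demo_run", seed=1))
print(manifest["stages"])
```

runs the full pipeline on a simulated study and writes tidy CSVs. From the
run above (`demo_run/best_windows.csv` and `effects_coefficients.csv`):

```
response           variable  open  close        r  certain
   start   mean_temperature   129    155 -0.59312     True
   start precipitation_days   105    119  0.53677     True
     end   mean_temperature   159    181 -0.43032     True
```

The scan identified days 129–155 as the critical temperature window for
breeding start (r = −0.59: warm springs → earlier breeding), overlapping
the generator's planted causal window (days 125–161). The start model's
unstandardized temperature coefficient was −2.34 days/°C
(95 % CI −3.27 to −1.40): each 1 °C of extra window warmth advances the
estimated start by ~2.3 days. This is deliberately smaller in magnitude
than the planted −6 days/°C — the hierarchical phenology stage shrinks
region contrasts, attenuating downstream slopes by roughly half; see
`docs/methods.md` for why, and the equivalent CLI:

```bash
snowphen run-all --seed 1 --out demo_run
```

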