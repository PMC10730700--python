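# Methods

This note records the modelling assumptions, parameter defaults, numerical
choices and known limitations of `darkbirds`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The estimation problem

Island bird extinctions cluster in the centuries after first human arrival,
mostly before 1500 CE, so the observed record misses them and the fossil
record captures them only where preservation and research effort allow. The
package treats the per-archipelago count of *fossil* extinct species as a
noisy, effort-limited measurement of the true extinction toll, and asks the
counterfactual: how many extinct species would each archipelago's record show
under the research effort that produced a complete inventory for the
reference archipelago? The gap between that counterfactual and the observed
fossil count is the estimate of undiscovered extinctions.

## Fossil-count model

`log(F + 1)` is regressed by OLS on twelve standardized predictors plus an
area-by-effort interaction. Choices:

- **Transforms** (configurable per column): log for areas, isolation,
  elevation, precipitation and plant richness; log1p for counts that can be
  zero (research effort, endemics); identity otherwise. Transforms are
  applied before centring and scaling.
- **Standardization** uses the sample (n−1) standard deviation; the
  convention is recorded in the design's `transform_spec` so raw values can
  be projected into model space exactly as at fit time.
- **Interaction**: product of the two scaled main-effect columns, left
  unscaled, so its coefficient reads as effect modification per SD.
- **Collinearity screen**: for each predictor pair with |Pearson r| ≥ 0.8
  the lower-priority member is dropped (total area outranks SD of area,
  isolation distance outranks surrounding landmass); constant columns are a
  validation error.
- **Posterior simulation** follows the standard noninformative-posterior
  recipe for the Gaussian linear model: σ² ~ SSE/χ²(df), then
  β | σ ~ N(β̂, σ²(X′X)⁻¹). This makes the 95% posterior intervals exactly
  calibrated when the generating process is the model itself, which the
  acceptance suite verifies over 200 replicates.
- **Quasipoisson alternative**: Poisson GLM point estimates with covariance
  inflated by the Pearson-χ²/df dispersion. Its posterior draws (used only
  in comparison runs) are multivariate normal with the dispersion-scaled
  covariance; no scale draws, since quasilikelihood defines none.
- **LOOCV goodness of fit** is computed on the count scale
  (back-transform exp(ŷ)−1, floored at 0). `r2_cv` is the squared Pearson
  correlation between observed and predicted; the Nash–Sutcliffe model
  efficiency is exposed alongside (`r2_nse`) because "variance explained by
  predictions" admits both readings. Percent bias follows the hydrological
  convention 100·Σ(pred−obs)/Σ(obs).
- **Moran's tests** of residual spatial autocorrelation use row-standardized
  k-nearest-neighbour weights for k = 1..20 and the two-sided
  normality-approximation p-value.

## Extrapolation

Per posterior draw, the link-scale increment
`(β_effort + β_int·z_area)·(z_effort^ref − z_effort)` is added to the
*observed* `log(F+1)` rather than predicting from the model surface. This
choice makes two properties hold exactly — the reference archipelago's
estimate equals its observed count, and no estimated total falls below the
observed count — which prediction-based extrapolation cannot guarantee. The
surface-prediction variant remains available (`clamp_negative` and the
posterior machinery are shared). Negative increments, possible under adverse
coefficient draws, are clamped to zero and counted. Probability rounding
(floor plus Bernoulli on the fractional part) converts fractional species to
integers without bias; rounding happens after subtracting known fossils.

## Upper bounds

Continental grid richness is modelled by a quasipoisson GLM on five
environmental predictors plus a residuals autocovariate: each cell's
covariate is the row-standardized first-order (queen) neighbourhood mean of
the non-spatial fit's response residuals (deviance residuals by flag; rook
adjacency by flag). Archipelago ceilings are draw-wise medians of predicted
richness over mapped cells, scaled by the species–area relationship with
z = 0.25 from a cell area of 12,300 km² (an equal-area 1° emulation), minus
recorded species, floored at zero. The reference archipelago needs no bound
because its estimate is pinned to its observed count.

A caution the test suite encodes: the autocovariate is a *generated
regressor* (built from residuals of a fit to the same response), so its
naive standard error understates sampling variability and its z-scores are
mildly negatively biased under the null of no spatial dependence. The
meaningful null property — and the one tested — is specificity: positive
spatial dependence is detected in ≤10% of null replicates, while genuinely
autocorrelated fields are detected essentially always, and the refit shrinks
residual Moran's I in the majority of replicates.

## Rejection sampling and totals

Undiscovered draws above their archipelago's bound draw are rejected and
both members redrawn from their ensembles, up to 100 retries, after which
the estimate is truncated to the bound (truncations are counted and
reported). This keeps the accepted ensemble at exactly n_draws. The
per-archipelago rejection rate is rejected proposals over all proposals.
Observed extinctions are resampled per draw: confirmed species count once,
possibly-extinct species enter by Bernoulli(p_extinct) with one shared
realization per draw, so Pacific and non-Pacific strata sum exactly to the
global total. Intervals are equal-tailed sample quantiles by default; a
highest-density variant sits behind a flag (HDIs are shorter on skewed
ensembles, so headline intervals can differ slightly between conventions).
Continental fossil species are fixed data assigned to the non-Pacific
stratum.

## Bayesian models

A single component-wise Gaussian random-walk Metropolis engine drives both
models; chains record thinned post-burn-in samples
(`floor(iterations·(1−burn_in)/thinning)` of them), per-component acceptance
rates, and a split-half (Geweke-style) convergence diagnostic.

- **White-noise linear model**: counts are N(μ₀ + Σeᵢzᵢ + e_int·z_area·z_eff, σ)
  on the natural count scale. Priors: μ₀ ~ U(0, 200); σ ~ Gamma(1, 0.01);
  effects hierarchically N(0, τ) with τ ~ Exponential(1), τ sampled jointly
  by MH (no Gibbs step, keeping the engine generic). Chains start at the
  least-squares solution with SE-scaled proposals so desk-scale runs
  (default 200,000 iterations, thin 100, 10% burn-in, a few tens of seconds)
  converge; archival-scale settings remain available via `McmcConfig`. Its
  extrapolation is additive on the count scale: undiscovered =
  max(increment, 0), probability rounded, with the same rejection step.
  The exponential variant of this model is deliberately not implemented as a
  forward path; the linear variant is the supported alternative.
- **Logistic description curve**: cumulative described-species counts are
  N(M/(1+exp(−r(t−m))), σ) with flat priors except positivity of M, r, σ and
  a hard window on the midpoint m (the observed year range, 1843–2017 for
  the default series) — a negative asymptote or growth rate is meaningless,
  so "flat unbounded" is interpreted as flat on the admissible half-line.
  The asymptote draws are the describable total; subtracting the described
  count gives the undescribed lower bound.

## Chronologies and rates

Extinction years are continuous (astronomical year numbering; year 0 exists)
within a draw and are floored to integer years only when binned into rate
series.

Dating rules: archipelago fossils and undiscovered pseudo-species decay from
the realized arrival year with half-life 100 y truncated at the 90th
quantile (support bound −ln(0.1)/λ ≈ 332.19 y); Madagascar uses half-life
1000 y truncated at the 75th quantile (bound exactly 2000 y — no extra
post-1950 cap is imposed, the truncation provides it given arrival inputs);
Australasian/Nearctic/Neotropic continental fossils use half-life 1000 y at
the 90th quantile after realm arrival (Clovis-bracket bounds for the
Nearctic; arrival bounds are data, not code); Indo-Malayan and Palearctic
fossils are uniform between the fossil's minimum age and 1500 CE; observed
species use their last record year, or the island decay rule when no record
exists (the truncation quantile for that case, unstated in the rule's
source, is taken as 0.9 for consistency); possibly-extinct species enter by
Bernoulli inclusion at their last record year. Undiscovered pseudo-species
share the archipelago fossil rule — they are, by construction,
fossil-process species that were never found.

Rates: N(t) counts species not yet extinct at the start of year t (an event
in year t is alive at the year's start), so rate(t) = d(t)/N(t) ≤ 1 and N is
non-increasing; the present-day extant pool defaults to 10,865. Rolling
means are centred, complete-window only (the year axis shrinks by
window−1), computed per draw *before* cross-draw summarizing, matching the
order rolling-then-median implies for envelope interpretation. The central
curve is the per-year median by default with the mean behind a flag (the
two conventions differ and both are legitimate summaries; the median is
robust to the occasional extreme chronology). Peak detection
(local maxima above a prominence threshold, default 10% of the central
maximum) is a reporting aid for locating extinction waves, not part of the
estimator. Rates are compared to a background of 2 E/MSY after multiplying
by 10⁶.

## Synthetic data

The generators produce the statistical structure the analysis assumes, not
real geography:

- **Archipelago table** (default n = 69): right-skewed predictor
  distributions spanning realistic island ranges (areas and isolation over
  orders of magnitude, tropical temperature regime); `sd_area` and
  `surrounding_landmass` are constructed collinear with `total_area` and
  `isolation_distance` so the screen has real work; research effort is
  capped below the reference value 343, held by exactly one archipelago
  flagged as reference with late (1230–1280) arrival bounds. Fossil counts
  are `max(round(exp(Xβ+ε)−1), 0)` with σ = 0.75 — chosen so the fitted
  model's explanatory power (R² ≈ 0.7) and effort dominance (partial R²
  0.3–0.5) sit in the regime typical of fossil-record completeness data. A
  Poisson mode exists to probe misspecification. The integer rounding and
  zero floor mildly censor the smallest counts; calibration studies
  therefore use `integer_counts=False`, under which the linear model is
  exactly specified and coverage is interpretable.
- **Grid** (default 30×30 = 900 cells, full 10,600 by config): richness is
  Poisson with a log-link on five predictors plus an optional log-normal
  overdispersion term and a latent field made by mixing white noise with its
  queen-neighbourhood mean (`autocorr` weight, two passes) — simple, and
  sufficient to exercise the autocovariate machinery. Each archipelago maps
  to 1–5 random cells.
- **Species register**: one record per fossil/observed species reconciling
  exactly with the table counts; 46 possibly-extinct species with
  Beta(4, 1) extinction probabilities (mean 0.8, reflecting that
  possibly-extinct listings are usually well-founded) and recent last
  records; 17 observed species without last records; 98 continental fossils
  across five realms, the Indo-Malayan/Palearctic ones carrying pre-1500
  minimum fossil ages.
- **Description series**: logistic mean plus Gaussian noise, rounded and
  made non-decreasing; default truth (522, 1950, 0.05 yr⁻¹, sd 5).

What passing tests on these data do **not** show: robustness to real-world
predictor covariance structures, to preservation biases that correlate with
the predictors themselves (e.g. soil chemistry), to non-uniform arrival-date
errors, or to archipelago classification choices. The generators are
correctly-specified worlds; the tests certify the machinery, not the
ecology.

## Problem sizes and defaults

Desk-scale defaults keep every stage in minutes on one CPU: 1000 posterior
draws (pipeline), 500 in the acceptance script, 200-replicate LM and
50-replicate white-noise recovery studies, 25,000-iteration white-noise and
60,000-iteration logistic chains in tests, 900-cell grids. All are
configuration, not constants; the heavy settings (10,600 cells, hundreds of
millions of MCMC iterations) are reachable through the same interfaces.

## Known limitations

- The white-noise model's component-wise MH is a pure-Python loop; at
  archival iteration counts it is slow. The engine favours transparency
  over speed.
- Rejection replacements are resampled from the existing draw ensembles
  rather than fresh model simulations; with 1000-draw ensembles the
  distinction is negligible except under pathologically tight bounds, where
  the truncation fallback (counted and reported) takes over.
- The full-data mode (`mode: tables`) reproduces the pipeline on deposited
  tables but the repository ships no real data; all shipped numbers are
  synthetic-world results.
- Chronology generation iterates the register row-wise per draw; at 10⁴+
  species it would want vectorizing.
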