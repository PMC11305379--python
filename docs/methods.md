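# Methods

`dietstrata` implements the estimation machinery used in global dietary
surveillance to turn a sparse, heterogeneous corpus of survey means into
stratum-level national intake estimates with propagated uncertainty. This
note documents the models, their assumptions, the synthetic worlds the
package is exercised on, and the numerical choices that a maintainer would
otherwise have to reverse-engineer.

## The estimation problem

Dietary surveys report mean beverage intake for demographic cells of a
country in some year, with a sampling standard error, an assessment method
(24-hour recall, food-frequency questionnaire, short questionnaire, or
household budget survey), and a representativeness flag. Coverage is
sparse: most country-years have no survey, some surveys collapse cells
(e.g., both sexes combined), methods carry systematic bias, and
non-representative surveys carry extra non-sampling error. The target of
inference is the mean intake, in standardized 248 g (8 oz) servings per
week, for each of 264 demographic strata per country-year — the joint cells
of 22 age bins (&lt;1 through ≥95 years), sex, three education levels
(≤6, &gt;6–12, &gt;12 years; parental education for children), and
urban/rural residence — for the years 1990, 1995, 2000, 2005, 2010, 2015,
2018.

## Harmonization

Raw records are standardized before modeling:

* **Beverage classification.** A beverage counts as a sugar-sweetened
  beverage (SSB) if it has added sugars and provides ≥50 kcal per 237 g
  serving; 100% juices, non-caloric artificially sweetened drinks,
  sweetened milk, tea and coffee are excluded regardless of sugar content.
  A record with an unknown added-sugar flag raises an error rather than
  silently classifying as non-SSB.
* **Energy adjustment.** Intakes are ratio-scaled to age-specific daily
  energy targets: 1300 kcal/day for the youngest bins (through ages 3–4),
  1700 kcal/day for the 5–9 bin, 2000 kcal/day from age 10 up. The
  published targets are banded as 3–5 / 6–10 / 11–19 years; our model bins
  do not align exactly, so each bin is assigned the band covering the
  majority of its span, and adults use 2000 kcal/day. Density (ratio)
  scaling is used because it is monotone, unit-consistent and requires no
  within-survey regression; the residual method would need individual-level
  data the pipeline does not receive.
* **Units.** grams/day × 7 / 248 = servings/week; the sampling SE of a cell
  mean is SD/√n in the same units.

## The intake model

Let `y_i` be observation *i*'s harmonized mean (servings/week) with
sampling SE `se_i`. On the log scale with offset ε = 0.01 servings/week:

    log(y_i + ε) ~ Normal(η_i,  s_i² + σ² + τ²·od_i),     s_i = se_i/(y_i + ε)

    η_i = x_i'β + b_i'γ + v_{r(i)} + u_{c(i)} + w_{cy(i)}

* `x_i`: prediction covariates — intercept, 21 age contrasts, sex,
  2 education contrasts, urban residence, and the standardized country-year
  food-availability covariate. For a coarse observation covering several
  elementary cells, `x_i` is the population-weighted average of the
  elementary design rows.
* `b_i`: survey-bias covariates — assessment-method contrasts (24-hour
  recall is the reference), dietary-metric contrasts, and a
  non-representative indicator. These columns are zeroed at prediction
  time, so estimates refer to a representative 24-hour-recall-equivalent
  survey.
* `v_r ~ N(0, σ_r²)`, `u_c ~ N(0, σ_c²)`: region and nested country random
  intercepts.
* `w_cy ~ N(0, σ_w²)`: a country-year random effect (config-selectable,
  default on). This level lets predictions track the surveys of a specific
  country-year; without it a country's predicted trajectory could move over
  time only through the global availability coefficient, and the downstream
  trend model would have no country-specific time variation to work with.
* `od_i` flags surveys that are non-representative **or** coarsely
  stratified; τ is the extra non-sampling SD for those rows. A per-flag
  variant (separate τ for the two conditions) is config-selectable. When no
  row is flagged, τ is unidentified and fixed at 0.
* `s_i` is the delta-method transfer of the sampling SE to the log scale.

Priors are weakly informative: N(0, 2²) on fixed effects, half-N(1) on all
SD parameters, and a first-difference random-walk prior (SD 0.3 between
adjacent bins) smoothing the age coefficients, which captures age patterns
without assuming a functional form. Bias coefficients get N(0, 0.3²):
survey-instrument biases are modest multiplicative effects (±35% on the
natural scale at one prior SD), and because the level-versus-bias
decomposition is only anchored by the reference-method surveys — of which
a sparse corpus may contain very few — an unbounded bias prior would let
realized anchor-country effects masquerade as instrument bias.

**Sampling.** The model is linear-Gaussian given its variance parameters,
so inference uses a collapsed sampler written for this package: the five
variance parameters (σ, τ, σ_r, σ_c, σ_w) are updated by per-coordinate
adaptive random-walk Metropolis on the log scale under the *marginal*
likelihood with all linear coefficients integrated out analytically (the
marginal density falls out of the same sparse normal-equations
factorization used for the coefficient draw, via the matrix determinant
lemma), and the coefficients are then drawn exactly from their joint
multivariate-normal conditional. Marginalizing the coefficients is what
removes the funnel pathology that traps centered Gibbs updates of
hierarchical SDs near zero. Defaults: 4 chains × (500 warmup + 1000 kept);
step sizes adapt only during warmup, so the kept draws form a valid Markov
chain. Convergence is summarized by split-R̂ (threshold 1.05) on the
variance parameters and key fixed effects; non-convergence warns and is
recorded in the diagnostics report, never silent.

**Prediction.** For a country-year, the 264-cell design is evaluated at
reference bias levels per posterior draw and back-transformed as
`max(exp(η) − ε, 0)`. For a country with no surveys, the country effect is
drawn from `N(0, σ_c²)` per posterior draw (deterministically seeded per
country, shared across years so its trajectory is coherent), and the
result is flagged `no-country-data`; unsurveyed years of a surveyed country
get fresh `N(0, σ_w²)` country-year draws and the flag
`no-survey-this-year`. This is what makes interval widths honestly wider
where data are absent. Uncertainty is carried everywhere as the strata ×
draws matrix (default 4000 draws); summaries are medians with 2.5th/97.5th
percentile uncertainty intervals.

## The trend model and combination

Time is never modeled directly. The trend model regresses the log
population-weighted country mean `z_ct` (mean over the intake model's
draws, with the across-draw SD as its SE) on the country-centered
food-availability covariate:

    z_ct ~ Normal(α_c + β_c·(a_ct − ā_c),  se_ct² + σ_t²)
    (α_c, β_c) ~ MVN(μ, Σ)

with two-dimensional partial pooling: the 2×2 covariance Σ (and hence the
intercept–slope correlation) is estimated across countries, shrinking
extreme country slopes toward the population slope. The Gibbs sampler here
is fully conjugate — per-country bivariate normal draws, a normal draw for
μ, an inverse-Wishart draw for Σ (prior: df 3, scale 0.05·I) — plus an
adaptive Metropolis step for σ_t. A country observed in a single year
centers its availability to zero and therefore informs only its intercept.

**Combination rule.** The published pipeline combines its two models in a
supplementary procedure whose details are not in the main text; this
package adopts a multiplicative anchor-ratio rule as its own convention:
for country *c* and target year *y*, every one of the 264 stratum draws is
multiplied by

    exp( β_{c,d} · (a_{c,y} − a_{c, anchor(c,y)}) )

where `anchor(c,y)` is the country's nearest survey-informed year (ties to
the later year) and *d* indexes draws. The rule (i) leaves survey-informed
years exactly unchanged, (ii) preserves all within-country demographic
contrasts draw by draw, and (iii) propagates trend-slope uncertainty into
out-of-anchor years. An inverse-variance log-scale blend of the two
models' country levels is available behind `TrendSpec.combination_rule =
"log_blend"`. Whether the original combination operates at stratum or
country level, and on which scale, is unknown; this is a documented
convention, not a claim about the original. Countries with no trend fit or
no survey-informed year pass through with an `uncombined` flag.

## Aggregation, changes, and headline statistics

All aggregates are computed per draw as population-weighted means of
member strata, then summarized by percentiles (numpy's linear-interpolation
rule, fixed and bit-stable). Because per-draw aggregation is linear,
region-then-global equals direct global aggregation exactly, and
zero-weight strata never influence any aggregate. Child/adolescent
estimates restrict to the 3–4, 5–9, 10–14 and 15–19 age bins.

Changes between years are computed at the draw level with **both** years
weighted by the standardization-year (2018) stratum proportions, so that
changes reflect intake, not demographic drift: per draw,
`A_d = m_w(y₂,d) − m_w(y₁,d)` and `P_d = 100·A_d / m_w(y₁,d)`; draws with a
zero baseline are excluded from the percent summary and counted. When the
two years' population proportions are identical, standardized and naive
changes coincide exactly.

National headline statistics: the count/percent of countries whose
national median intake is at or above 7 servings/week (with the covered
population), and Pearson correlations of national medians with the
sociodemographic index and obesity prevalence. The published "mean"
intakes are treated as posterior medians, consistent with the percentile
definition of the uncertainty intervals; the mean of draws is emitted
alongside in every summary table.

## Validation

Five-fold cross-validation omits 20% of survey *rows* (stratum-level
holdout), refits, and predicts the held-out rows **including** their
survey-bias covariates — the biased observation is the only observable
target. Reported metrics per fold and pooled, repeated five times with
fresh seeded partitions: log-scale R², mean bias, RMSE, and empirical
coverage of the 95% predictive interval (which adds the sampling, residual
and overdispersion variance to the linear-predictor draws). Implausibility
screening flags summaries whose median falls outside configurable bounds
(default 0–35 servings/week, i.e. five servings/day) or whose interval
ratio exceeds a configurable factor; the original screening bounds are not
public, so these defaults are package conventions.

## The synthetic world

Real survey corpora for this problem are not publicly redistributable, so
the package generates fully specified synthetic worlds with known ground
truth. The generator mirrors the model's structure — which is exactly what
makes parameter recovery and calibration checks well-posed:

* True stratum means are `exp` of a log-linear predictor: intercept
  (default log 2.0 servings/week), a smooth age curve rising to a plateau
  in adulthood (amplitude 0.8), male +0.05, education +0.15/+0.30,
  urban +0.50 — magnitudes chosen to put child-age strata in the
  few-servings/week range with urban/education gradients like those in
  published tables; region effects N(0, 0.3²); country effects N(0, 0.4²)
  correlated (ρ = 0.6) with country availability slopes N(0.3, 0.15²).
* The availability covariate is a per-country level plus linear drift with
  innovation noise, standardized; SDI ∈ [0,1] and obesity prevalence are
  generated with configurable correlations (defaults 0.2, 0.3) to log
  intake.
* Surveys hit a country-year with probability 0.7; methods are drawn with
  probabilities (0.24, 0.61, 0.10, 0.05) matching the published corpus
  composition, 94% representative; 30% of surveys are coarse, collapsing
  sex and/or education into population-weighted averages. Observed cell
  means are true means × `exp(method bias + noise)` plus sampling error
  SD/√n with per-cell n log-uniform in [30, 3000] and within-cell SD equal
  to the cell mean (CV = 1). The noise SD is `sqrt(0.10² + 0.15²)` for
  overdispersion-flagged surveys (non-representative or coarse — the same
  flag the likelihood uses) and 0.10 otherwise.
* Populations combine independent marginal shares (exponential age
  pyramid, even sex split, education and urbanization drifting over
  1990–2018) times a nationally declared exponentially growing total, so
  stratum proportions genuinely differ between 1990 and 2018 and change
  standardization is non-trivial.
* Synthetic surveys report energy intake exactly at the age-specific
  target, i.e. the corpus arrives pre-standardized; harmonization is then a
  pure unit conversion. This keeps the generator's ground truth valid
  through the harmonization stage while still exercising the code path.

What the generator does **not** emulate: item-level beverage composition,
household-to-individual disaggregation, non-random survey placement
(richer countries being surveyed more often), age-range-restricted
surveys, and reporting error correlated with intake. Passing tests
therefore demonstrate internal correctness and calibration under the
model's own assumptions, not robustness to the full messiness of real
corpora.

## Numerical choices and experiment sizes

* log(x + ε) transformation with ε = 0.01 servings/week guarantees
  positivity; back-transformation clips at zero.
* Percentile convention: linear interpolation between closest ranks
  everywhere (the numpy default), documented and bit-stable.
* Anchor ties resolve to the later year. Draw indices are selected
  deterministically (evenly spaced) when thinning a posterior to a
  requested draw count, so "draw d" refers to the same parameter state in
  every prediction and all draw-level arithmetic aligns.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawn keys; identical configuration gives
  bit-identical CSV outputs.
* Test and acceptance experiments run scaled-down worlds chosen as the
  smallest sizes at which the checked property is identifiable: 2 regions ×
  4 countries × 4 years with 2 × (200+200) MCMC for calibration (two dozen
  replicates), 4 regions × 5 countries with 4 × (250+250) for
  demographic-effect recovery, and 40 countries for intercept–slope
  correlation recovery. The calibration experiment draws each replicate
  world's method biases from the model's own prior (simulation-based
  calibration): posterior intervals promise coverage averaged over the
  prior, and that is the average the experiment takes. Eight countries per
  world keeps enough reference-method surveys in each corpus to anchor the
  level-versus-bias decomposition, whose whole-world misses otherwise
  dominate the variance of the coverage estimate. The default pipeline configuration (200 draws,
  desk-scale world) is likewise sized for interactive use; production-style
  runs raise `n_draws` to 4000 and the sampler to 4 × 1000.

## Known limitations

* The correlation recovered by the trend model is the correlation among
  the country (intercept, slope) pairs *as the model parameterizes them*
  (intercept at the country's own mean availability). This differs from
  the generator's nominal ρ by finite-sample realization noise and by the
  slope × mean-availability contribution to intercepts; recovery against
  the realized estimand is tight (±0.1 at 40 countries), against the
  nominal ρ it is looser.
* With a single survey per method in a country-year, method bias and the
  country-year effect are confounded; the prior resolves the split. This
  is inherent to bias adjustment from observational survey metadata.
* MCMC at the scaled-down test settings occasionally leaves variance
  components with split-R̂ slightly above 1.05; the package warns and
  reports. Production settings (4 × 1000) converge cleanly in our runs.
* The Gibbs sampler's per-iteration cost is dominated by the sparse
  normal-equations assembly; worlds much larger than ~200 countries ×
  7 years would want a sparse Cholesky of the blocked precision instead of
  the dense solve.
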