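# Methods

`elkrsf` implements a complete workflow for studying how a large
herbivore balances forage quality against predation risk from two
predators with different hunting styles, and whether individual
risk-avoidance carries a physiological cost (a nonconsumptive effect).
This note records the models, the estimation machinery, the synthetic
data that stands in for field data, and the design decisions that were
genuinely open.

## The resource selection model

Selection is analysed at two of Johnson's orders: placement of a summer
home range within the population range (second order) and placement of
foraging locations within the home range (third order).  Both use a
used–available design.  The relative probability that individual *i*
uses location *j* is modelled in exponential form,

    w(x_ij) = exp( g0_i + gDE_i DE_j + gML_i ML_j + gWF_i WF_j
                   + gDExML_i DE_j ML_j + gDExWF_i DE_j WF_j )

with DE the digestible-energy raster (kcal/g) and ML, WF the natural
logs of mountain-lion and wolf relative-use surfaces (floored at each
raster's smallest positive value before the log).  The forage-by-risk
interactions are the trade-off terms: a negative gDExML means selection
for good forage weakens where lion risk is high.

Because the exponential form makes the point-process likelihood
proportional to a logistic regression, the model is estimated as a
weighted Bernoulli-logit: used points carry weight 1, available points
weight 1000, the per-row log-likelihood multiplied by the weight (the
infinitely-weighted-logistic construction).  Covariates are centred and
scaled by one sample standard deviation (n−1), computed over the pooled
used+available rows of each order's table separately, and the constants
are stored beside every table.

Individual heterogeneity enters through hierarchical centering:
g0_i ~ Normal(b0, 100) with the scale *fixed* (so intercepts absorb
unbalanced exposure without shrinking), and each slope/interaction
gcov_i ~ Normal(bcov, sigma_cov) with sigma_cov ~ Uniform(0, 2).
Population coefficients get Normal(0, 2) priors.  All prior scale
parameters are standard deviations.

## Estimation

No probabilistic-programming backend is used; the posterior machinery is
implemented directly:

* **Inner step.**  Given candidate population parameters, each
  individual's coefficient vector has a strictly concave penalized
  logistic posterior; its mode and curvature are found by a damped
  Newton solve, batched across individuals (rows are padded to a common
  length with weight-0 rows so the whole solve is three matrix products
  per iteration).
* **Marginal likelihood.**  The individual coefficients are integrated
  out by the Laplace approximation at that mode — the same construction
  mixed-model tools use for generalized linear mixed models.  The
  normalisation constants of the Gaussian prior and the Laplace integral
  cancel exactly, leaving joint-at-mode − Σ log d − ½ log det H per
  individual.
* **Outer step.**  The 11-dimensional marginal posterior (6 fixed
  effects + 5 SDs, the SDs mapped to an unconstrained scale by a scaled
  logit with its Jacobian) is maximised with L-BFGS-B.
* **Draws.**  By default (`method="laplace"`) population-level draws
  come from a Gaussian approximation at the marginal mode (numeric
  Hessian, eigenvalue-floored); for each draw the per-individual
  conditional mode is re-solved and the individual coefficients drawn
  from their conditional Gaussian.  `method="mcmc"` replaces the
  population-level Gaussian with an affine-invariant ensemble sampler
  over the same marginal posterior — useful when the Gaussian shape is
  in doubt — and `method="map"` returns modes only (the fast
  cross-validation path).  Convergence is summarised by potential scale
  reduction and effective sample size on the stored draws; values above
  1.05 raise a warning.

Two properties pin the estimator to an external reference: with weights
1, flat priors and no random effects the MAP equals the logistic MLE to
1e-3 (checked against an independent IRLS implementation), and the
weighted likelihood is exactly linear in the weights (duplicating
available rows at half weight leaves the fit unchanged).

Posterior summaries are reported as the mean with an equal-tailed 90%
credible interval.

## Home ranges and design tables

Home ranges are 99% fixed-kernel isopleths from one location per animal
per day (the earliest fix of each day, a deterministic tie rule).  The
UD uses a Gaussian product kernel evaluated exactly on the grid with the
per-axis reference bandwidth h = sigma · n^(−1/6); the kernel and
bandwidth rule are configurable because no single convention is
canonical.  Isopleths are extracted by thresholding the density at the
smallest cutoff whose superlevel set holds the target mass, contouring
with marching squares (zero-padded so margins close), and resolving
nested contours into shells and holes by containment parity.  Grid
resolution defaults to 250 m.

Second-order tables contrast 500 uniform points per individual range
with 1000 uniform points in the population range; these polygon samples
carry no timestamps, so the time filters do not apply to them.
Third-order tables contrast observed fixes — restricted to July 1–
August 31 and excluding the midday rest window (11:00 ≤ t < 18:00,
half-open so no fix is double-counted at either boundary) — with 10
uniform available points per used fix in the individual's range.
Isopleths that overhang the covariate rasters are clipped to the raster
extent before sampling, since covariates are undefined beyond it.

## Cross-validation

Model validation is fivefold by individual: animals are randomly
assigned to balanced folds; each fold's model is refit without it;
withheld rows are scored with the population coefficients; bin cutoffs
are the 20/40/60/80th percentiles of the withheld *available*
predictions; and the count of withheld *used* locations per bin is
tested against the ranks 1–5 with a Spearman correlation.  Raw counts
are the default statistic; an area-adjusted (classical Boyce ratio)
variant sits behind a flag.  The Spearman p value is the exact two-sided
permutation probability for n ≤ 8 ranks and the large-sample t
approximation otherwise; ties get midranks.  Cross-validation refits
default to the MAP mode for tractability.

## Trade-off metric and nonconsumptive-effect models

For each individual, the trade-off for a predator is the difference in
relative use of high-quality forage between high and low risk:

    delta_i = w_i(DE = q95, risk = q95) − w_i(DE = q95, risk = q05)

with quantiles taken across the pooled third-order table on the
standardized scale, the other predator held at its mean (its terms then
cancel exactly), and the intercept excluded by default — it multiplies
both terms of a quantity that is only defined up to relative scale
(an `include_intercept` flag restores it).  Negative values are
risk-averse trade-offs.  The computation uses per-individual
posterior-mean coefficients and matches a brute-force evaluation of the
exponential predictor exactly.

Body fat (% ingesta-free) is regressed on the trade-off, lactation
status and their interaction with a Gaussian likelihood, Normal(0, 100)
priors and a flat prior on log residual SD; draws use the exact
normal/inverse-chi-square factorisation.  Pregnancy uses a
Bernoulli-logit with Normal(0, 100) on the intercept and Normal(0, 2)
on slopes, a Laplace posterior at the penalized mode, and an explicit
complete-separation diagnostic.  Age is deliberately not a covariate.

## The synthetic study

The generator produces every input the pipeline reads, with the
statistical structure the analysis assumes:

* **Landscapes.**  Gaussian-smoothed white-noise fields (smoothness 8
  cells, 250 m cells, 256² grid).  DE is rescaled to 0.5–3.0 kcal/g.
  Each predator surface mixes the standardized DE field with an
  independent field and exponentiates; the independent component is
  residualized against the DE field in sample, so the realized squared
  correlation equals the mixing weight squared *exactly* — 0.35 for
  lions (mix ≈ 0.59) and 0.15 for wolves (mix ≈ 0.39) — rather than
  wandering with the few effective degrees of freedom a smooth field
  has.
* **Individuals.**  Population coefficients default to bDE = 0.2,
  bML = −0.1, bWF = 0.3, bDExML = −0.1, bDExWF = 0, with all
  random-slope SDs 0.15 — moderate selection with real heterogeneity.
  Per-individual coefficients are exact Normal(b, sigma) draws at the
  stored seed.
* **Telemetry.**  Each individual occupies a disc home range (radius
  3 km, centres uniform with a margin inside the map).  Fixes are
  rejection-sampled with acceptance proportional to exp(g·z) using an
  exact envelope (the max linear predictor over raster cells in the
  disc's bounding box), with covariates standardized by constants from a
  uniform availability sample over all ranges.  Timestamps sit on a
  regular 2-h (or 30-min) schedule spanning June 15–September 15, so the
  season and rest-window filters have work to do.  Defaults are 40
  individuals × 640 fixes, chosen so that roughly 300 fixes per animal
  survive the filters — a deliberately scaled-down version of a
  multi-year field dataset that keeps a full fit in tens of seconds.
* **Demography.**  Body fat follows the linear NCE model plus Gaussian
  noise (SD 2.5), truncated to 0–30%; the intercept 8.9 offsets the
  lactation penalty (−2.89 at 48% lactating) so median body fat sits
  near 7.5%.  Pregnancy is logistic with intercept logit(0.76).
* **Model-level tables.**  `simulate_used_available` skips the spatial
  layer entirely: availability is standard normal on the standardized
  scale and used rows are importance-resampled with weight exp(g·x).
  This is the clean recovery oracle for the estimator, with truth
  exactly on the fitted table's scale.

## What passing tests do and do not show

Parameter recovery is sharp at the model level: over replicated
model-level tables at the defaults, posterior means track the truth and
90% intervals cover it at near-nominal rates.  Through the *full*
telemetry pipeline the picture is deliberately different: a 99% kernel
isopleth estimated from ~90 daily fixes strictly contains a hard-edged
generative range (the dilation is about two bandwidths, roughly half
the range's radius), so a substantial share of the available sample
falls where generative use is zero.  Each individual's fit absorbs that
availability mismatch as apparent selection, inflating the random-slope
SDs (to ~1 where the generative value is 0.15) and widening — honestly —
the population intervals; individual-level trade-off estimates are
correspondingly noisy.  This is not an estimator defect (with
availability drawn from the true disc, per-individual recovery is
clean); it is the familiar sensitivity of RSF coefficients to the
availability definition, reproduced in miniature.  Real telemetry has
no hard range edge, but the lesson transfers: conclusions at the
individual level lean on the availability polygon much harder than
population-level ones.  The test suite therefore checks sharp recovery
where the model's assumptions hold and bounded, heterogeneity-detecting
behaviour through the full spatial pipeline.

Features of real data the generator does not emulate: autocorrelated
movement (fixes are conditionally independent), collar dropout and
irregular schedules, predator–prey dynamic feedback (risk surfaces are
static), multi-year variation, and measurement error in body condition.

## Numerical choices

* Inner Newton: backtracking line search only when a step exceeds 0.5
  in any coordinate (the penalized objective is strictly concave);
  convergence at max-gradient 1e-8.
* Isopleth mass tolerance is grid-limited; on a 512² grid the 99%
  contour holds 0.990 ± 0.005 and the unit-kernel radius matches the
  bivariate-normal value 3.035 to 2%.
* Points exactly on a raster cell edge resolve to the lower-index cell;
  nearest-cell lookup is the default, bilinear optional.
* Uniform-in-polygon sampling is batched rejection from the bounding
  box; with a fixed generator it is bitwise reproducible.
* Sigma draws are parameterized on a scaled-logit scale; the Laplace
  covariance floors eigenvalues at 1e-8 to guard against numerically
  indefinite curvature.
* Degenerate inputs fail loudly: < 5 fixes for a UD, constant covariate
  columns, zero-variance ranks, polygons with zero area, missing
  pregnancy outcomes.

## Known limitations

* The Laplace population posterior is Gaussian by construction; strongly
  skewed marginal posteriors (tiny data, boundary-adjacent SDs) are
  better served by `method="mcmc"`.
* The ensemble MCMC mode samples the 11-dimensional marginal posterior,
  not the full joint; per-individual draws remain conditional Gaussians.
* Uniform(0, 2) caps the random-slope SDs; data generated with more
  heterogeneity than that will pile posterior mass at the bound (the
  full-pipeline fits above illustrate this).
* No geographic CRS handling: all inputs must share one planar,
  metre-based system.
* Second-order "selection" in the synthetic study is emergent (range
  placement is uniform, but estimated ranges bulge toward preferred
  habitat), so it has no closed-form truth to test against.
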