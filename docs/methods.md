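# Methods

`heatmort` implements a two-stage time-series design for quantifying
heat-related mortality from weekly regional data, together with the
climatological context analyses that place an extreme summer within the
long-term warming record, and a synthetic-data generator that makes every
stage testable by parameter recovery.

## First stage: region-level quasi-Poisson distributed-lag model

For each region (and, where available, each sex/age stratum) weekly
all-cause death counts `mort_t` are modeled as

    log E[mort_t] = intercept + ns(t; 8 df/year) + crossbasis(temp; lags 0-3)

* `ns(t; 8 df/year)` is a natural cubic spline of the week index with a
  total of `round(8 * n_weeks / 52.18)` equally spaced degrees of freedom;
  it absorbs seasonality and long-term trends.
* The cross-basis couples a natural cubic spline of temperature (three
  internal knots at the 10th/50th/90th centiles of the region's weekly
  temperatures, boundary knots at the observed min/max) with an
  unconstrained lag structure over 0-3 weeks: one spline block per integer
  lag. Columns are ordered basis-major (all lags of basis function 1,
  then basis function 2, ...), so the reduction matrix that sums
  coefficients over lags is `I_4 (kron) 1_4'`.
* Estimation is Poisson maximum likelihood (IRLS via statsmodels) with the
  covariance scaled by the Pearson dispersion `phi = X^2 / (n - p)`; this
  is what "quasi-Poisson" means operationally. No floor is applied at
  `phi = 1`. Counts are not offset by population: rates enter only at the
  attribution step, and a population rescaling provably shifts only the
  intercept.
* Weeks whose lagged exposures reach before the start of the series are
  dropped, not imputed; regions with too few usable weeks or events are
  excluded with a logged reason rather than silently.
* The natural-spline basis uses the truncated-power representation. It is
  not numerically identical to any particular package's parameterization;
  correctness is defined by the natural-spline constraints (C2 inside,
  linear beyond the boundary knots) and fit-space equivalence, which the
  test suite verifies against a generic equality-constrained
  piecewise-cubic least-squares oracle.
* Model comparison uses qAIC = -2 loglik + 2 phi p (the parameter penalty
  inflated by the dispersion).

The fit is then reduced to the *overall cumulative* exposure-response
association: the 4-vector `eta = M theta_cb` and covariance `M V M'`,
describing the summed effect of a week's temperature over lags 0-3.

## Second stage: multivariate multilevel meta-regression

The per-region `(eta_i, S_i)` pairs of one stratum are pooled in the
marginal model

    eta_i ~ N(X_i beta, S_i + Psi_region + Psi_country(c(i)))

with `Psi_country` inducing covariance between regions of the same
country. `X_i` holds an intercept and three region-level meta-predictors:
mean temperature, temperature interquartile range, and the share of the
population aged 80+. Predictors are z-scored internally for conditioning
and the fixed effects are reported on the original scale.

Variance components are estimated by REML. Because countries are
independent, the marginal covariance is block-diagonal by country and the
restricted likelihood is evaluated blockwise (batched Cholesky over
equal-sized country blocks). The unstructured 4x4 covariances use the
log-Cholesky parameterization, optimized by L-BFGS-B with central-difference
gradients; convergence requires a projected-gradient max-norm below 1e-5 or
a vanishing relative objective change, and bounded log-diagonals represent
the positive-semidefinite boundary (a variance component collapsing to
zero). The default random-effects structure is country-level only; a
nested region-level component is available by flag.

Per-region curves are shrunk by best linear unbiased prediction:
`coef_i = X_i beta + Cov(u, y_c) V_c^{-1} (y_c - X_c beta)` within the
country block, with covariance equal to the conditional variance of the
random effects plus the fixed-effect uncertainty. Wald chi-square tests on
rows of `beta` and a multivariate Cochran Q / I^2 (at the zero-heterogeneity
GLS fit) summarize whether the meta-predictors explain spatial
heterogeneity.

## Attribution

Each region's BLUP curve is re-referenced at its minimum mortality
temperature (MMT): the argmin of the cumulative curve on a 0.1 degC grid
over the region's observed weekly temperature range, ties broken toward
the colder temperature, with no percentile trimming of the search range.
For weeks with mean temperature above the MMT,

    AN_t = mort_t * (1 - exp(-f(x_t)))

with `f` the cumulative log relative risk at the week's temperature versus
the MMT (forward attribution; always < mort_t). A backward option spreads
each week's exposure contribution over the following lag window, dividing
the cumulative curve evenly across the four lags since the reduced
coefficients no longer identify lag-specific curves.

Uncertainty comes from Monte Carlo simulation: 1000 draws of the curve
coefficients from `N(coef, vcov)` per region, with the MMT held fixed at
its point estimate (re-estimating it per draw is available by flag).
Weekly attributable numbers are recomputed per draw, summed across weeks
and regions *within* each draw index, and 95% intervals are the empirical
2.5th/97.5th percentiles of the aggregated draws. Draws are deliberately
not truncated at zero — weakly identified burdens legitimately have
negative lower bounds. Each region uses a deterministic substream of the
run seed (derived from a CRC of the region id) so that draws are aligned
across regions and aggregation is coherent at every level. Rates divide
by population and are expressed per million; reported tables round deaths,
rates, and percentages to integers.

## Climate context

The climatological baseline is an OLS fit of weekly temperature on an
intercept plus a 6-df natural cubic spline of the day of the year over a
30-year reference period; anomalies are observed minus baseline. The day
of the year of an ISO week is its Thursday in the idealized calendar where
week 1 starts on 1 January (`doy = 7w - 3`), a deterministic mapping that
makes the baseline exactly periodic across years. Summer means average ISO
weeks 22-35; standardized anomalies divide by the reference-period
standard deviation of summer means, computed with denominator n
(population convention; n-1 by flag). Warming is summarized by OLS trends
over configurable periods with excluded years (e.g., a pre/post breakpoint
split), the mortality-temperature slope is the OLS slope of yearly summer
attributable deaths on summer mean temperature, and forward projection is
linear: anchor burden plus slope times the projected warming read off the
trend line.

European weekly series are population-weighted averages of the regional
series (an unweighted option is a one-line change in the caller); the
weighting convention is not derivable from first principles and
population-weighting matches the mortality-weighted nature of the burden.

## Synthetic data

The generator emulates the structure of the European weekly setting:

* regions nested in countries (defaults: 35 countries x 24 regions,
  2015-2022), each with a climatological mean drawn from 4-19 degC, an
  annual-cycle amplitude of 6-11 degC, a warming trend (default
  0.03 degC/year), and AR(1) weekly noise (marginal sd 1.8 degC,
  lag-1 correlation 0.5);
* weekly counts are gamma-mixed Poisson with variance `phi * mean`
  (default phi 1.5), i.e. the NB1 negative binomial whose first two
  moments match what a quasi-Poisson fit assumes — the fitting device of
  the analysis is not itself a generative model, so the NB1 stands in for
  it at matched moments;
* a baseline of ~130 deaths/region-week reflects an average region of
  roughly 660,000 inhabitants, with a mild winter-peaked seasonal cycle
  (amplitude 0.10 on the log scale);
* the true cumulative curve of region i is `eta_i = X_i beta_true + u_c`
  in the same 4-df spline space the first stage fits (knots at the
  region's own temperature percentiles), with `u_c ~ N(0, Psi_country)`
  shared within countries. The default `beta_true` is the least-squares
  projection of a canonical U-shaped weekly-scale curve (minimum near
  18 degC, RR ~1.35 ten degrees above it) onto a reference knot layout,
  scaled by the standardized meta-predictors. Truth being in-basis makes
  two-stage recovery exact in expectation; an off-basis
  quadratic-above-threshold truth is available for misspecification
  studies;
* the cumulative curve is spread over lags 0-3 with weights
  0.4/0.3/0.2/0.1; a burn-in of max-lag weeks precedes the first reported
  week so that every reported week has defined lagged exposures;
* ISO weeks use 52-week years by default (week 53 by flag); strata are
  simulated independently given stratum-specific baselines.

Ground truth retained per region: the coefficient 4-vector, the MMT
(argmin of the true curve on the same 0.1 degC grid the estimator uses),
and weekly true attributable numbers `E[mort_t] (1 - exp(-f_true(x_t)))`
above the true MMT.

What the generator does *not* emulate: spatial correlation of temperature
across regions, the COVID-19 mortality disturbance, reporting artifacts,
demographic drift, or between-stratum correlation. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to the full complexity of real
surveillance data.

## Test and experiment sizes

Routine tests use 4 countries x 3 regions x 6 years; recovery experiments
use 50 replicates of 4 x 3 x 8 years (two-stage fixed-effect recovery), 50
replicates of 50 countries x 10 regions (REML recovery, simulated directly
at the coefficient level), 200 replicates for quasi-Poisson coverage and
Monte Carlo CI coverage, and a 40-region, 10-year design for MMT recovery.
These sizes keep each experiment's Monte Carlo error comfortably below the
assertion margins while remaining desk-scale.

Two recovery regimes deserve emphasis. MMT localization to 0.2 degC is
only statistically identified when the curve has a pronounced minimum and
counts are large; the MMT recovery experiment therefore uses a steep
V-shaped truth, country-scale counts (1500 deaths/week), and no country
heterogeneity. Under the default, realistically flat-bottomed curve with
heterogeneity, MMT estimates scatter on the degree scale — matching the
wide MMT uncertainty seen in real analyses — which is a property of the
estimand, not an implementation defect. Similarly, the Monte Carlo
coverage experiment samples estimated coefficients directly from their
sampling distribution rather than refitting 200 GLMs; it isolates the
uncertainty-propagation logic, which is what the interval construction is
responsible for.

## Numerical choices and edge cases

* Natural splines: truncated-power basis; evaluation outside the boundary
  knots continues linearly; NaN inputs propagate to NaN rows.
* IRLS: statsmodels defaults with deviance tolerance 1e-9, max 100
  iterations; rank-deficient designs are rejected with the offending
  columns named; all-zero counts are rejected.
* REML: start values from the residual covariance of an unweighted fit;
  log-Cholesky diagonals bounded in [-12, 4] (a diagonal at the lower
  bound is a numerically-zero variance, i.e. the PSD boundary); tie-break
  in the MMT grid search toward the lower temperature; the grid is aligned
  to multiples of 0.1 degC.
* Attribution validates the MMT against the spline's domain (boundary
  knots ± one grid step) rather than the temperatures of the particular
  sub-period being attributed, since a cool sub-period legitimately lies
  entirely below the MMT.
* Degenerate Monte Carlo covariance (all zeros) yields zero-width
  intervals rather than an error.

## Known limitations

* Weekly resolution underestimates acute, short-lag heat effects relative
  to daily models; the package deliberately mirrors the weekly design.
* The backward attribution mode's even split of the cumulative curve
  across lags is a simplification; lag-specific attribution would require
  carrying the full cross-basis coefficient block into the second stage.
* The meta-regression assumes known first-stage covariances `S_i`;
  uncertainty in `S_i` itself is not propagated (standard in two-stage
  designs).
* Monte Carlo intervals propagate BLUP-level coefficient uncertainty only;
  variance-component uncertainty in `Psi` is not resampled.
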