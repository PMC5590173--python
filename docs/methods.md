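# Methods

## Outcome model

Daily death counts are modelled as quasi-Poisson with log link:
`log mu_t = alpha + s(x_t; eta) + confounders`.  Quasi-likelihood point
estimates coincide with the Poisson MLE, so fitting is a plain Poisson IRLS
(delegated to statsmodels GLM); the overdispersion parameter `phi` is the
Pearson chi-square divided by residual degrees of freedom, and the
coefficient covariance is `phi` times the Poisson covariance.  The canonical
link guarantees that fitted means reproduce the observed total deaths, which
the suite asserts.  Convergence uses statsmodels' deviance criterion
(tol 1e-8, max 100 iterations); non-convergence raises rather than returning
a silent fit.  Days without a complete lag history (the first `L` days) are
dropped from all design blocks rather than padded.

Confounders are six day-of-week indicator contrasts (Monday reference) and a
natural cubic spline of the day index with `round(8 * n_years)` columns
(knots at day-index quantiles).  Rounding to the nearest integer is a
declared convention for non-integer year counts.

## Basis construction and coefficient reduction

The temperature basis is a quadratic B-spline (degree 2, de Boor evaluation
via `scipy.interpolate.BSpline`) with internal knots at the 10th/75th/90th
percentiles of the exposure series by default and boundary knots at its
observed range; without an intercept the first basis function is dropped
(the R convention), anchoring the spanned curve to zero at the lower
boundary — an affine shift absorbed by the model intercept.  Evaluation
outside the boundary knots errors by default; an explicit `extrapolate`
policy extends natural splines linearly and B-splines by their boundary
polynomial pieces (used only for lag bases evaluated at integer lags).  The
natural cubic basis is the truncated-power natural parameterisation; any
parameterisation spanning the same function space is equivalent, and tests
pin the spanned space (second derivatives vanish at and beyond boundary
knots), not basis values.

The cross-basis column for temperature-basis index `j` and lag-basis index
`k` holds `sum_l phi_j(x_{t-l}) psi_k(l)`; columns are ordered with the
temperature index fastest, matching the Kronecker structure of the reducing
matrix `M = 1'C (x) I`.  Lag knots default to equal spacing on the log-lag
scale between log 1 and log L.  With a moving-average exposure metric the
cross-basis degenerates to the temperature basis applied to the trailing
window mean, and reduction is the identity.  Reduction symmetrises the
output covariance; reduced covariances can be numerically indefinite at the
−1e−8-relative level, which the MVN sampler tolerates by eigenvalue
clipping (anything more negative is an error).

## MMT estimators

All argmins are grid argmins on a 0.1 °C grid spanning the observed exposure
range (no finer resolution is scientifically meaningful, and the grid makes
tie-breaking exact: ties go to the lowest temperature).  `Argmin2`
constrains the grid to the 1st–99th observed percentiles, computed by linear
interpolation between order statistics — the same definition used for the
prior supports and RR comparison points.

The empirical estimators draw `beta_(i)` from
`MVN(beta-hat, V(beta-hat))` using a symmetric eigendecomposition factor.
Draws come from a single seeded `numpy` Generator stream in chunks, so the
proposal sequence is independent of chunking; the prior-restricted sampler
(`Empirical2`) consumes exactly the stream the unrestricted sampler
(`Empirical1`) would produce and keeps draws whose argmin falls inside the
uniform prior support.  Proposals stop at `n_sim` acceptances or at a budget
of `100 * n_sim`; below an acceptance rate of 0.5% the sampler raises,
naming the support as incompatible with the data, rather than returning a
quietly short sample (a short-but-adequate sample above the floor is
returned with its bookkeeping).  The default Monte Carlo size is 5000 for
one-shot estimation and 2000 inside the replicated studies.  The point
estimate defaults to the empirical mean (median available); intervals are
empirical percentiles with linear interpolation, (2.5, 97.5) by default and
(0, 95) as the skew-adjusted option.  No automatic skewness rule is applied
— sample skewness is reported and the pair is a caller choice.

Relative risks referenced to the MMT either fix the reference at a point
estimate (delta-method normal CI on the log scale) for the Argmin methods,
or propagate MMT uncertainty through the paired draws,
`RR_(i) = exp((Q_x − Q_theta(i)) beta_(i))`, for the empirical methods.  The
pairing of `theta_(i)` with its generating `beta_(i)` is preserved by the
sampler and required by the RR computation.

## Synthetic scenarios

Real city series are not redistributable, so the harness generates its own
study conditions:

* **Temperature** — annual sinusoid (mean 12 °C, amplitude 15 °C, coldest in
  mid-January) plus AR(1) noise (innovation sd 2.5 °C, lag-1 correlation
  0.6), giving realistic mid-latitude ranges of about −12 to 34 °C.  The
  rotated-S scenario uses a warmer climate (mean 14 °C, amplitude 16 °C) so
  its high true MMT (29.167 °C) sits in the interior of the observed range,
  as it does for the milder source city that scenario emulates.
* **True curves** — four shape families with fixed true MMTs of 23.889
  (U), 11.274 (reverse-J), 29.167 (rotated-S) and −3.333 °C (sector), and
  per-scenario moving-average windows of 3, 2, 4 and 1 days.  Cold arms are
  linear in log RR below the minimum (the threshold form typical of
  lag-cumulated cold effects); heat arms are quadratic (quartic for the
  reverse-J's long flat bottom).  The rotated-S adds a local Gaussian well
  around its warm minimum and an exponential downturn at the extreme cold
  end, producing exactly two local minima with the global one at high
  temperature.  Templates are projected onto the scenario's own B-spline
  basis by least squares, with the template centre calibrated by bisection
  so the projected curve's fine-grid (0.001 °C) argmin lands on the stated
  true MMT; construction errors out if it cannot.  Amplitudes are chosen to
  give cold/heat RRs at the 1st/99th percentiles of roughly 1.0–1.25.  For
  the flatter scenarios (reverse-J, rotated-S) the cold-side slopes are set
  high enough that the MMT remains identifiable from five years of data;
  with weaker slopes the scenario geometry is unidentifiable at this sample
  size and every estimator degenerates.
* **Counts** — mean `exp(baseline + curve + day-of-week + seasonal term)`
  with baseline log rate 5 (≈148 deaths/day, a large city), day-of-week
  effects of up to ±2%, and a 12% winter excess seasonal term (an annual
  cosine, well inside the span of the 8-df/year time spline).  Quasi-Poisson
  is not a generative family, so overdispersed counts are drawn from a
  negative binomial with per-observation size `mu/(phi−1)`, whose variance
  is exactly `phi * mu`; `phi = 1` degenerates to Poisson.  The default
  dispersion is 1.3, typical of city-level daily mortality series.

A study run draws the covariate (temperature/calendar) series once per
scenario and redraws only the counts across replicates — the standard
parametric-simulation protocol, which also makes the fitted basis and knots
identical to the generating ones.  Replicates are seeded by spawned
`SeedSequence` substreams and recorded; replicate-level failures (e.g. the
acceptance floor for a hostile prior) are recorded and excluded with a
count.  Metrics per (scenario, method) cell are mean bias, RMSE, coverage
probability and mean interval length; the RMSE² = bias² + variance identity
is asserted.

### What the generator does and does not emulate

It reproduces the features that drive MMT inference: seasonal temperature
with autocorrelated noise, nonlinear lag-cumulated association with a known
argmin, smooth seasonal/long-term confounding, day-of-week structure, and
variance-proportional-to-mean overdispersion.  It does not emulate
influenza epidemics or heat-wave clustering, lag-structure misspecification
(generation and fitting share the exposure metric), missing data, or
between-city heterogeneity.  Passing coverage here therefore demonstrates
correctness of the estimators under a correctly specified model, not
robustness to the misspecifications real data contain.

## Study sizes and expected results

The replicated studies use 200 replicates of 5 years each with 2000 Monte
Carlo draws per replicate — sizes chosen so a full study runs in well under
a minute on one CPU while binomial noise on a coverage estimate stays near
1.5 percentage points.  Under these conditions the unrestricted empirical
interval covers the true U-shape MMT at or slightly above its nominal 95%
rate; the prior-restricted interval with the minimally informative 1st–99th
percentile support covers comparably while being materially shorter on
average; and in the sector scenario, where the MMT distribution is highly
right-skewed, the (2.5, 97.5) pair under-covers and the skew-adjusted
(0, 95) pair restores >95% coverage.  Interval lengths are several times
larger than they would be with two decades of data — five years simply
identifies an MMT loosely — but coverage, the property under test, is
unaffected.  `scripts/acceptance.py` recomputes these three coverages from
scratch.

## Known limitations

* The prior is restricted to a uniform support; non-uniform priors over
  temperature are out of scope.
* Penalised/smoothing splines and information-criterion basis selection are
  not provided; the basis is the caller's choice.
* The "MMT range" concept (reporting the flat bottom as a range rather than
  a point) is not implemented.
* Attributable-fraction computation downstream of the RRs is out of scope.
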