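# Methods

This package implements a probabilistic pipeline linking an extreme-event
attribution statistic to fish recruitment: compute the Fraction of
Attributable Risk (FAR) for annual sea-surface-temperature anomalies from a
climate-model ensemble, model recruitment and survey catch as functions of
FAR, and compare recruitment distributions expected under historical
(backward-looking) versus projected (forward-looking) climate conditions.
This note records the models, the parameter choices that matter, what the
synthetic data emulate, and the numerical decisions taken where the design
was open.

## Attribution statistic

For a focal anomaly *a*, exceedance probabilities are empirical proportions
`P(sample >= a)` — ties count as exceedances.  FAR is

    FAR = 1 − p_pre / p_cur,

with `p_pre` computed against a climate model's preindustrial realization
and `p_cur` against the "current" sample: the observed anomaly series for
the hindcast, or the model's own scenario realization for projections.  The
focal year is always a member of its own current sample, so `p_cur >= 1/n`
and the ratio is defined.  Raw FAR = 1 (anomaly beyond every preindustrial
value) is reset to 0.9999; raw FAR <= 0 (anomaly no rarer now than
preindustrially) is clamped to 0.0001, symmetrically, because the beta
likelihood's support is the open unit interval.  Clamping is logged.

Anomaly standardization follows the convention of centering on a recent
window (default 1961–2020) and scaling by the SD of a long window (default
1900–2020), applied when raw series are supplied; the synthetic generator
emits anomalies directly.

Note one structural property of the empirical statistic: FAR is monotone
non-decreasing in the focal anomaly only while the current-sample exceedance
count is unchanged.  Crossing a current-sample order statistic lowers
`p_cur` and can lower FAR.  The property tests assert the correct
(conditional) version.

## Beta ensemble model

Per-year-per-model FAR values are combined with a Bayesian beta regression:

    y_ij ~ Beta(mu_ij * phi, (1 − mu_ij) * phi)
    logit(mu_ij) = alpha_year(i) + sigma * (z_model(j) − mean(z))

with year fixed effects `alpha`, climate-model random effects, and a single
shared precision `phi`.  Priors: `alpha ~ Normal(0, 3)` — wide enough on the
logit scale to reach the clamp at 0.9999 (logit 9.2), which an SD of ~1.5
cannot; `z ~ Normal(0, 1)` with `sigma ~ half-Normal(1)`;
`phi ~ half-Normal(50)`.  The model effects are centered inside the
predictor: with ~5 models, a free random-effect mean is confounded with the
year effects, and in that parameterization the sampler can push the global
FAR level into the random effects (we observed exactly this: sigma drifting
to ~3 and year means biased low).  Centering restores identifiability and
matches the term's role — between-model spread, not level.

Reported per year: posterior mean of `expit(alpha)`, its posterior SD (the
"SE" used downstream as measurement error), and equal-tailed 80/90/95%
intervals.  Equal-tailed rather than HPD intervals match conventional
ribbon plotting.  A consequence of the shared precision worth knowing: when
the table mixes noisy mid-range years with saturated years, `phi` settles at
a compromise and saturated-year means plateau around 0.95–0.99 rather than
at the clamp.

## Sampling

No Stan-family probabilistic-programming stack is among this package's
dependencies; all Bayesian models are fit by a compact Hamiltonian Monte
Carlo sampler written here (`farrec.mcmc`), with analytic log-posterior
gradients per model.  The sampler uses dual-averaging step-size adaptation
(target acceptance 0.8), a diagonal mass matrix estimated during a
three-phase warmup (identity-mass step-size search; windowed mass
estimation with adaptation restart; final step-size re-equilibration), and
leapfrog trajectory lengths jittered uniformly in [L/2, L] (default L = 32)
to avoid periodic trajectories.  Trajectories whose energy error exceeds
1000 during sampling are counted as divergent and reported.  Every model's
gradient is verified against central finite differences in the test suite.

Convergence reporting follows the usual bar: split R-hat < 1.05 and bulk
ESS >= 1000 for all parameters, no divergences (`check_convergence`,
computed via ArviZ).  Fits in examples and tests often use shorter chains
than an ESS-1000 run requires; the report then flags this honestly, and
tests assert the quantities they need (calibration, recovery) rather than
the pass flag.  Latent-variable models (measurement-error spline) pass rough
posterior scales to the sampler as the initial mass matrix — latent logit-FAR
scales span two orders of magnitude and identity-mass warmup mixes poorly.

## Dynamic factor analysis

The survey panel is reduced to one shared latent trend:

    x_t = x_{t−1} + w_t,  w_t ~ N(0, 1)       (process variance fixed = 1)
    y_it = Z_i x_t + v_it, v_it ~ N(0, r_i)    (diagonal R, unequal)

Scale is identified by fixing the process variance; sign by requiring a
non-negative mean loading.  The initial state has a weak N(0, 100) prior.
Estimation is EM with a univariate-processing Kalman filter and RTS
smoother; missing observations contribute nothing to the update step.  The
EM log-likelihood is asserted non-decreasing every iteration (a decrease
raises, signalling a bug); convergence is a relative change < 1e−6 or 5000
iterations.  Loading CIs come from the numerically differentiated
observed-information Hessian in (Z, log r); the trend CI from the smoother
variance.  For short panels a conditional parametric bootstrap is available
(`ci_method="bootstrap"`): trend paths are drawn from the smoothing
posterior (forward-filter backward-sample), observations regenerated from
the fitted model with the missingness pattern preserved, and the model
refit per draw.  Conditioning on the realized trend matters because trend
magnitude acts as an ancillary for loading identification — a panel whose
trend happened to wander little identifies loadings weakly, and an
unconditional bootstrap would understate exactly those panels'
uncertainty.  The EM/Kalman core is numba-compiled, which makes a few
hundred bootstrap refits cost a few seconds.  The filter log-likelihood is
verified against a brute-force joint-Gaussian density of the stacked
observations.

Series are standardized per series (observed entries) before fitting by
default, the convention for survey indices on disparate scales; loadings
are then unitless.  Simulation-recovery tests fit with
`standardize=False`, because with the process variance fixed the generative
loadings are only identified on the unstandardized scale.

## Seine catch models

Set-level counts follow a zero-inflated negative binomial: logit link for
the structural-zero probability, log links for the NB mean and shape.
Continuous covariates (egg/larval temperature anomaly, day of year, SSB)
are standardized internally and enter both model parts, as do nested random
intercepts (bay; site within bay), non-centered.  Priors: Normal(0, 2) on
fixed effects, half-Normal(1) on the four random-effect SDs, Normal(0, 1)
on the log shape.  Coefficients are reported on the standardized scale with
the centering/scaling constants attached for natural-unit conversion.

The annual abundance index refits the ZINB with year as a categorical
effect (cell-means coding) in both parts, day of year held at its sample
mean and random effects marginalized at zero; the index is the posterior of
`(1 − pi) * mu` per year — expected fish per set.

The categorical-FAR comparison is, as specified, a Gaussian model on
set-level catch with two class means (years with FAR above vs below 0.98),
kept positive through a log-scale parameterization with a Normal(2, 3)
prior on the log means and a wide half-Normal on the residual SD.  A
Gaussian likelihood on counts is a deliberate simplification — it estimates
the class mean difference, not a full count distribution — and Bayesian R²
is attached for comparability.

`pin_zero_inflation=True` pins the structural-zero intercept at logit −12
(tight prior), reducing the likelihood to a plain negative binomial; the
tests verify the reduction matches a maximum-likelihood NB fit to within
0.01 log-score per observation.

## Recruitment–FAR response

Standardized log recruitment anomalies (zero mean, unit variance; the
constants are retained for back-transformation) are modeled as a penalized
low-rank thin-plate spline of FAR.  Basis construction: radial basis
`|x − x'|^3` on the distinct covariate values, rank-k spectral truncation of
the radial matrix (dominant eigenvectors), absorption of the `{1, x}`
null-space constraint, and re-diagonalization of the reduced penalty so the
penalized coefficients carry an iid N(0, tau^2) smoothing prior.  The
covariate is z-scored internally and penalized columns are normalized to
unit sample SD, making fits invariant to affine rescaling of the FAR axis.
Basis size is restricted to k = 3 (default for FAR, ~40–50 annual
observations) or k = 5 (richer smooths, e.g. day of year), i.e. 1 or 3
penalized functions beyond the linear null space.  Priors: Normal(0, 10) on
null-space coefficients, `tau ~ half-Normal(1)`, residual
`sigma ~ half-Normal(1)` (the response has unit variance).

An earlier construction that kept the *smallest*-eigenvalue directions of
the constrained penalty was discarded: its penalized column was nearly
collinear with the linear term (condition number in the hundreds) and badly
attenuated step-like responses.  The dominant-eigenvector construction is
well conditioned (condition ~1) and recovers a −2 SD step at FAR 0.98 to
within posterior uncertainty.

The measurement-error variant treats each year's true FAR as latent with a
truncated-Normal(mean, SE) prior on (0, 1) — mean and SE from the beta
ensemble model — sampled through a logistic transform (with Jacobian), with
spline knots fixed at the posterior-mean FAR values.  With all SEs zero it
falls back to the error-free fit with a notice.  The classical attenuation
property (noisier covariate, no steeper response) and the
variance-ordering property (ME predictive variance not smaller) are checked
on simulations.

Model comparison is PSIS-LOO via ArviZ (`LOOIC = −2 * elpd_loo`), with
Pareto-k > 0.7 flagged; correctness is checked against brute-force exact
leave-one-out refits of a conjugate Gaussian model.  Bayesian R² is the
per-draw ratio `var(fitted) / (var(fitted) + sigma^2)` with the model's
residual variance, reported as median and 95% CI.  Recruitment failure is a
standardized log anomaly strictly below −1.

Recent years poorly informed by assessments are bridged from the seine
annual index: ordinary least squares of assessment recruitment on the log
index over the overlap years (>= 3 required), with closed-form predictive
SEs.  Bridged values enter the spline fit as plug-in data; propagating
their predictive SE is possible in principle but is not done by default.

## Projection

Predictive recruitment for a period (historical, 2020s, 2030s, 2040s): per
posterior draw, sample a year uniformly from the period, draw that year's
latent FAR from its truncated-Normal posterior, evaluate the spline, add
residual noise — a full distributional comparison, not a mean comparison.
Percent decline is computed in original units: invert the standardization
(`exp(z * scale + center)`), take medians, report `100 * (1 − ratio)`.  A
period median above the historical one yields a negative decline, reported
as-is; no lognormal bias correction is applied to the back-transform (the
statistic is a median, which commutes with the monotone transform).
Posterior uncertainty on the decline comes from per-draw period medians of
the fitted spline (residual noise has median zero and drops out of a
median), giving a draw-wise decline distribution and a 95% interval.

Years within a period are weighted equally.  The historical predictive
distribution resamples historical FAR years with their posterior
uncertainty; a mean-plug-in variant is available
(`use_posterior_far=False`).

## Synthetic data

The generator supplies every pipeline input with the statistical structure
the analysis assumes, under fixed study-like conditions:

* **Climate** — observed series: linear trend + stationary AR(1) noise
  (stationary initialization); per model, one stationary preindustrial
  realization (default 60 years) and one trended projection realization,
  default five pseudo-models.  Defaults (trend 0.05 anomaly units/yr over
  60 years, AR(1) 0.5, noise SD 0.4; projection trend 0.06/yr anchored to
  the observed trend line at the projection start year) were chosen once so
  the system reproduces the study regime: early decades inside the
  preindustrial envelope, roughly half of the final decade outside it
  (hindcast FAR ≈ 1 for those years), and projections transitioning from
  mixed FAR to values fixed above 0.95.
* **Recruitment** — mean response linear in FAR or a step at a threshold
  (default 0.98, step −2 SD, residual SD 0.5), Gaussian residuals.
* **Seine catches** — ZINB with logit-linear zero part and log-linear mean,
  covariates in both parts (zero part with opposite sign, scaled 0.5: what
  raises mean catch lowers structural-zero odds), nested bay/site
  intercepts, 15 bays × 6 sites by default with July–August sampling dates.
  When FAR drives the simulation, the year-level temperature anomaly is
  centered on `2*FAR − 1`, tying catch to FAR through temperature.
* **Survey panel** — series = loading × shared random-walk trend + Gaussian
  noise with per-series SDs, missing-completely-at-random gaps per series.

One global seed expands into independent substreams (SeedSequence), so
adding a generator does not perturb the others and every generator is
byte-reproducible.  What the generator does *not* emulate: spatial
structure, structured (non-MCAR) survey gaps, collinear covariates
(salinity, transport) alongside FAR, autocorrelated recruitment residuals,
and climate-model bias differences.  Passing tests therefore demonstrate
the estimators' correctness and calibration under the assumed structure,
not robustness to real-data misspecification.

## Problem sizes and degenerate inputs

Test and example problem sizes are chosen to exercise the study's design
scale where it matters (e.g. 3,000 seine sets for covariate recovery; 50
replicate panels for DFA calibration; 20 ensembles for FAR-interval
coverage; 25 replicates for decline coverage) with chain lengths of a few
hundred warmup/draw iterations — enough for stable posterior means and
intervals in these smooth, low-dimensional posteriors, while keeping the
full suite in the minutes range.  Degenerate inputs are rejected with named
errors (zero-SD scale window, empty exceedance sample, zero current
probability, non-integer counts, single-class FAR data, single-chain
diagnostics, oversized spline bases); underobserved DFA series are dropped
with a warning rather than failing the fit.

## Known limitations

* The affine-invariant HMC replacement for a mature PPL is deliberately
  minimal: no NUTS tree-building, no per-parameter step sizes beyond the
  diagonal mass.  Funnel-prone posteriors are handled by non-centered
  parameterizations rather than sampler sophistication.
* The shared beta precision compresses saturated FAR years (see above);
  a year-varying precision would free them at the cost of n more
  parameters.
* The Gaussian categorical-FAR model ignores count skew; its class means
  remain interpretable but its predictive distribution is not a count
  model.
* The seine-bridge uncertainty is plugged in, not propagated.
* k = 3 splines can represent monotone threshold-like responses but not
  multimodal ones; that is the point of the restriction, but it is a real
  constraint.
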