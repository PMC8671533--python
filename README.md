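# farrec

Climate attribution meets fish recruitment: this package asks how the
production of young fish changes when ocean temperatures leave the envelope
of natural variability, and what that implies for the backward-looking
expectations that fisheries decisions usually rest on.

It is written for quantitative fisheries scientists and climate-impact
analysts.  The pipeline has three stages:

1. **Attribution.**  For each year's sea-surface-temperature anomaly,
   compute the Fraction of Attributable Risk

   *FAR = 1 − P(anomaly | preindustrial) / P(anomaly | current)*,

   with probabilities measured as empirical exceedance proportions against
   each climate model's preindustrial realization ("≥" counts as
   exceedance; FAR = 1 is reset to 0.9999).  Per-year, per-model FAR values
   are combined in a Bayesian beta regression — year fixed effects on the
   logit scale, climate-model identity as a (centered) random effect,
   shared precision — giving a posterior mean, SE, and 80/90/95% credible
   ribbons per year, for the observed record (hindcast) and for
   high-emissions scenario realizations (projection).

2. **Recruitment as a function of FAR.**  Recruitment signals come from a
   stock-assessment-style series, from a shared latent trend extracted from
   multiple survey indices by dynamic factor analysis (random-walk trend,
   diagonal unequal observation variances, EM + Kalman smoother robust to
   missing years), and from set-level beach-seine catches modeled with a
   hierarchical zero-inflated negative binomial (temperature, day-of-year
   and spawning-stock-biomass covariates plus nested bay/site intercepts).
   Standardized log recruitment anomalies are then regressed on FAR with a
   penalized thin-plate spline (3 or 5 basis functions), including a
   measurement-error variant that treats each year's true FAR as latent
   with the attribution posterior's SE.  Candidate models are compared by
   LOOIC (PSIS-LOO); fits are summarized by Bayesian R²; recruitment
   failure is a log anomaly below −1.

3. **Projection.**  Predicted recruitment distributions under historical
   FAR are compared with the 2020s/2030s/2040s projection FAR posteriors,
   and declines are reported as percent change in median recruitment in
   original (back-transformed) units, with posterior intervals.

All Bayesian models are fit with a built-in Hamiltonian Monte Carlo sampler
(analytic gradients, dual-averaging step size, diagonal mass adaptation);
convergence is reported as split R-hat, bulk ESS and divergence counts.
Every input can be simulated by the `farrec.simulate` module, so the whole
pipeline runs and is tested with no data download.  See `docs/methods.md`
for model details and assumptions.

## Worked example

The `analysis/` scripts run the full study on synthetic data (about ten minutes
end to end; outputs land under `results/`):

```bash
python analysis/01_simulate.py      # climate ensemble, surveys, seines
python analysis/02_attribution.py   # FAR tables + beta ensemble posteriors
python analysis/03_dfa.py           # shared latent recruitment trend
python analysis/04_counts.py        # ZINB catch models, annual index
python analysis/05_recruitment.py   # recruitment-FAR spline fits, LOOIC
python analysis/06_project.py       # decadal projection + percent declines
```

`02_attribution.py` prints the decade means of the hindcast FAR posterior,
showing the emergence of anthropogenic extremes from the natural envelope:

```
hindcast: 300 rows, max R-hat 1.022, min ESS 618
1960    0.015
1970    0.015
1980    0.030
1990    0.195
2000    0.521
2010    0.866
2020    0.985
  years with posterior mean FAR >= 0.98: 7
```

`03_dfa.py` recovers the survey-panel structure — three informative indices
and one (larval-style) series whose loading cannot be distinguished from
zero:

```
series_id  estimate    se   lo95  hi95
 series_1     0.459 0.070  0.323 0.595
 series_2     0.504 0.079  0.348 0.659
 series_3     0.356 0.083  0.194 0.519
 series_4    -0.111 0.094 -0.295 0.074
loadings indistinguishable from zero: series_4
```

`05_recruitment.py` fits the recruitment-FAR response on the bridged,
standardized series (`Bayesian R2 = 0.25 [95% CI 0.06-0.47]`; mean response
at FAR 0.999 is 1.12 SD below FAR 0.5 with posterior probability 0.99), and
`06_project.py` compares backward- and forward-looking recruitment
distributions — medians in original recruitment units with 95% CIs,
declines relative to the historical period:

```
    period  median  ci95_lo  ci95_hi  pct_decline_vs_historical
historical   28.69     7.16    97.47                       0.00
     2020s   16.40     4.81    55.05                      42.84
     2030s   16.69     4.68    64.07                      41.81
     2040s   15.42     4.57    53.66                      46.26
2020s: decline 43% [95% CI 18-67%]
```

The pattern mirrors the scientific story: the predicted decline is almost
entirely in place by the 2020s, because projected FAR is already near its
ceiling — the statistic saturates once anomalies are attributable, so it
flags the transition into the anthropogenic state rather than further
warming within it.

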