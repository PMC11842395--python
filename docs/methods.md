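# Methods

## Model and assumptions

The package models the probability that a heart-failure patient reaches a
composite endpoint (all-cause death or heart transplantation) within a fixed
horizon as a saturating function of their plasma NT-proBNP concentration
`x` (pg/mL):

```
P(x) = p0 + pmax · x^γ / (x^γ + ec50^γ),   0 ≤ p0 ≤ p0 + pmax ≤ 1,  ec50, γ > 0
```

Endpoints are treated as independent Bernoulli outcomes with per-patient
probability `P(x_i)`; the likelihood is the product of Bernoulli terms, and
estimation is by maximum likelihood.  The model is cross-sectional: it maps a
single per-patient concentration summary to a cumulative risk over the
horizon.  It deliberately ignores time-to-event structure, covariates, and
repeated-measures correlation.  `p0` and `pmax` are cohort-specific (they
absorb age mix, disease severity and observation window), whereas `ec50` and
`γ` describe the rise of relative risk with concentration and are the
quantities most meaningfully compared across cohorts.

Two reduced regimes mirror how such data are usually analysed.  With `γ`
fixed at 1 the curve is a rectangular hyperbola (fewest free parameters;
appropriate when the data cannot support a free shape exponent).  With
`p0 = 0` and `pmax = 1` fixed the model is exactly a log-logistic regression:
`P(x) = expit(γ·(ln x − ln ec50))`, i.e. logistic regression on
ln-concentration with slope `γ` and intercept `−γ·ln ec50`.  This equivalence
is used as an independent test oracle (statsmodels `Logit`), never as the
implementation.

## Numerical implementation

**Function evaluation.**  The saturating ratio is computed in log space as
`expit(γ·(ln x − ln ec50))`, which is overflow-safe for any `γ·ln x`;
`x = 0` is special-cased to return `p0` exactly.

**Reparameterization.**  Optimization runs on an unconstrained internal
scale: `p0 = expit(t0)·(1 − pmax_fixed)`, `pmax = expit(t1)·(1 − p0)`,
`ec50 = exp(t2)`, `γ = exp(t3)`.  Every internal point maps to an admissible
parameter set for *any* combination of fixed parameters, which a direct
logit transform of `(p0, p0 + pmax)` would not allow (fixing `pmax` alone
does not fix a coordinate of that pair).  Masks that leave no headroom
(e.g. `pmax` fixed at 1 with `p0` free) are rejected at construction.

**Optimizer.**  BFGS from a default start (`p0` = half the event rate,
`pmax` = event rate, `ec50` = median concentration, `γ = 1`) plus 4
seeded perturbed restarts (SD 0.5 on the internal scale); the likelihood can
be nearly flat in `pmax` when high-concentration observations are sparse, and
the restarts guard against the resulting local minima.  Ties within the nll
tolerance (1e-8, relative at large n) are broken by the lower `ec50` for
determinism.  A Nelder–Mead polish from the best point supplies the
convergence verdict on the nll-change scale — at n ~ 10⁵ the gradient norm is
dominated by numeric-differentiation noise and is not a usable criterion —
and its solution is adopted only if it improves the nll beyond tolerance
(otherwise the gradient-centred quasi-Newton point is kept, which stabilises
the finite-difference Hessian).  Estimates at the internal-scale boundary
(|logit| > 15, `ec50` far outside the data range) are flagged
`identified=False` rather than raising, mirroring the practice of fixing a
non-identifiable `pmax` and refitting.

**Variance–covariance.**  Central finite-difference Hessian of the negative
log-likelihood at the optimum, per-coordinate step `1e-4·(1 + |θ|)` on the
internal scale; off-diagonals use the symmetric four-point formula.  The
inverse Hessian is the internal-scale covariance; natural-scale covariance
follows by the delta method with a numerical Jacobian.  A non-positive-
definite Hessian raises a non-identifiability error naming the parameter that
dominates the flattest eigendirection, with the advice to refit with it
fixed.

**Confidence bands.**  Parameter vectors are sampled from a multivariate
normal on the internal scale (so every draw is admissible — no clipping or
rejection is ever needed), mapped through the model on the concentration
grid, and summarised pointwise by the median and equal-tailed quantiles.
Defaults: 10,000 samples, 90% level, log-spaced grid 10–100,000 pg/mL with
200 points.  Per-parameter intervals use the normal approximation
(`estimate ± z·se`); fixed parameters report `se = 0` and degenerate
intervals, marked as fixed.

**Quantile binning.**  Bin edges are inverse-CDF empirical quantiles of
concentration; an observation exactly on a cut point goes to the lower bin;
duplicate edges caused by ties are merged with a logged warning.  Binomial
intervals are Wilson score intervals (statsmodels), chosen for sane behaviour
at 0 events and small n — bins with zero events still get a non-degenerate
upper bound.  The same inverse-CDF quantile convention is used for
median/IQR entries in baseline tables.

**Cohort data.**  Times are integer-valued days relative to enrollment
(day 0); any calendar-date or baseline-shift logic (e.g. setting baseline one
month after first diagnosis) is the caller's responsibility upstream.  Two
biomarker summaries are supported: the measurement nearest enrollment within
±30 days (a bounded window prevents silently using late values), or the
median of all measurements within the horizon.  Patients with no eligible
measurement are excluded with a logged count, not an error.  Percentages in
baseline reports are rounded to integers.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: per-patient true
concentrations from a log-scale normal mixture, Bernoulli endpoints from the
model at the true concentration, event times uniform on the horizon split
between death and transplant by a configurable fraction, and longitudinal
measurement series with multiplicative lognormal noise (default SD 0.2 on the
ln scale) around the true concentration.

Presets encode the three published cohort settings used throughout the tests
(pediatric EHR cohort n=109, horizon 730 d, generative parameters
(0.094, 0.65, 3730, 1); pediatric registry cohort n=146, horizon 1825 d,
(0, 1, 4200, 1.21); adult EHR cohort n=108,330, horizon 730 d,
(0.055, 0.55, 3880, 1)).  The mixtures are this package's own choice — the
sources report only cohort medians and a qualitatively bimodal shape — and
were tuned once, analytically, so the mixture median equals the reported
cohort median: equal-weight components with medians 312.5 and 5,000 pg/mL
(ln-SD 1.0) give median 1,250 for the pediatric EHR preset (geometric-mean
identity for equal weights and SDs); components (0.65, median 88.5) and
(0.35, median 3,000) give median 184 for the registry preset; the adult
preset is a single lognormal ln N(ln 2000, 1.2²).  The registry EC50 is
reported as 4199 in one place and 4200 in another in the source material;
presets use 4200 and the preset notes record the discrepancy.

What the generator does **not** emulate: informative measurement timing,
time-varying hazard (event times are uniform, since only the binary endpoint
enters the likelihood), covariate effects, missingness mechanisms, or
assay floor/ceiling effects.  Passing tests therefore demonstrate that the
estimation and uncertainty machinery is correct under the model's own
assumptions, not that the model is adequate for any particular real cohort.

## Simulation design in the test suite

Problem sizes were chosen once as the package's own testing conditions:
parameter recovery at n = 20,000 (pediatric regimes) and n = 100,000 (adult
regime); band coverage with 200 replicate cohorts of n = 800 (large enough
for the Wald/Monte-Carlo band to be in its asymptotic regime) evaluated at
the generative EC50 with 2,000 propagation samples; consistency and
band-width monotonicity with 20 replicates at each of n ∈ {500, 5,000,
50,000}; Monte-Carlo band stability at n = 500 with the full 10,000 samples.
Bulk simulations use 2 optimizer starts (the surfaces there are unimodal in
practice); single headline fits use the default 5.

## Known limitations

* Wald/normal-approximation intervals can undercover at small n (a few
  hundred patients) where the likelihood is markedly non-quadratic in
  `pmax`; the propagated band's coverage was verified at n = 800, not at
  n ≈ 100.
* The interval-overlap comparison criterion is conservative relative to a
  formal test of difference; the Wald z-test on ln EC50 is reported alongside
  as an explicitly labelled extension.
* `p0` and `pmax` are not comparable across cohorts with different horizons
  or age structures by design; only `ec50` and `γ` are.
* The finite-difference Hessian assumes an interior optimum; boundary
  (non-identified) fits must be rerun with the offending parameter fixed, as
  the error message advises.
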