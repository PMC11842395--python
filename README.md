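# emaxrisk

Saturating (E<sub>max</sub>-type) biomarker–risk modelling for heart-failure
cohorts: fit the probability of a composite clinical endpoint — all-cause
death or heart transplantation within a fixed follow-up horizon — as a
function of plasma NT-proBNP concentration, quantify the uncertainty of the
fitted risk curve, and compare curves across cohorts.

NT-proBNP (N-terminal prohormone of B-type natriuretic peptide) is released
from cardiomyocytes under myocardial stretch and is the standard circulating
heart-failure biomarker.  In both pediatric and adult cohorts its
relationship to event risk is well described by an E<sub>max</sub> function:
risk starts at a baseline, rises around a characteristic concentration, and
saturates at high concentrations.  The package is aimed at biostatisticians
and pharmacometricians who need this analysis on their own cohort data — or,
because real linked biomarker/outcome datasets in pediatric heart failure are
proprietary, on realistic synthetic cohorts that the package generates.

## Model

For patient *i* with NT-proBNP concentration *x<sub>i</sub>* (pg/mL), the
event probability is

```
P_i = P0 + Pmax · x_i^γ / (x_i^γ + EC50^γ)
```

* `P0` — baseline event probability at vanishing concentration,
* `Pmax` — maximum probability added onto the baseline (`P0 + Pmax ≤ 1`),
* `EC50` — concentration of half-maximum added risk (pg/mL),
* `γ` — Hill-type shape exponent controlling steepness.

The binary endpoints `y_i ∈ {0,1}` are modelled as independent Bernoulli
draws with probability `P_i`, and parameters are estimated by maximum
likelihood.  Any subset of parameters can be held fixed: with `γ = 1` the
curve is a rectangular hyperbola in concentration; with `P0 = 0, Pmax = 1`
the model reduces to a log-logistic regression (equivalently, logistic
regression on `ln x`, with slope `γ` and intercept `−γ·ln EC50`).

Standard errors come from the inverse finite-difference Hessian of the
negative log-likelihood at the optimum (computed on an unconstrained internal
scale and mapped back by the delta method).  Confidence bands for the risk
curve come from parametric Monte-Carlo forward propagation: 10,000 parameter
vectors drawn from the approximate sampling distribution, each pushed through
the model, summarised pointwise by the median and equal-tailed 90% interval.
Model-free quantile-binned event rates with Wilson score intervals provide
the observed-data comparison.

## Worked example

Fit a synthetic pediatric-EHR-like cohort (2,000 patients, γ fixed at 1):

```python
from dataclasses import replace
import numpy as np
import emaxrisk as er

cfg = replace(er.preset_configs()["explorys_child"], n=2000, seed=11)
cohort = er.generate_cohort(cfg)
model = er.EmaxRiskModel.from_rows(cohort.analysis_rows)
result = model.fit(mask=er.FixedMask.gamma_fixed(1.0))
print(result.summary())
```

```
Emax risk model (Bernoulli maximum likelihood)
==========================================================
N obs: 2000    events: 582 (29.1%)
Log-likelihood: -1072.2741    converged: True    identified: True
Free parameters: p0, pmax, ec50
----------------------------------------------------------
       estimate        se        lo       hi  fixed
p0    0.0878362 0.0157858 0.0618708 0.113802  False
pmax    0.58301 0.0466666  0.506251  0.65977  False
ec50    3312.77   862.502   1894.08  4731.46  False
gamma         1         0         1        1   True
```

The cohort was generated with true parameters `(P0, Pmax, EC50, γ) =
(0.094, 0.65, 3730, 1)`; each 90% interval covers its generating value.
Propagate the parameter uncertainty to the risk curve:

```python
curve = result.risk_curve(grid=np.array([100., 1000., 3730., 10000.]),
                          n_samples=10_000, seed=0)
print(curve.to_frame().to_string(index=False))
```

```
 ntprobnp_pgml  median_prob       lo       hi
         100.0     0.105028 0.086518 0.130866
        1000.0     0.224090 0.202645 0.245111
        3730.0     0.394364 0.366399 0.422338
       10000.0     0.522842 0.486433 0.553835
```

A patient at 100 pg/mL has roughly a 10% two-year risk of death or
transplant; at 10,000 pg/mL the risk is about 52% — the steep rise is
centred at EC50.  `er.bin_event_rates(rows, n_bins=4)` gives the matching
model-free quartile event rates, and `er.compare_cohorts({...})` reports
pairwise EC50 interval-overlap verdicts across cohorts.

The same analyses are available from the shell:

```
emaxrisk generate --preset pcmr --seed 1 --out pcmr.csv
emaxrisk fit pcmr.csv --fix p0=0 --fix pmax=1
emaxrisk run config.yaml --out artifacts/
```

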