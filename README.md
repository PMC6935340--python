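# nodewalk

Mortality hazard-ratio series over lymph-node-involvement cutoffs, modelled
as a random walk with drift.

## The problem

In node-positive breast cancer, the *percentage of involved nodes* (positive
axillary nodes among those examined, ×100) is a more robust prognostic
measure than the raw positive-node count, which is confounded by how many
nodes were examined. A registry-scale analysis of this relationship proceeds
in three steps:

1. At every percentage cutoff *t*, dichotomise the cohort into high
   (pct ≥ *t*) versus low involvement and fit a covariate-adjusted Cox
   proportional-hazards model; the coefficient of the indicator gives the
   adjusted mortality hazard ratio *H<sub>t</sub>*.
2. Treat the ordered *H<sub>t</sub>* as a time-series-like sequence and model
   its increments as a **random walk with drift**:

   *H<sub>t</sub> − H<sub>t−1</sub> = μ + a<sub>t</sub>*,

   where μ is a constant drift (the mean increment of mortality risk per
   cutoff step) and *a<sub>t</sub>* is white noise. Integrating gives
   *H<sub>t</sub> = μ·t + H<sub>0</sub> + (a<sub>1</sub> + … + a<sub>t</sub>)*:
   the risk at involvement *t* is a baseline plus a linear burden term plus
   accumulated stochastic shocks.
3. Check the white-noise hypothesis on the residuals with the sample
   autocorrelation function and the portmanteau (Ljung–Box) test.

The registry data behind such analyses are access-restricted, so this
package ships a **synthetic cohort generator** that reproduces the published
marginal structure of the study population — nodal-count strata, covariate
prevalences, proportional-hazards survival with a log-hazard linear in the
percentage of involved nodes, and administrative censoring — making every
stage testable end to end. It is aimed at biostatisticians who want to study
the behaviour of this estimator chain (bias, coverage, drift recovery,
diagnostic calibration) under a known truth.

All components are implemented from first principles where they are the
point of the analysis (Cox partial likelihood with Efron/Breslow tie
handling, Newton–Raphson, the drift estimators, ACF, Ljung–Box); established
libraries (lifelines, statsmodels) appear only as independent oracles in the
test suite.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (4,387 patients, seeded):

```text
$ python analysis/01_simulate_cohort.py --seed 1
wrote 4387 patients to results/cohort.csv
  deaths: 1877 (42.8%)
  median follow-up among censored: 105 months
  examined >= 15 nodes: 56.5%
  single positive node: 34.7%

$ python analysis/02_sweep_hazard_ratios.py
retained 93 cutoffs, skipped 1
  H at t=3%: 1.33 (1.00-1.76)
  H at t=98%: 2.56 (1.89-3.48)

$ python analysis/03_fit_random_walk.py
drift mu = 0.0134 hazard-ratio units per step (~1.3% mortality increment per retained cutoff)
innovation variance sigma^2 = 0.0021
white-noise check: Q = 13.89 on 10 df, p = 0.178 (consistent with white noise)

$ python analysis/04_render_figures.py   # H_t with 95% bands + differences panel
```

Reading the output: the adjusted hazard ratio rises steadily from 1.33 at a
3% cutoff to 2.56 at 98%, the mean increment per retained cutoff is
μ̂ = 0.013 with innovation variance σ̂² = 0.002, and the Ljung–Box test
(p = 0.178) finds no evidence against treating the increments as white
noise — the random-walk-with-drift description is adequate for this cohort.

The same pipeline is scriptable (`nodewalk run --config analysis.yaml`) or
callable from Python:

```python
from nodewalk import CohortConfig, generate_cohort, sweep_cutoffs, fit_random_walk

cohort = generate_cohort(CohortConfig(seed=1))
series = sweep_cutoffs(cohort)           # ordered (t, H_t, CI) points
fit = fit_random_walk(series)            # DriftFit + AcfResult + PortmanteauResult
print(fit.drift.mu, fit.drift.sigma2, fit.portmanteau.p)
```

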