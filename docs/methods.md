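# Methods

## The estimator chain

The package implements a three-stage analysis of the relationship between
the percentage of involved axillary nodes and overall mortality in
node-positive breast cancer.

**Stage 1 — adjusted hazard ratios per cutoff.** For each cutoff *t* on the
percentage scale, the cohort is split at pct ≥ *t* (strictly-below as the
reference arm; ≥ is used so that *t* = 100 contrasts full involvement) and a
Cox proportional-hazards model is refit with the high-involvement indicator
plus the full adjustment set: registry area (two indicators), year of
diagnosis, race, marital status, age, histology, grade, ER and PR status,
tumour location and size. *H<sub>t</sub>* = exp(β̂) of the indicator, with a
Wald 95% interval on the log scale. The default grid is the integers 1–100,
collapsed so each retained cutoff induces a distinct high/low partition
(cutoffs between two adjacent observed percentages give identical fits).
Cutoffs with fewer than `min_events = 10` deaths in either arm, degenerate
designs, separation (monotone likelihood) or non-convergence are recorded as
skipped with a reason.

**Stage 2 — random walk with drift.** The ordered retained *H<sub>t</sub>*
are differenced on the natural hazard-ratio scale (a log-scale option
exists but is not the default). Retained points are re-indexed consecutively
(unit steps): the cutoff axis is a surrogate ordering rather than a physical
time scale, and skipped cutoffs would otherwise create irregular spacing; a
`per_percent` flag divides each difference by the actual cutoff gap instead.
The drift μ̂ is the sample mean of the differences — which telescopes to
(H_last − H_first)/(n−1) — residuals are the centred differences, and the
innovation variance σ̂² is their sample variance with denominator n−1.
Reconstruction H_t = μ̂·t + H₀ + Σa inverts the decomposition exactly.

**Stage 3 — white-noise diagnostics.** Sample autocorrelations
ρ̂_k = Σ(x_t−x̄)(x_{t−k}−x̄)/Σ(x_t−x̄)² feed the portmanteau statistic,
Ljung–Box by default (Q = n(n+2)Σρ̂²_k/(n−k); Box–Pierce selectable), with h
degrees of freedom and **no degrees-of-freedom correction** — only a mean
was removed from the differences, no ARMA parameters were estimated. The
default lag count is h = min(10, ⌊n_diffs/5⌋); h is echoed in every output
because the p-value depends on it.

## Cox fitting

The partial likelihood, score and observed information are computed exactly
(suffix sums over the risk sets, `reduceat` over tied-event groups), with
**Efron** tie handling by default (month-resolution registry times guarantee
ties; Efron is the less biased standard) and Breslow as an option; the two
coincide on tie-free data. Newton–Raphson with step-halving maximises the
likelihood; convergence requires score sup-norm < 1e-8 within 50 iterations.
Step-halving rejects genuine likelihood decreases but tolerates
rounding-level wobble (1e-10·|ℓ|), without which the final Newton steps of a
large fit can stall below machine precision. |β̂_j| > 15 flags a monotone
likelihood (separation); the sweep skips such cutoffs instead of failing.
Constant covariate columns raise a degenerate-design error; a fit with no
events is rejected. The sweep warm-starts each cutoff's fit from the
previous solution, which does not change converged results (tolerance
1e-8) but roughly halves iteration counts. No stratification, time-varying
effects, robust variance or baseline-hazard estimation: the analysis uses
none of them.

## The synthetic cohort generator

The generator emulates the study population of the motivating registry
analysis: women 50–65 with a first primary T1–T2, node-positive, M0 breast
carcinoma treated by mastectomy without radiotherapy. It reproduces the
published *marginal* structure; the joint structure is a modelling choice.

- **Nodes examined**: stratum-first sampling with weights 37/543/1327/2480
  out of 4387 for strata 1–4, 5–9, 10–14, 15+ (exact published counts, so
  the weights sum to one), uniform within stratum; the open 15+ stratum is
  capped at 40 nodes, a practical ceiling for an axillary dissection.
- **Nodes positive**: Binomial(examined, p_i) truncated to ≥ 1, with the
  per-patient involvement propensity p_i drawn from a **two-component beta
  mixture**, w = 0.5304 on Beta(0.0686, 1.0670) and the rest on
  Beta(9.5831, 107.9061). A patient's component is a fixed trait: the
  truncation redraws propensity and count *within* her component, so counts
  follow the mixture of per-component truncated beta-binomials. The
  components read as a low-burden mode (most examined nodes clear) and a
  moderate-burden mode. A single beta cannot reproduce the published
  involved-node strata (its best fit misses the 4–9 stratum by ~0.03); the
  mixture parameters were calibrated once, by exact truncated beta-binomial
  probabilities marginalised over the examined-node distribution, to match
  the published margins 35.6% / 32.6% / 22.0% / 9.8% for 1 / 2–3 / 4–9 / 10+
  involved nodes to numerical precision.
- **Covariates**: Bernoulli with published prevalences (black 0.084, married
  0.674, ductal 0.791, grade 3–4 0.358, ER− 0.163, PR− 0.228, medial 0.109;
  area east/central/west 0.417/0.310/0.273), age ~ U(50, 65) years, tumour
  size ~ U(1, 50) mm, diagnosis year uniform on 1988–1997. Only marginals
  are published, so covariates are sampled independently.
- **Survival**: exponential event times with log rate = log(baseline) +
  β_pct · pct + Σ effects · covariates. Cox estimation is baseline-agnostic,
  so the simplest constant-hazard generator consistent with proportional
  hazards is used. Default covariate effects are the logs of the published
  adjusted hazard ratios (e.g. log 1.42 for black race, log 0.94 per
  diagnosis year). Continuous covariates enter centred (age at 57.5 y, size
  at 25.5 mm, year at 1992.5) purely to keep the baseline scale sane; the
  fitted model is invariant to this shift. Defaults: β_pct = 0.012 per
  percentage point, which puts the high-vs-low hazard ratios on the scale
  the motivating analysis displays (≈1 to ≈3 across the cutoff range), and
  baseline rate 0.0035/month, giving ≈40% any-cause deaths over follow-up.
- **Censoring**: administrative, uniform on (58, 167) months. The window was
  calibrated once by simulation so that the median follow-up among censored
  patients is ≈106 months with a 167-month maximum, mimicking staggered
  entry over a decade with a fixed cutoff date.

Everything flows through one seeded `numpy` generator per stage: identical
configurations are bit-reproducible, different seeds give different cohorts.

**What the generator does not emulate** — and hence what passing tests do
not show about real registry data: covariate dependence (joint
distributions, the pre-1990 hormone-receptor missingness pattern),
non-proportional or time-varying effects, cause-specific mortality, and any
within-patient biology linking nodal burden to covariates beyond the linear
log-hazard term. Conclusions from this package are about the estimator
chain under a known generating model, not about breast-cancer biology.

## Numerical and design choices

- Wald intervals on the log-HR scale at 0.95, matching the convention of
  published adjusted hazard ratios.
- The hazard-ratio series invariants (strictly increasing cutoffs, both-arm
  event minima, positive HRs) are validated when a series is read back from
  CSV before the random-walk stage consumes it.
- A numerically pure-drift series (residual SD below 1e-10 of the series
  scale) raises an explicit error from the random-walk fit: white-noise
  diagnostics on rounding noise would be meaningless.
- The ACF rejects zero-variance input; the portmanteau test requires
  n > lags + 1.
- Exit codes: 2 configuration, 3 data integrity, 4 numerical failure.

## Simulation study sizes

The test suite exercises the chain at sizes chosen to make each check
well-powered yet quick: oracle equivalence on 20 random tied datasets of
n = 50; drift/variance recovery with 2,000 replicates of length-80 series at
truth μ = 0.02, σ² = 0.004; portmanteau size with 5,000 replicates and power
against AR(1) φ = 0.8 with 1,000; end-to-end recovery with 50 effect cohorts
of n = 5,000 (full sweeps on a step-3 grid) plus 200 null cohorts. Null
CI coverage is evaluated at **one rotating cutoff per replicate** (5 to 80
by 5): coverage indicators across the cutoffs of a single cohort are
strongly correlated because every fit reuses the same patients, so pooling
them would not have a binomial reference distribution; one indicator per
independent cohort makes the nominal-coverage check exact.

## Known limitations

- **Portmanteau finite-sample size.** With short series and many lags the
  chi-square reference for the Ljung–Box statistic over-rejects: at series
  length 60 with h = 10 the true size at nominal 0.05 is ≈0.065 (Monte
  Carlo; statsmodels' implementation gives the same rate), while Box–Pierce
  under-rejects (≈0.035). Calibration is accurate in the long-series/few-lag
  regime (size ≈0.046 at length 300, h = 5). p-values from short series
  with h = 10 should be read with this inflation in mind.
- **Jensen-type bias at extreme cutoffs.** H_t = exp(β̂) is convex in β̂, so
  sparse high-involvement arms (large SE) inflate E[H_t] slightly; under the
  null generator the drift estimate inherits a small positive bias through
  the telescoping endpoints.
- **Successive H_t share patients**, so the white-noise model for their
  increments is an approximation by construction; the diagnostics quantify
  its adequacy, they do not make the increments independent.
- The percentage of involved nodes is bounded in (0, 100], whereas a random
  walk is unbounded; the model is a local description over the observed
  range, not a generative claim.
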