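# Methods

## The model chain

The package implements a projection pipeline for community home-based
eldercare demand among adults aged 60+, organized around six
functional-capacity (FC) states: 1 "viability disorder", 2 "acute
disease", 3 "somatic functional disorder", 4 "health", 5 "sub-disorder
status", and 6 death (absorbing). Severity runs 4 < 5 < 2 < 3 < 1 from
mild to severe. The stages are:

1. **State definition (LCA).** A finite mixture of K latent classes over
   29 categorical functional indicators with conditional independence
   given class. Fitted by EM from multiple random starts; model choice by
   AIC/BIC/SSA-BIC, relative entropy, and a parametric bootstrap
   likelihood ratio test (BLRT) of K−1 vs K. Classes are mapped onto the
   canonical state ids by ranking their mean impairment probability
   (share of non-baseline responses averaged over indicators) along the
   severity ladder; ties break by class index and are logged.
2. **Transition modelling.** A continuous-time Markov model on the six
   states, observed as an interval-censored panel (states known only at
   survey waves). Instantaneous transitions are restricted to
   severity-adjacent living states (4↔5, 5↔2, 2↔3, 3↔1) plus every
   living state → death; over a finite interval all living states remain
   reachable through P(h) = exp(hQ). Intensities are log-linear in 0/1
   covariates (female, age ≥ 70), so exp(β) is a hazard ratio. The panel
   log-likelihood is the sum over consecutive observation pairs of
   ln P(Δt)[s_prev, s_next]; an optional exact-death mode replaces a
   death interval's term with ln Σ_r P(Δt)[s_prev, r]·q_r6. This flag is
   off by default: survey panels usually record death from registries
   with uncertain timing, and the interval-censored form is the
   conservative choice.
3. **Embedding / rescaling.** An empirical transition matrix P observed
   over Δ years is converted to a per-year generator Q = log(P)/Δ
   (principal matrix logarithm), and rescaled to any horizon as
   exp(hQ) — e.g. a 3-year matrix yields a 10-year one as
   exp(10·logP(3)/3). Empirical matrices need not be embeddable: small
   negative off-diagonal rates are repaired by clipping to zero and
   resetting the diagonal (the repair magnitude is returned), while a
   zero or negative real eigenvalue means the principal logarithm does
   not exist and the function raises rather than guessing a branch.
4. **Cohort projection.** Sex × age-band cohorts of state-specific
   counts advance in 5-year steps by exp(5Q) of their current stratum;
   cohorts are promoted from the 60–69 band to ≥ 70 exactly 10 years
   after entry (within-band age heterogeneity is ignored); new entrants
   join the 60–69 band at decade boundaries with a configurable initial
   state distribution; deaths accumulate in state 6, so a closed cohort
   conserves persons. A community/home care share (default 0.97, the
   "90-7-3" policy's home + community share) scales living counts only.
5. **Costing.** Two engines. The *project-cost* method composes per-item
   costs A–E (materials, manpower, transport, management = 5% of A+B+C,
   education = 5% of A+B+C+D, hence total = 1.1025·(A+B+C) exactly) and
   aggregates per-item annual totals. The *man-hour* method prices care
   time: monthly per-person cost = weekly hours(state) × 4 × 1.8 ×
   hourly wage(year), with weekly hours 10.58/1.5/7.42/4.5 for states
   1/2/3/5 (states 4 and 6 consume no care), the 1.8 community-care cost
   coefficient, and a wage anchored at 97,379 yuan/year over 251×8 h
   (48.50 yuan/h in 2020) compounded at 6.5%/5.4%/4.5% per year over
   2010–2020/2020–2030/2030–2040. Totals split into family vs
   professional caregiver demand by a `family_share` parameter.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| chain baseline intensities | 0.02–0.45 | /year | produce one-year transition probabilities on the scale of the published fitted matrices |
| female effect on 2→5 / 5→2 | HR 0.72 / 1.56 | — | the published covariate estimates |
| age ≥ 70 effect on 2→5 / 5→2 | HR 0.42 / 1.51 | — | the published covariate estimates |
| age ≥ 70 effect on death | HR 2.0 | — | our choice: doubling matches the roughly twofold 1-year death probabilities of the ≥ 70 stratum |
| wave times | 0, 2, 4 | years | biennial survey waves |
| care share | 0.97 | fraction | home (90%) + community (7%) share of the 90-7-3 pattern |
| family_share | 0.7416 | fraction | not stated as an input anywhere; back-calculated once from the published 2020 state-1 family/combined totals (196.418/264.850); the "about three times" family:professional ratio is then a derived quantity (0.7416/0.2584 ≈ 2.87) |
| weekly care hours | 10.58/1.5/7.42/4.5 h | states 1/2/3/5 | published service-duration standards |
| EM restarts | 20 (5 in bootstrap refits) | — | multimodal mixture likelihood |
| optimizer | L-BFGS-B + simplex polish + restart | — | finite-difference gradients on log intensities; Hessian by central differences (relative step 1e-5) for Wald CIs |

## What the synthetic generator does and does not emulate

`synthetic.generate_cohort` simulates latent trajectories as an exact
continuous-time Markov chain (exponential holding times, competing-risk
destination draws), records the state at the wave times, and emits 29
binary indicators per living wave from class-conditional distributions
ordered along the severity ladder. It reproduces the features the
estimators rely on — interval censoring, absorbing death, stratified
intensities, covariate proportionality, a measurement layer with
entropy ≈ 0.8 — and is exactly Markov at all horizons, which real
functional-decline data need not be. It does not emulate survey
weights, household clustering, missing data/imputation, time-varying
age within a panel, or misclassification of death. Passing recovery
tests therefore validate the estimators under the model's own
assumptions, not the substantive fit of any real cohort.

## Numerical choices

- EM declares convergence on an absolute log-likelihood change below
  `tol` (default 1e-8; 1e-3 inside bootstrap refits, where the
  null-model likelihood surface is flat and a slightly early stop only
  shrinks the bootstrap statistic, i.e. is conservative). Monotonicity
  is enforced to 1e-8. Response patterns are collapsed to unique rows
  with multiplicity weights.
- `0·ln 0 = 0` throughout entropy computations; relative entropy for
  K = 1 returns 1 by convention with a log note.
- `transition_probability` uses scaling-and-squaring Padé (scipy expm)
  and clips only excursions within 1e-12 of [0, 1].
- The panel likelihood collapses the data to sufficient statistics
  (covariate pattern, Δt, state pair) so each evaluation costs one
  matrix exponential per distinct (pattern, Δt).
- The prevalence goodness-of-fit statistic T = Σ(obs−exp)²/exp is
  evaluated over state × time cells with positive expected counts;
  expected counts propagate each covariate pattern's observed first-wave
  distribution through exp(tQ); the χ² reference uses
  df = cells − parameters (floored at 1), and a parametric-bootstrap
  alternative (`gof_bootstrap_p`) re-simulates panels from the fitted
  intensities without refitting.
- Decimal-exact aggregation: published table cells are summed as
  `decimal.Decimal` scaled integers, so 3-decimal printed values add
  without binary floating-point drift.

## Design choices that were genuinely open

- **Chain topology.** The adjacency set is fixed from the severity
  ordering 4–5–2–3–1 (the published transition diagram is not
  enumerated edge-by-edge in text); death is reachable directly from
  every living state, as all published matrices show nonzero death
  probabilities from every state. The mask is user-overridable.
- **Printed-table anomalies.** Fixtures carry the published tables
  digit-for-digit and flag, never repair: two state-6 rows with a stray
  0.080, one transition row summing to 1.079, repeated 2030/2035
  columns in the caregiver tables, and a per-item total row that is
  0.001 off the decimal-exact item sum in three of four years. Grand
  totals are always computed as item sums.
- **Embeddability of the printed matrices.** At printed 3-decimal
  precision the states-2 and -3 rows of most strata coincide, making
  the matrices singular; their principal logarithm does not exist, and
  the package reports this rather than renormalizing. The projection
  therefore runs on generators estimated by the package's own pipeline
  (an exact embedding round trip), and the repair path is exercised on
  the one quasi-embeddable printed stratum (male ≥ 70, clipped rate
  0.057/yr).
- **Entrants timing.** Output periods are every 5 years while entrants
  arrive per decade; entrants are injected at the 2020/2030 steps by
  default and the injection periods are configurable.
- **Death accounting.** State-6 projection counts are cumulative (the
  published death column is consistent with cumulation); a per-period
  flow can be recovered by differencing.

## Problem sizes used in validation

Recovery and calibration checks run at panel sizes of 1000–4000
individuals (2000 for the 20-seed intensity-recovery study, 4000 for
hazard-ratio recovery), LCA selection at n = 5000 over K ∈ {2..6}, and
bootstrap tests at 19–49 replicates. These sizes give sampling errors
comfortably inside the asserted tolerances while keeping the full suite
in the minutes range.

## Known limitations

- No misclassification (hidden Markov) layer on the state process; the
  measurement model applies only to the indicator emission stage.
- Intensities are time-homogeneous within a stratum; ageing acts only
  through the band promotion at 10 years.
- The man-hour engine prices all listed care states at full uptake; the
  published caregiver tables embed an unstated additional scaling, so
  they are carried as fixtures and the engine's bottom-up totals are
  validated against the formula, not against those tables.
- Bootstrap p-values use the add-one rule, so the attainable minimum is
  1/(B+1).
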