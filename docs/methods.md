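# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `psomipd`. Units: time in days (week-based regimen inputs are
converted as 1 week = 7 days exactly), doses in mg, concentrations in mg/L
(identical to µg/mL, the ELISA assay unit), PASI dimensionless.

## Structural models

**Pharmacokinetics.** Two-compartment disposition with first-order absorption
from a subcutaneous depot and linear elimination. The central concentration
after a single dose is the classic tri-exponential

C(t) = F·D·ka/V2 · [ A·e^(−αt) + B·e^(−βt) + C·e^(−ka·t) ],

with α, β the roots of λ² − (k10+k12+k21)λ + k10·k21 and coefficients from
k21, ka. Multi-dose profiles are exact superpositions of shifted single-dose
solutions; the PK is never integrated numerically in the production path. An
ODE integrator (LSODA, rtol 1e-8) over the depot/central/peripheral/eliminated
states exists solely as an independent oracle, including a mass-balance check.
If ka collides with a disposition eigenvalue, ka is nudged by a relative 1e-7
so the generic formula remains valid; the difference from the exact limiting
form is far below every tolerance used.

Because all administrations are subcutaneous, bioavailability is not
separately identifiable: parameters default to the apparent scale (CL/F etc.,
F = 1), with an explicit F < 1 available as a configuration switch.

*Typical values.* The shipped PK defaults (ka 0.35/day, CL/F 0.465 L/day,
Q/F 0.4 L/day, V2/F 4.6 L, V3/F 2.8 L, reference weight 70 kg) are
illustrative, for testing the machinery; real analyses must substitute a
published ustekinumab population model through the configuration file. Body
weight acts allometrically with exponents 0.75 (CL, Q) and 1.0 (V2, V3) —
standard allometric theory, all configurable. A consequence of the
illustrative values worth knowing: simulated troughs on label-like regimens
are a few tenths of mg/L, so roughly half of the synthetic pre-dose samples
fall below the 0.63 mg/L assay limit, and strict targets are hard to attain —
the decision mix on synthetic cohorts is therefore not comparable to any real
cohort.

**Pharmacodynamics.** PASI follows type-I indirect response: production k_in
inhibited by the drug, first-order loss k_out,

dPASI/dt = k_in·(1 − Imax·C/(IC50+C)) − k_out·PASI,  k_in = k_out·PASI₀,

initialized at the untreated steady state PASI₀. With constant concentration
the trajectory relaxes mono-exponentially (half-time ln2/k_out ≈ 43 days at
k_out = 0.016/day) to PASI₀·(1 − Imax·C/(IC50+C)); both facts are exploited as
closed-form test oracles. Only subcutaneous dosing, no target-mediated
elimination, no immunogenicity.

## Solvers

The reference PD integrator is LSODA (rtol 1e-6 production, 1e-8 for
oracles). All inner loops (estimation, sampling, regimen simulation) use an
exponential-stepping scheme on a uniform grid: over each step the inhibition
is frozen at the midpoint of its node values, for which the linear turnover
ODE is solved exactly,

P_{k+1} = P_k·a + PASI₀·(1 − Ī_k)·(1 − a),  a = e^(−k_out·Δt),

evaluated as an IIR filter in C (scipy.signal.lfilter). The scheme is
unconditionally stable, exactly proportional to PASI₀, and agrees with the
adaptive solver to ≲0.1% at Δt = 0.25–0.5 day (asserted in tests). Δt
defaults: 0.25 day for cohort generation and regimen simulation, 0.5 day
inside estimation.

## Estimation

Sequential PK→PD, mirroring practice for sparse TDM against a fixed
literature PK model.

1. **Individual PK (MAP).** For each patient, maximize
   log p(y_PK|η) + log p(η|ω) over the log-scale deviations of parameters
   with non-zero IIV (default CL, V2 at SD 0.3 — illustrative). Residual
   error is proportional with the SD anchored at the observation
   (sd = σ_PK·y): this keeps η = 0 exactly optimal when the data sit on the
   typical prediction and avoids the degenerate incentive to shrink the
   predicted variance. Below-LOQ samples (< 0.63 mg/L) are excluded by
   default and tallied; a left-censored normal likelihood is available as a
   configuration option. Patients with no quantifiable samples get the
   covariate-typical individual.

2. **Population PD (Laplace).** Estimated: k_out, Imax, ω_kout (log-scale
   IIV SD on k_out), σ (log-scale residual SD). IC50 is fixed at 0.07 mg/L.
   Two latent dimensions per subject are marginalized: η_kout and η_RV, the
   baseline deviation of the B2 method PASIᵢ = PASIᵢ₀·e^(η_RV) with
   Var(η_RV) = σ² tied to the residual variance. Because the turnover
   solution is exactly proportional to the baseline, η_RV maximizes in
   closed form given η_kout — the inner optimization is one-dimensional
   (bounded Brent, warm-started across outer iterations) and the joint 2×2
   curvature at the mode is semi-analytic. The outer optimizer is
   Nelder–Mead on transformed coordinates (log for positive parameters,
   logit for Imax) with bounds and 5 perturbed starts (seeded; default
   20240101). Relative standard errors come from a finite-difference Hessian
   of the negative log marginal likelihood at the optimum, delta-transformed
   to the natural scale.

   Table-2 interpretation: the printed residual "Error (%) 0.86" is treated
   as the log-scale SD 0.86 (i.e. exp-multiplicative error consistent with
   the B2 form), and the IIV "55.87 (%)" as log-scale SD 0.5587 × 100. A
   natural-scale proportional error variant exists as a configuration stub.
   PASI observations of exactly 0 (possible in real records) have no density
   under a log-normal error and are raised to a configurable floor (default
   0.1), logged whenever applied; positive observations are never altered.

   An adaptive Gauss–Hermite quadrature (nodes centered and scaled at the
   Laplace mode) evaluates the same marginal integral as an independent
   oracle; tests require agreement with a dense-trapezoid brute force to
   1e-3 on single-subject problems.

3. **pcVPC.** Prediction-corrected VPC: each observed and simulated value is
   rescaled by (bin-median population prediction / own population
   prediction); quantile-based time bins; simulation bands are percentile
   CIs across ≥100 replicate cohorts drawn from the fitted model. Note that
   within one cohort all bins shift together through the shared random
   effects, so per-bin coverage statements should be pooled across replicate
   cohorts (the test suite does).

## Conditional sampling and decisions

Per patient, random-walk Metropolis–Hastings on (η_kout, η_RV) — optionally
plus PK η dimensions — targets p(ψᵢ|yᵢ) ∝ p(yᵢ|ψᵢ)p(ψᵢ). Defaults: chain
initialized at the empirical-Bayes mode, initial proposal SD 0.5× the prior
SD per dimension, burn-in 500 with adaptation toward 30% acceptance every 50
iterations (capped at ×10/÷10, frozen after burn-in to preserve detailed
balance of retained draws), thinning 10, 100 retained clones. Per-patient
seeds derive from a base seed plus a CRC of the patient id, so cohorts are
reproducible patient-by-patient.

Each clone is simulated deterministically (no residual noise — decisions
should reflect parameter uncertainty, not assay noise) through 5 cycles of
the patient's current regimen and 5 cycles of each candidate, PD state
continuous across the switch; a "cycle" lasts the interval of whatever
regimen is being given, and evaluation happens at the trough instants ending
cycles 5 and 10 (the conservative reading of "PASI at the 5th/10th cycle").
The probability of PASI ≤ 1 (inclusive at the boundary) is the exact clone
fraction × 100. Selection: candidates with probability ≥ 90% qualify; the
minimum dose intensity in mg/week wins, ties to the longer interval;
classification against the current regimen's intensity gives
maintain/optimize/intensify, or failure when nothing qualifies. The
simulation starts from the untreated steady state with the full current
dosing history applied, since the patients' true historical PD state is not
observable.

Cost arithmetic uses the per-dose price of EUR 2915.4: first-year counts
include induction at weeks 0 and 4 then maintenance spacing within weeks
[0, 52); maintenance years count floor(52/interval) doses; savings are dose-
count ratios, independent of price.

## Synthetic cohorts

The generator reproduces the study conditions summary-by-summary: body
weight ~ truncated normal 92 ± 18.4 kg on [70, 135]; observed baseline PASI
~ truncated normal 14.4 ± 6.23 on [5, 31.9]; current regimens drawn from the
published frequency table (e.g. 8/23 on 90 mg q12w); label-style dosing
history (weeks 0 and 4, then maintenance spacing); PK sampling = pre-dose at
a mid-study anchor dose plus a thinned template of 2–18 weeks post-dose,
2–5 samples per patient targeting ≈75 cohort samples; PASI visits every
3 months in year one then every 6 months (≈115 observations per 23
patients), or biweekly over 18 months in the rich-sampling mode used for
recovery experiments; assay censoring flags outside 0.63–20 mg/L. True
baselines are obs·e^(η_RV) with η_RV ~ N(0, σ²), matching the B2 model
exactly. Hidden truths (parameters, latent trajectories, per-patient noise
seeds) ride along for recovery scoring, and everything regenerates
byte-identically from the master seed.

What passing tests on these cohorts do *not* show: correctness of the
illustrative PK typical values, real-world decision fractions or trough
targets, adherence/dropout effects, PASI scoring artifacts (integer-ish
clinical scoring, floor effects at 0), or time-varying weight. The
generator's distributions are exactly the model's own, so estimation tests
demonstrate internal consistency, not robustness to misspecification.

## Problem sizes and seeds

The reference recovery experiment uses 100 virtual patients with biweekly
PASI over 18 months and known individual PK; the median fit takes a couple
of minutes on one CPU, and tolerances (25% on k_out, 0.05 absolute on Imax,
30% on ω_kout and σ) were set from pilot simulation of cohort-to-cohort
spread at that size. End-to-end pipeline checks use the study-sized
23-patient cohort. All stochastic stages (generation, multi-start, MH) are
seeded; reruns under one configuration are byte-identical.

## Known limitations

- ω_kout shows a mild downward finite-sample pull (≈10–20% at n = 100):
  subjects with fast k_out carry little information about how fast (the PASI
  plateau is k_out-independent), one-sidedly truncating the identifiable
  spread. Well inside the stated tolerance, but visible.
- Laplace vs quadrature differ by ~0.1 per subject in log-likelihood at
  σ ≈ 0.86; this shifts estimates negligibly relative to sampling noise but
  matters if objective values are compared across implementations.
- The candidate evaluation simulates 5+5 cycles from baseline rather than
  the patient's actual (unobservable) clinical state; for patients whose
  history differs grossly from steady state the cycle-5 probabilities are
  approximate.
- Single PD random effect (k_out only), per the declared random-effects
  structure; Imax carries no IIV, so between-patient differences in maximal
  response load onto k_out and the baseline.
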