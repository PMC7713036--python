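# Methods

## Estimand and regimens

The package estimates the counterfactual cumulative incidence (risk) of a
rare terminal adverse event under two *stochastic* treatment-duration
regimens, from longitudinal observational data with quarterly (90-day)
follow-up over at most 40 quarters:

* **Short-term**: discontinue treatment during the first 3 years, with the
  discontinuation quarter uniform on quarters 1–12, and stay off afterwards.
* **Longer-term**: stay on treatment through quarter 12, then either
  discontinue in one of quarters 13–40 or never discontinue; each of those
  29 outcomes carries equal mass by default (the "never" atom's mass is a
  configuration parameter).

Both regimens assign probability 0 to restarting after discontinuation, so
an observed restart makes the history incompatible with the arm from that
quarter on (artificial censoring). A subject continuously on treatment has
positive probability under both laws and contributes person-time to both
arms simultaneously during quarters 1–11; at quarter 12 an on-treatment
history becomes impossible under the short-term law.

The per-quarter conditional discontinuation hazard implied by the uniform
marginal law is `1/(13−t)` for the short-term arm (t = 1..12) and
`1/(42−t)` for the longer-term arm (t = 13..40, with the default 1/29
"never" atom); forward-multiplying these reproduces the uniform masses to
machine precision, which is asserted in the test suite.

## Exposure classification

Exposure is reconstructed from dispensing records (start day, days' supply)
on a day-level calendar. Quarter *t* is the half-open interval
[90(t−1), 90t) with day 0 the index date; the half-open convention avoids
double counting and is asserted by a brute-force day-walk oracle in the
tests. A refill that arrives while ≤ 30 covered days remain is stockpiled
(the remainder is appended after the prior supply ends); with > 30 days
remaining, the new prescription takes precedence and the earlier surplus
beyond its reach is discarded. When three or more prescriptions overlap,
the rule is applied sequentially pairwise in start-day order (ties broken
by days' supply). A quarter counts as *on treatment* when its proportion of
days covered (PDC) is ≥ 0.50; the boundary (45 of 90 days) classifies as
on. Covariate measurements carry forward without expiry, and never-measured
subjects receive the cohort-mean fill value with a paired imputation
indicator.

## Synthetic cohort

The generator produces the treatment-confounder feedback topology that
motivates inverse probability weighting, with a deliberately reduced
covariate set: an age-like baseline covariate (N(68.6, 9.1²)), a binary
frailty indicator (20%), and a dynamic bone-density-like score
L(t) = L(t−1) − 0.02 + 0.05·on(t−1) + N(0, 0.05²), L(1) ~ N(−2.5, 0.7²).
Treatment slows the decline of L; a low *measured* L makes continuation
more likely (log-odds −1.5 per unit); and a low *true* L raises the event
hazard (log-odds −1.0 per unit) — so past treatment shapes a covariate that
confounds later treatment and outcome.

Treatment decisions depend on the last *measured* score: baseline L is
unmeasured for 27.6% of subjects (replaced by the cohort mean −2.5 with an
indicator), re-measurement occurs at 5%/quarter, and values carry forward.
Because prescribing depends only on observed quantities, sequential
exchangeability holds with respect to the recorded history and the weighted
estimator is consistent by construction; the event hazard still depends on
the latent score, so the panel retains realistic measurement sparseness.

Default rates were chosen to mirror the scale of a large
pharmacoepidemiologic new-user cohort: quarter-1 on-treatment prevalence
≈ 95%, per-quarter continuation ≈ 0.88 at typical covariates (about 20% of
entrants complete 12 consecutive on-quarters, matching the flow of such
cohorts), re-initiation ≈ 3%/quarter, and per-quarter censoring hazards of
roughly 0.2% (death, age- and frailty-dependent), 1% (disenrollment) and
0.25% (exclusion). The event is rare: logistic per-quarter hazard with
intercept −13.4, cumulative-exposure log-odds +0.10 per on-quarter, and the
L and frailty terms above, giving ≈ 2×10⁻⁵ per quarter at baseline
covariates and 20–60 events per 20,000-subject cohort. The rare-event
invariant is enforced as a *population-average* per-quarter hazard ≤ 10⁻³;
a pointwise bound cannot hold for any nondegenerate logistic hazard because
the covariate tail is unbounded.

Administrative end of study falls at the fixed 40-quarter horizon for every
subject — entry is not staggered in the synthetic design — so the
administrative "censoring model" is degenerate by construction and
contributes weight 1.

Smaller study sizes use a *scaled* family: the event-hazard intercept is
shifted by log(20000/n) so the expected event count (which governs
estimator stability) is preserved; the confounding structure is unchanged.
Two special variants support the operating-characteristic studies: a
*null* configuration with a flat 5×10⁻⁴ per-quarter hazard that ignores
treatment, cumulative exposure, L and frailty (both arms then share one
truth exactly), and a *strong-effect* configuration with cumulative-exposure
log-odds 0.15/quarter.

### Dispensing emission

On-quarters are rendered as one 90-day record per quarter: the first record
of a run starts 0–9 days into the quarter (refill delay); subsequent
refills either start after a ≤ 9-day gap or are picked up 1–9 days early
with probability 0.3, producing ≤ 30-day overlaps that exercise the
stockpiling rule. Under these defaults the re-classification is exact:
stockpiling keeps coverage contiguous within a run, the first quarter of a
run is covered for ≥ 81 days, and spill past the run's end is at most 9
days — so the round trip reproduces the simulator's on/off flags
identically, which the tests assert.

### Ground-truth oracle

True counterfactual risks are computed by direct Monte-Carlo intervention:
treatment is drawn from the regimen's conditional discontinuation hazards
while covariate dynamics and the event and death processes are left
untouched; disenrollment and exclusion are disabled (the estimand adjusts
them away via censoring weights) and death is retained as a censoring
event, matching the follow-up rules of the emulated design. Risk is
1 − ∏(1 − h(t)) with h(t) the event fraction among at-risk survivors, and
Monte-Carlo uncertainty uses the Greenwood variance. The oracle is verified
in the tests against an exact finite-state recursion on a coarsened
configuration (baseline and dynamics noise set to zero, so the intervened
process is a Markov chain over discontinuation-quarter × frailty).

## Weights

Six logistic models define the weights: treatment initiation (entry or
re-initiation after a gap, with an entry indicator), treatment continuation
(with a cumulative-exposure main term), and one per-quarter hazard model
per censoring cause (death, disenrollment, exclusion; administrative end is
deterministic). All models adjust for the current measured score, its
imputation indicator, frailty, standardized age, cumulative exposure to
date, follow-up time, and time since the last measurement. The continuation
model is fit on person-quarters on treatment in the prior quarter; each
censoring model on person-quarters at risk of that cause (causes resolve
sequentially within a quarter: death, then disenrollment, then exclusion,
so the product of the three fitted survival factors is the joint uncensored
probability). A cause with zero observed transitions is flagged degenerate
and contributes probability 0.

The treatment weight is self-stabilized by the intervention law:
w_trt(t) = ∏_{k≤t} g*(A_k | history)/ĝ(A_k | history), where g* is the
arm's law and ĝ the fitted probability of the *observed* action. The
censoring weight uses the pooled marginal per-quarter uncensored fraction
as numerator over the fitted joint uncensored probability. Weights are
cumulative, zero from the first arm-incompatible quarter, floored in the
denominator at 10⁻⁴ (floored cells are counted and reported), combined
multiplicatively, and truncated at 50 (configurable).

Two diagnostics are always reported: per-arm weight median/IQR over
compatible at-risk person-quarters and the truncated fraction. Under the
default conditions the short-arm median sits near 1.08 and the truncated
fraction near 0.1–0.3%. The longer-arm median lands near 1.6–1.7: with an
intervention-law numerator the forced-continuation window accumulates
factors 1/ĝ(on) ≈ 1/0.95 per quarter among continuers, so the median
weight of that arm is mechanically (1/ĝ)^t at the median contributing
quarter. This is a structural property of intervention-law stabilization
combined with the cohort's realistic persistence (≈ 22% of entrants
complete 12 consecutive on-quarters), not an estimation defect; truncation
bias is the price at the far horizon (see Limitations).

## Estimation

The marginal structural model is saturated (one hazard parameter per
arm-quarter), so the IPW fit is the closed-form weighted empirical hazard
h_a(t) = Σ w·event / Σ w·at-risk over arm-compatible person-quarters —
algebraically identical to a weighted logistic regression on quarter
indicators, but exactly testable. Survival is S_a(t) = ∏(1 − h_a), risk is
1 − S_a, the arm contrast is risk_longer − risk_short, and the global
curve comparison is the difference in Σ_{t≤40} S_a(t) (one-quarter
rectangle rule on the discrete grid).

Uncertainty comes from a subject-level nonparametric bootstrap with *full
re-fit* of every propensity model in each replicate, expressed as
multiplicity weights so the original design matrices are reused. CIs are
pointwise percentile (2.5/97.5), SEs are replicate standard deviations, and
the curve-area difference is tested with a bootstrap-SE Wald statistic
(two-sided normal). Replicates with an empty weighted risk set in any
quarter are dropped and counted; more than 20% dropped raises an inference
failure. B defaults to 200.

### Numerical choices

* Logistic fits use an in-package Newton/IRLS solver (ridge 10⁻¹⁰ on the
  Hessian diagonal, step tolerance 10⁻¹⁰, linear predictor clipped at ±30),
  cross-validated against statsmodels GLM to 10⁻⁶ in the tests.
* Bootstrap re-fits run batched across replicates in float32 with two
  warm-started Newton steps from the full-data solution; quadratic
  convergence makes the residual coefficient error ~10⁻³, which moves risk
  curves by ~10⁻⁵ — two orders below bootstrap noise. Shared per-cell Gram
  tensors make a replicate cost a few dense matrix products.
* Quarters with an empty weighted risk set contribute h = 0 and carry an
  emptiness flag propagated to the outputs.
* Ties in dispensing start days are broken by days' supply before the
  sequential overlap rule is applied.

## Operating-characteristic studies (problem sizes)

* **No-confounding equivalence**: marginally randomized treatment,
  n = 20,000; IPW and crude risks agree at quarters 16/20/40 within 3
  Monte-Carlo SEs.
* **Parameter recovery**: default confounded cohort, n = 20,000, B = 200,
  oracle n_mc = 100,000; IPW within 3 bootstrap SEs of truth in both arms
  at quarters 16/20/40 while the crude longer-arm estimate is > 3 oracle
  MC SEs from truth.
* **Type-I error**: 200 null cohorts (n = 2,000, B = 100); rejection rate
  at α = 0.05 within [0.02, 0.09].
* **Power**: 30 strong-effect cohorts (n = 2,000, B = 100); rejection rate
  ≥ 80%.
* **Coverage**: 50 cohorts from the scaled confounded family (n = 2,000,
  B = 100); the fraction of repetitions whose 95% percentile CI for risk
  at quarter 20 covers the oracle truth is assessed per arm against a 90%
  target (see Limitations for the measured shortfall at this scale).

## What the generator does and does not emulate

The synthetic cohort reproduces the *structure* that matters for the
method: quarterly exposure updating from raw dispensings, a
treatment-responsive confounder observed through a sparse measurement
process, four censoring mechanisms, dual-arm person-time contribution, and
rare events at the scale of tens per 20,000 subjects. It does not attempt
real-data features such as bimodal adherence phenotypes, staggered entry
with calendar-time administrative censoring, covariate-dependent
measurement scheduling, multi-drug switching, or dose variation. Passing
tests therefore certify the estimator's internal validity under a known
generating law — not the clinical magnitude of any real-world association.

## Limitations

* Weight truncation at 50 trades variance for a late-horizon bias of a few
  to ~10% relative at quarter 40 when event rates are artificially
  inflated (positive in the longer arm, negative in the short arm); the
  deviation vanishes without truncation, and under the default rare-event
  conditions it is far below one bootstrap SE.
* Treatment initiation and re-initiation are deliberately independent of
  the dynamic score: score-driven restarting makes long off-treatment
  histories practically unobservable for exactly the high-risk stratum,
  and under such finite-sample positivity failure no weighting estimator
  can recover the short-term arm's risk at realistic cohort sizes.
  Confounding therefore operates through the continuation model.
* The bootstrap Wald test for the curve-area difference relies on a normal
  approximation that is coarse when expected events are very few; the
  calibration study runs at an event scale where the approximation is
  exercised meaningfully.
* Percentile CIs for rare-event risks undercover at small n: at n = 2,000
  (≈ 55 events) the measured coverage of the 95% interval for risk at
  quarter 20 is ≈ 84% per arm even though the point estimator is unbiased
  there, because cohorts that under-draw events yield bootstrap
  distributions that sit entirely below the truth; raising B does not
  help. At the reference cohort size the oracle truth falls inside the
  bootstrap intervals at every quarter examined by the parameter-recovery
  check.
* No competing-risk estimand is offered: death is censoring, matching the
  emulated follow-up rules, and the oracle retains death-selection of the
  at-risk population while the censoring-weighted estimator removes it —
  a discrepancy that is second-order at the default death rates.
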