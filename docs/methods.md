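# Methods

## Model and estimands

Each trial arm g ∈ {C, E} contributes an aggregate summary: an event
count x_g, assumed Poisson with mean λ_g T_g / 100, and its person-years
of follow-up T_g (PYFU). All incidences, including the counterfactual
placebo incidence λ_P, are expressed per 100 PYFU; person-time is stored
in PYFU and the scale conversion happens at exactly one point
(`avert.estimands.INCIDENCE_SCALE`). Rates are treated as constant over
follow-up; the package works entirely with count/person-time summaries
and does not model individual event times, time-varying incidence,
dropout or non-adherence. "Rate ratio" here means the incidence-rate
ratio; for rare events it is numerically close to the hazard ratio that
trial reports often quote, but no hazard model is fitted.

The averted events ratio is

    Psi = (lambda_P - lambda_E) / (lambda_P - lambda_C),

computed at full double precision from the observed incidences and the
counterfactual input. The two admissible counterfactual inputs are
(a) λ_P itself, or (b) the control efficacy θ_CP ∈ (0, 1), which implies
λ_P = λ_C / (1 − θ_CP); with β_EC = λ_E/λ_C the equivalent form is
Psi = (1 − β_EC(1 − θ_CP))/θ_CP = θ_EP/θ_CP. These identities hold to
floating-point precision and are enforced by property tests (relative
1e−12, with λ_P bounded away from the degenerate boundary λ_P = λ_C,
where cancellation makes any fixed absolute tolerance unattainable).

A deliberate subtlety: Psi is defined on *incidences*. The ratio of
averted *counts* A_E/A_C differs from it by the exposure ratio T_C/T_E
(for the packaged HIV-prophylaxis example, 1.0588 vs 1.0627 — both print
as 1.06). The incidence form is used everywhere because it is the one
for which the two parameterisations are algebraically identical; per-arm
predicted and averted counts are reported alongside.

Degenerate and harmful configurations: λ_P ≤ λ_C is a hard error (the
denominator collapses and Psi is undefined); a negative *experimental*
averted count is legitimate (Psi < 0 means the experimental treatment
caused more events than no treatment would have) and is returned with a
warning flag rather than an error.

## Interval estimation

The method behind each interval travels with the result as a tag.

* **`wald_log`** (rate ratio): exp(log β̂ ± z √(1/x_E + 1/x_C)), z the
  exact standard-normal quantile (1.959964 at 95%). Requires ≥ 1 event
  per arm; with a zero count the caller is directed to the exact method.
* **`exact_conditional`** (rate ratio): conditional on n = x_E + x_C,
  x_E ~ Binomial(n, p) with p = β T_E/(β T_E + T_C); the Clopper–Pearson
  interval for p (beta quantiles) is mapped through the odds transform
  and T_C/T_E. Boundaries: lower limit 0 when x_E = 0, upper limit ∞
  when x_C = 0. Tests verify it against an independent bisection
  inversion of the binomial tail probabilities to 1e−8.
* **`delta_log`** (AER, λ_P known): with averted counts A_g,
  Var(log Psi) = x_C/A_C² + x_E/A_E², since ∂ log Psi/∂x_g = ∓1/A_g and
  each count carries its Poisson variance. Requires A_C, A_E > 0.
* **`delta_log`, efficacy mode** (AER, θ_CP known): the implied
  λ_P = λ_C/(1 − θ_CP) is a function of the *random* λ̂_C, so the λ_C
  error partially cancels between numerator and denominator; propagating
  both counts through Psi = (1 − β(1−θ))/θ gives
  Var(log Psi) = [β(1−θ)/(1 − β(1−θ))]² (1/x_E + 1/x_C). Note this is
  *not* the λ_P-mode variance evaluated at the implied λ_P: the coherent
  propagation makes the efficacy-mode variance smaller at the implied
  point (by roughly x_E/x_C for equal exposures), while over a plausible
  *range* of efficacies — which maps onto implied incidences far closer
  to λ_C — efficacy-mode bands are much wider. The packaged sensitivity
  comparison asserts the range-level statement, which is the
  decision-relevant one.
* **`bayes_mc`** (AER): per-arm conjugate posteriors
  λ_g ~ Gamma(x_g + c, T_g/100) with c = 0.5 (Jeffreys) by default; λ_P
  fixed, or drawn from its prior (gamma/lognormal/beta/point families)
  for the unconditional analysis; Psi evaluated per draw; equal-tailed
  credible interval plus posterior mean/median. Draws with λ_P ≤ λ_C are
  *discarded* (not truncated — truncation would bias the quantiles
  invisibly) and the discarded fraction is reported; above 50% the
  counterfactual is declared inconsistent with the data. Default 200 000
  draws keep 2-dp quantiles stable to ~±0.005; the seed is a mandatory
  argument. At the packaged example's counts the fixed-λ_P Bayesian
  interval agrees with the delta interval to < 0.02 on both bounds, and
  a test asserts that agreement for counts ≥ 50 generally.

Interval levels default to 0.95 two-sided, so non-inferiority bounds are
97.5% one-sided limits, matching trial convention.

## Decision rules

Rate-ratio scale: non-inferior iff the upper confidence limit is
*strictly* below the margin (> 1); ties at the margin fail, matching the
strict phrasing used in trial protocols. AER scale: non-inferior iff the
lower interval bound is at least the preservation threshold ∈ (0, 1];
the narrative states the preserved percentage as the 2-dp-rounded lower
bound × 100, the precision at which such bounds are conventionally
reported. The effect-preservation margin for a rate-ratio analysis on
the log-incidence scale is (1/(1 − θ_CP))^(1−f) for preserved fraction
f — e.g. θ_CP ≈ 0.62 and f = 0.5 give the familiar 1.62. The regulatory
relative-efficacy criterion maps the rate-ratio interval (L, U) to
(1 − U, 1 − L) for the head-to-head proportionate reduction 1 − β_EC and
passes iff its lower bound strictly exceeds −10% (configurable floor).
Fragility scans re-run any of these rules with k = 0..K events added to
one arm (person-time unchanged) and report the smallest conclusion-
flipping k.

Default sensitivity grid: 50 evenly spaced λ_P values between 1.05 λ_C
and 4 λ_C (or the corresponding efficacies) when no range is given —
wide enough to show the approach of Psi toward 1 without touching the
degenerate boundary.

## Synthetic trials

`avert.simulate` generates active-control trials under the generative
reading of the model: true arm incidences λ_C = λ_P(1 − θ_CP),
λ_E = λ_P(1 − θ_EP); counts Poisson with mean λ_g T/100; true
Psi = θ_EP/θ_CP. Scenario defaults used in the calibration tests mirror
a realistic HIV-prophylaxis setting: λ_P = 2.0 per 100 PYFU, θ_CP = 0.88,
θ_EP = 0.90, T = 5000 PYFU per arm (expected counts 12 and 10), 2000
replicates — small enough to run in well under a second, large enough
that a 95% coverage estimate has Monte Carlo error ≈ 0.5%. Replicate r
draws from the child stream seeded by (seed, r), so a replicate is
identical whether generated alone or inside a batch. Calibration
excludes replicates where the delta method is inapplicable (observed
control incidence at or above the analysis λ_P, or non-positive
experimental averted count), reports their number, and refuses scenarios
with > 20% such replicates.

What the simulator does *not* emulate — overdispersion, secular incidence
trends, informative dropout, non-adherence — bounds what the passing
tests show: they demonstrate correctness of the estimators under the
package's own Poisson model, not robustness of the AER framework to
real-data violations of it.

## Known limitations

* The counterfactual parameter is an input; nothing here estimates it
  from auxiliary data, and every conclusion is conditional on it (hence
  the sensitivity and Bayesian machinery).
* The delta interval degrades when averted counts are small (it refuses
  non-positive ones); the Bayesian interval is the fallback there.
* The exact conditional interval is conservative by construction
  (Clopper–Pearson); mid-p variants are not implemented.
* Reported person-time is treated as fixed, not random.
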