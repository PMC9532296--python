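# Methods

## Model overview

`flscea` is an individual-level (microsimulation) state-transition model
comparing two secondary fracture-prevention strategies for Chinese patients
aged 65 with a recent fragility fracture: referral to a fracture liaison
service (FLS) versus usual care (no-FLS). Each simulated patient first
passes through a decision tree that fixes, at model entry:

- gender (57.7% female),
- FLS attendance (66% of the FLS arm; the one-off FLS fee, US$200 in the
  base case, is charged to attenders only),
- osteoporosis status, drawn from age/gender-specific prevalence at the
  starting age and never re-evaluated while the patient ages,
- treatment initiation with weekly oral alendronate — only osteoporotic
  patients may initiate; attenders initiate with probability 38%,
  non-attenders and the no-FLS arm with 17.2%,
- adherence class (57% among attender initiators, 34.1% otherwise).

This yields 12 decision-tree pathways in the FLS arm and 6 in the no-FLS
arm. The patient then enters a Markov model with 6-month cycles: from the
"recent fracture" entry state they can sustain incident hip, clinical
vertebral, or wrist fractures (acute "first-year" states lasting two
cycles, followed by site-specific post-fracture states), or die. Death is
absorbing; simulation ends at death or age 100. Lifetime fracture counts
per site are tracked per patient.

## Event probabilities

All published inputs are annual population rates. Per cycle:

- **Fracture.** The general-population incidence i(age, gender, site) is
  split into osteoporotic and non-osteoporotic rates consistent with
  prevalence p and the osteoporosis relative risk R (optionally shrunk by
  an attribution probability a, effective ratio R' = 1 + a(R−1)):
  i_nonOP = i / (1 + p(R'−1)), i_OP = R'·i_nonOP. The result is multiplied
  by the subsequent-fracture relative risk (1.95 women / 3.47 men — every
  simulated patient has a recent fracture; the risk is not escalated
  further by in-simulation fractures) and by the current treatment
  efficacy RR, then converted once: P = 1 − exp(−rate × 0.5). Composing
  all multiplicative adjustments on the rate scale keeps P in [0, 1] for
  any stack of relative risks. At most one incident fracture per cycle,
  with severity priority hip > vertebral > wrist.
- **Death.** Life-table rate, multiplied — after an in-simulation hip or
  clinical vertebral fracture, for the remainder of life — by
  1 + 0.25(RR_excess − 1) (1.2275 women, 1.4975 men; only a quarter of the
  observed post-fracture excess mortality is attributed to the fracture
  itself), then converted to a cycle probability. When an FLS mortality
  odds ratio is configured (sensitivity analyses only), it is applied to
  the FLS arm's cycle probability on the odds scale:
  p' = OR·p / (1 − p + OR·p).

## Treatment

Initiators start therapy at entry, for at most 5 years (10 cycles).
Adherent initiators discontinue according to the published persistence
curve (56% on therapy at 6 months, 50% / 33% / 21% / 12% / 6% at years
1–5, linearly interpolated at 6-month boundaries); the per-cycle
continuation probability is the ratio S(t)/S(t−½). Non-adherent
initiators take exactly one cycle of therapy. This operationalization of
the dichotomous adherence class is a modelling choice (the adherence
mechanism is not otherwise constrained); it separates initiation from
persistence while leaving the published persistence curve intact for
adherent patients.

While on therapy the fracture RRs are 0.67 (hip), 0.45 (vertebral), 0.81
(wrist). After discontinuation the risk reduction wanes linearly to zero
over a period equal to the time spent on therapy; inside the engine the
waning RR is evaluated at the midpoint of each off-treatment cycle, so a
patient treated for a single cycle gets exactly half the reduction in the
one offset cycle that follows (evaluating at cycle start would grant a
full extra cycle of efficacy).

On-treatment cycle cost = 6-month drug cost (392.31) + amortized
monitoring (one GP visit/year and one DXA/2 years, charged as GP/2 and
DXA/4 per cycle — expectation-equivalent to lump sums and smoother for
short-horizon validation) + expected side-effect GP consultations (0.041
visits in the first cycle, 0.021 thereafter). Costs stop at
discontinuation; there is no re-initiation.

## Payoffs

- **Utility** (multiplicative): baseline 0.70 for the fracture population,
  times the first-year multiplier of the most recent fracture site during
  its two acute cycles (hip 0.55, vertebral 0.68, wrist 0.83), otherwise
  the *worst* subsequent-years multiplier over all sites ever fractured
  in-simulation (hip 0.86, vertebral 0.85, wrist 0.99). The worst-state
  rule avoids implausible permanent compounding of the near-unity wrist
  multiplier; a multiplicative rule is available via
  `conventions.longterm_utility_rule`. Cycle QALY = utility × 0.5 years.
- **Costs**: each incident fracture charges its full first-year cost
  (hip 11,166; vertebral 6,328; wrist 2,162; US$2020) split over the two
  acute cycles. The first hip fracture triggers nursing-home entry with
  probability 0.05; residents accrue half the annual long-term cost
  (4,799) every cycle after the acute phase, until death, paused during
  later acute hip cycles to avoid double counting. The index (baseline)
  fracture incurs no cost and no extra disutility: the 0.70 baseline
  utility already reflects it, and accounting starts with subsequent
  fractures.
- **Discounting**: 5%/year for costs and QALYs, annual compounding at the
  cycle-start time, df(t) = 1.05^(−t).
- **Cycle order**: death draw → fracture draw (survivors) → state update →
  payoff accrual → treatment-state update. A patient who dies within a
  cycle accrues that cycle's full half-year utility payoff and no costs
  (`conventions.death_cycle_payoff` switches to a half-payoff mid-cycle
  approximation). Both conventions are approximations of in-cycle event
  timing; incremental results between arms are insensitive to the choice.

## Outcomes

Per-arm means of discounted lifetime cost and QALYs, their per-patient
standard errors, and lifetime fracture counts per 100 patients. The ICER
is ΔC/ΔQ, labelled *dominant* (ΔC < 0, ΔQ > 0) or *dominated* (ΔC > 0,
ΔQ < 0). Because the fee is charged once at entry (discount factor 1) to
attenders only, ΔC is exactly linear in the fee with slope a/f₀, where a
is the realized mean fee burden per FLS-arm patient. The maximum
cost-saving fee solves ΔC(f) = 0 and the maximum cost-effective fee solves
ΔC(f) = WTP·ΔQ at WTP = US$10,500/QALY; both are solved in closed form
from one base run and confirmed by a same-seed rerun (which reproduces the
linear solve to floating-point precision under common random numbers).

## Random numbers and reproducibility

All randomness derives from one integer seed via `numpy` `SeedSequence`
spawning: one stream of six per-patient uniforms (gender, attendance,
osteoporosis, initiation, adherence, nursing-home entry) and five
per-cycle streams (death, one per fracture site, persistence). Both arms
— and all scenarios of a sensitivity analysis — consume identical
uniforms against different thresholds (common random numbers), so
incremental outcomes are variance-reduced, identical configurations give
identical arms patient-by-patient, and reruns are bit-for-bit
reproducible. The engine is vectorized across patients; per-cycle draws
are consumed in a fixed order regardless of survival so streams never
desynchronize.

## Validation oracle

`cohort_oracle` computes the *exact* expected discounted cost and QALY per
patient by exhaustive enumeration of the reachable state space (treatment
state × acute state × fracture-history set × excess-mortality flag ×
nursing-home flag), mixed over pathways and adherence classes. It shares
the per-cycle probabilities and payoff formulas with the engine but
replaces sampling with expectation propagation; state growth restricts it
to ≤ 8 cycles. The test suite checks the Monte-Carlo engine against the
oracle (4-SE bands), against closed-form survival sums with fractures
disabled (10⁻¹² agreement), and against a fully hand-computed two-cycle
single-site chain.

## Sensitivity analysis

`table2_scenarios()` builds the one-way grid: 8 FLS-related rows (fee
+100%/+200%; mortality OR 0.73/0.876; attendance and FLS adherence ±20
absolute percentage points) and 23 other rows (starting age 60/70/75/80;
women 80%/100%/0%; nursing-home proportion +100%/−50%; osteoporosis
prevalence +20%/+40% multiplicative, capped at 100%; nursing, fracture and
drug costs ±50%; baseline utility ±20%; efficacy ±20% — interpreted as
scaling the risk *reduction* 1−RR, keeping RR ≤ 1; discount 3%/0%). Two
further rows (FLS initiation halved/doubled) are available via
`include_initiation=True`. Age tables extend their first published band
down to age 60 so the age-60 scenario is covered, mirroring the convention
used for the osteoporosis relative risk at ages 60–64.

`perturbed_parameters(rng, spread)` multiplies every positive scalar by an
independent factor in [1−spread, 1+spread], clipping probabilities to
[0, 1], relative risks to ≥ 1, and utilities to (0, 1]; order-coupled
quantities (the persistence curve; each site's first/subsequent utility
pair) share a common factor so monotonicity invariants survive. Draws are
re-validated against the full schema.

## Problem sizes

Published analyses of this kind run 10⁶ trials per arm. The default CLI
sample is 10⁵ patients per arm and the bundled acceptance script uses
2×10⁵, chosen so that base-case incremental standard errors (≈ US$0.7 for
ΔC, ≈ 0.0001 QALY for ΔQ under common random numbers at 2×10⁵) are far
below the effect sizes of interest; `--n` scales this freely.

## What the generated data does and does not show

All inputs are parameter tables; no patient-level data exists. The
perturbation generator exercises schema validity and engine robustness,
not real-world parameter correlation (draws are independent). Passing
tests demonstrate internal correctness — exact oracle agreement, closed
forms, reproducibility, and directional behaviour of the sensitivity grid
— under the stated structural conventions; they cannot establish that
those conventions match any particular external implementation, nor that
the parameter tables describe any real cohort.

## Known limitations

- Treatment is initiated at most once, at entry; no re-initiation after
  subsequent fractures, no drug switching, no side-effect disutility.
- Excess mortality does not stack across multiple fractures and, by
  default, never expires (a fixed-duration variant is configurable in the
  engine; the enumeration oracle supports only the lifetime default).
- Osteoporosis attribution probabilities default to 1 (no adjustment); the
  schema accepts full site×age×gender tables when they are available.
- The wrist incidence table is taken as already adjusted for an Asian
  population; `risk.wrist_asian_adjustment` exposes the factor.
- No probabilistic sensitivity analysis and no budget-impact or
  per-baseline-fracture-type analyses.
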