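# Methods

## Scope and data-generating assumptions

The package models the lifetime cost-effectiveness of a six-month
telephone-coaching program for type 2 diabetes, evaluated in an 18-month
two-arm randomized trial (287 patients per arm, Belgian primary care,
claims-based costing). The real patient-level data are private, so every
analysis runs on synthetic cohorts whose *marginal* structure matches the
published trial summaries:

- **Continuous risk factors** (HbA1c, total and HDL cholesterol, systolic
  blood pressure, BMI) are truncated normals matched to the per-arm,
  per-visit means and SDs, truncated at physiologic bounds (HbA1c 4–15%,
  SBP 80–220 mmHg, total cholesterol 50–400 mg/dl, HDL 10–150 mg/dl,
  BMI 15–60 kg/m²). Bounds were chosen wide enough that the truncation bias
  on means/SDs stays below ~2% of an SD. Visits are linked by a Gaussian
  copula with AR(1) latent correlation ρ = 0.7 (configurable); the trial
  publishes no within-patient correlation, so ρ is a modelling choice, not
  a claim about the data.
- **Age** uses the published per-arm medians as truncated-normal location
  parameters (SD 8 y, bounds 35–75 y per the recruitment range); the
  realized median sits slightly below the location because of the upper
  bound. **Diabetes duration** is gamma distributed (mean 7 y, SD 5.2 y),
  which keeps the mean exact, respects positivity, and reproduces the
  published duration bands (~15% ≤ 2 y, ~30% ≥ 10 y).
- **Claims costs** (ambulatory/hospital × baseline/trial year) are
  lognormal, with per-patient SDs backed out of the published means' 95%
  CIs (normal approximation at n = 287) — right-skewed, as claims data are.
  Baseline and trial-year costs share a Gaussian copula (ρ = 0.7);
  ambulatory and hospital categories are drawn independently because no
  joint information is published.
- **Smoking** uses one latent uniform per patient against declining
  per-visit prevalences, so quitting is monotone. **Comorbidity flags**
  (IHD, MI, heart failure, stroke) are independent Bernoulli draws at the
  published prevalences; the joint distribution is not published.
- **Dropout** is injected completely at random per follow-up visit at the
  trial's loss-to-follow-up rates (intervention 11%/16%, control 9%/14%)
  and repaired by single conditional-mean imputation under a multivariate
  normal fitted per arm to the complete records — the same scheme the
  trial analysis used. The dropout mechanism in the real trial is unknown;
  MCAR is the neutral default.

What passing tests on these cohorts demonstrate: the estimators,
simulation and accrual arithmetic are correct under a known
data-generating process with the published first and second moments. What
they do not demonstrate: anything about the real joint distribution of
risk factors and costs, informative dropout, or the true treatment effect.

## Risk engine

Seven complications plus all-cause death are simulated in annual cycles.
Endpoint probabilities follow
`p = 1 − exp(−[H(t+1) − H(t)] · exp(x'β))` with constant, Weibull or
Gompertz integrated baseline hazards on the diabetes-duration time scale.
Within a cycle, endpoints are evaluated in the fixed order IHD, MI, heart
failure, stroke, amputation, blindness, ESRD, then death, with independent
draws; several first events may occur in one cycle. This ordering is a
package convention (the licensed outcomes model's event-sequencing
algorithm is not reproduced here) and is isolated in one kernel. Each
event may be fatal with a per-endpoint split probability (zero for IHD and
blindness, which have no priced fatal form). Flags are monotone and feed
the *next* cycle's linear predictors. Two uniforms per endpoint per cycle
(occurrence, fatality) plus one for death are drawn unconditionally, so
parameter scenarios on the same seed share common random numbers.

Risk factors are read from deterministic per-patient trajectories: years
0–2 are the observed visits; beyond year 2 a policy applies — `hold_last`
(base case) carries the 18-month value forward; `converge_to_control`
replaces the intervention trajectory with the control-arm mean path (the
effect vanishes); `maintain_difference` preserves the patient's year-2
offset from that path. With a flat (held-last) control reference the
`maintain_difference` and `hold_last` trajectories coincide by
construction; the policies differ whenever a drifting reference path is
supplied.

The published fitted coefficients of the UKPDS Outcomes Model are not
redistributable, so the default `CoefficientSet` is **illustrative**: the
same functional form, plausible effect directions (positive slopes for
age, HbA1c, SBP, smoking, prior events; negative for HDL), with baseline
scales anchored so the reference patient (age 65, 7 y duration, HbA1c 7%)
has annual endpoint hazards on the scale of published 40-year cumulative
event rates and — after numeric calibration of the death scale to 0.035 —
an undiscounted life expectancy of ≈10 years. Any coefficient set can be
loaded from JSON; all validation and tests are coefficient-agnostic.

## Economics

Per alive year: base annual cost €3,921 (diabetes without complications);
a new complication adds its acute event-year cost (fatal acute cost if
fatal); each established complication adds its subsequent-year cost; ESRD
and blindness carry the same amount in both columns, so they effectively
cost their annual amount every year from the event on. Utilities start at
0.785 and subtract event-year/subsequent-year decrements additively, with
an optional floor (default none; the theoretical EQ-5D minimum is −0.59).
Base cost continuing through event years is the default additive reading
of complication-specific costs on top of uncomplicated care; a switch
(`base_cost_in_event_years`) turns it off for sensitivity.

Half-cycle convention: recurring amounts (base cost, subsequent-year
costs, utility) are weighted 0.5 in the death year; one-off acute event
costs accrue in full. Costs discount at 3.0%, QALYs at 1.5% (differential
discounting per Belgian guidance), year 0 undiscounted.

## Trial costing

The within-trial incremental cost uses ambulatory claims only (the trial's
hospitalization swings are chance-confoundable) and adjusts each patient's
trial-year cost by `−β(HC1 − pooled mean)`, with β from a single pooled
OLS of trial-year on baseline cost. A pooled β keeps the adjustment
symmetric across arms; per-arm slopes would break the stated formula.
The program cost divides the prospective ledger (recruitment €3,900, fixed
€3,790, variable €273.5/patient) over the 287 enrolled: €300.3 per patient
operational. One-off set-up investment (€39,275) is excluded from the base
case and spread over a configurable allocation size in scenarios. Money is
reported at €0.1 (investment at cents), percents at one decimal; internal
computation is unrounded.

## CEA and uncertainty

The incremental cost sums three components: modelled long-term difference,
within-trial increment, and the (discounted) program cost contribution.
ICER = mean ΔC / mean ΔE with dominance handling (cost-saving → dominant,
no negative ratio reported; ΔE ≤ 0 → dominated/undefined, flagged).

**Bootstrap PSA** (default 999 replicates) resamples patients with
replacement *within arm*, preserving arm sizes, and recomputes the model
means and the baseline-adjustment regression per replicate. Per-patient
expected outcomes are computed once from patient-indexed seed streams and
cached; since those streams are fixed, reusing them inside the bootstrap
is byte-identical to re-running the simulation per replicate. CIs are
2.5/97.5 percentiles of the cloud. The crude ratio-of-CI-bounds ICER
interval (lower = ΔC_lo/ΔE_hi, upper = ΔC_hi/ΔE_lo) is reported alongside
the percentile interval because the two must be distinguishable in output;
the ratio-of-bounds form is statistically naive and should not be the
primary interval. A second mode resamples economic parameters (base cost
and baseline utility from their 95% CIs; complication costs and decrements
at 10% relative SE) over fixed histories, for users who read "probability
samples" as parameter uncertainty; patient resampling is the default.

**Horizon sweep**: one full-horizon simulation, truncated prefix sums of
the discounted streams at 1, 2, 5, …, 40 years, so every horizon shares
the same draws. **Scenarios**: program cost ±50%, complication costs ±50%,
utility decrements ±20% (the decrement sources' own CIs are not published
with the parameter table, so a symmetric 20% band is the documented
fallback; supply bounds via a custom `EconParameters` to override),
discounting 0%/5%, effect vanishing vs lifetime persistence, and bi-annual
program re-delivery for 20 years (deliveries at years 0, 2, …, 18,
discounted at the cost rate, under `maintain_difference`). All scenarios
run on one seed (common random numbers).

## Problem sizes and numerical choices

Default runs use 287 patients per arm, 20 inner replicates per patient, a
40-year horizon and 999 bootstrap replicates; the test suite uses smaller
cohorts (50–200 per arm) for pipeline behaviour and large n (4,000–10,000)
where closed-form oracles need Monte Carlo precision — sizes chosen so the
statistical checks have the power they claim. Imputation adds a 1e-12
ridge before solving the observed-block covariance system; stochastic
tests are seeded; money comparisons in tests use the report rounding
stated above.

## Known limitations

- The default coefficient set is illustrative. Absolute event rates, life
  expectancy and headline ICERs computed with it characterize the
  machinery, not the intervention; with 574 synthetic patients the QALY
  increment is smaller than between-arm sampling noise, so its sign
  depends on the cohort seed and the bootstrap CI spans zero.
- Endpoint draws are independent within a cycle given the state; no
  within-cycle event sequencing or correlated shocks.
- Risk-factor trajectories are deterministic given the policy; trajectory
  uncertainty enters only through the PSA and policy scenarios.
- No indirect/non-medical costs, no inflation adjustment (inputs are
  treated as same-year euros), no second-generation outcome-model
  equations.
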