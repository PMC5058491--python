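# telecoach-cea

Lifetime cost-effectiveness analysis of nurse-led telephone self-management
support ("telecoaching") for people with type 2 diabetes, from a healthcare
payer's perspective. The package is aimed at health economists and
biostatisticians who want a fully seeded, testable implementation of the
trial-to-lifetime modelling chain: an 18-month randomized trial measured
risk factors (HbA1c, blood pressure, cholesterol, smoking, BMI) at three
visits in two arms of 287 patients; a patient-level microsimulation then
extrapolates those measurements over 40 annual cycles to estimate
incremental costs, quality-adjusted life years (QALYs) and the incremental
cost-effectiveness ratio (ICER).

## The model

Each patient is simulated year by year over seven diabetes complications —
ischemic heart disease, myocardial infarction, heart failure, stroke,
amputation, blindness, end-stage renal disease — plus all-cause death. The
annual probability of endpoint *j* follows a proportional-hazards form

    p_j = 1 − exp( −[H_j(t+1) − H_j(t)] · exp(x'β_j) ),

where `H_j` is the integrated baseline hazard of a constant, Weibull or
Gompertz family on the diabetes-duration time scale and `x` holds the
current risk factors and prior-event flags. Events can be fatal with a
per-endpoint split; flags feed the following year's equations; events fall
mid-cycle, so the death year counts half a life-year.

Economics: every alive year accrues a base annual diabetes cost (€3,921);
complications add acute event-year costs and subsequent-year costs, and
subtract event-year and subsequent-year utility decrements from the EQ-5D
baseline utility (0.785). Costs are discounted at 3.0% per year, QALYs at
1.5%. The incremental cost is a three-part sum: modelled long-term cost
difference + within-trial incremental ambulatory cost (regression-adjusted
for baseline imbalance, `HC2_adj = HC2 − β(HC1 − mean HC1)`) + the
per-patient program cost (€300.3 from the program's ledger). Finally

    ICER = ΔC / ΔE  (€ per QALY),

with uncertainty from a 999-replicate patient-level bootstrap (CE plane,
acceptability curves, probability of cost saving), a time-horizon sweep,
and one-way scenarios (program/complication costs ±50%, utility-decrement
bounds, 0%/5% discounting, trial effect vanishing vs persisting, bi-annual
program repetition for 20 years).

Because the trial's claims data are private and the fitted risk-equation
coefficients of the licensed outcomes model are not redistributable, the
package ships (a) a synthetic-cohort generator that reproduces the trial's
published per-arm moments, cost distributions and dropout rates, and (b) a
clearly labelled *illustrative* coefficient set with the same functional
form, calibrated to a ~10-year life expectancy for the reference patient.
Any coefficient set can be supplied as JSON.

## Worked example

```python
import telecoach_cea as tc

spec = tc.default_cohort_spec(seed=1)              # two arms of 287
cohort = tc.generate_cohort(spec)
cohort = tc.inject_and_impute_missing(cohort, tc.DEFAULT_MISSINGNESS, seed=2)

program = tc.per_patient_program_cost(tc.default_program_cost_model())
print(f"program cost per patient: EUR {program.operational:.1f}")

config = tc.PipelineConfig(coeffs=tc.default_coefficient_set(),
                           econ=tc.default_econ_parameters(),
                           horizon=40, replicates=20,
                           program_cost_per_patient=program.operational)
result = tc.run_pipeline(cohort, config, seed=3)
print(result.arm_means().round(2))
inc = result.increments()
print(f"delta cost: EUR {inc['delta_cost']:.0f}   delta QALY: {inc['delta_qaly']:.3f}")

psa = tc.bootstrap_psa(cohort, config, n_bootstrap=999, seed=4, result=result)
print(f"95% CI delta QALY: ({psa.delta_qaly_ci[0]:.2f}, {psa.delta_qaly_ci[1]:.2f})")
```

prints

```
program cost per patient: EUR 300.3
                  cost  qaly  life_years
intervention  60003.68  6.91       10.15
control       59854.13  6.97       10.24
delta cost: EUR 1103   delta QALY: -0.061
95% CI delta QALY: (-0.48, 0.33)
```

Reading the output: both arms live ~10 years and accrue ~€60,000 of
discounted lifetime cost; the cost increment (€1,103) is dominated by the
front-loaded within-trial and program costs. Under the illustrative
equations the QALY gain of a 574-person cohort is far smaller than the
between-arm sampling noise — the bootstrap CI spans zero, and the point
estimate's sign flips with the cohort seed. This is the expected behaviour
of the machinery at trial scale, not a defect: resolving the effect is
precisely what the original lifetime model with its fitted equations and
real patient data was needed for.

The same analysis is available from the shell:

```
telecoach-cea synth --seed 1 --out cohort.csv
telecoach-cea run --cohort cohort.csv --seed 3 --outdir results/
telecoach-cea psa --cohort cohort.csv --seed 4 --mode parameters --outdir psa/
```

`run` writes the full bundle — base case and elevated-HbA1c subgroup
(baseline HbA1c ≥ 7%), horizon sweep, CE-plane cloud, CEAC table and the
scenario (tornado) table — plus a `config.json` echo so every file is
reproducible from the seed alone.

## Layout

- `src/telecoach_cea/cohort.py` — synthetic two-arm cohorts, missing-data
  injection and conditional-mean imputation, subgroup filter
- `src/telecoach_cea/engine.py` — hazard equations, trajectory policies,
  annual-cycle Monte Carlo
- `src/telecoach_cea/econ.py` — costs, utilities, discounting, accrual
- `src/telecoach_cea/costing.py` — baseline-adjusted within-trial costs,
  program ledger, percent changes
- `src/telecoach_cea/cea.py` — ICER, bootstrap PSA, CEAC, horizon sweep,
  scenarios
- `src/telecoach_cea/defaults.py` — published parameter defaults and the
  illustrative coefficient set
- `docs/methods.md` — modelling assumptions, numerical choices, limitations
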