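# ssbsim

Individual-level microsimulation of a workplace **sugar-sweetened beverage
(SSB) sales ban** among health-care employees: chronic-disease incidence and
mortality, quality-adjusted life-years (QALYs), health-care and productivity
costs under employer (10-year) and health-care (lifetime) perspectives, and
the sales-loss / break-even sensitivity analyses an employer would run
before adopting such a policy.

The package is aimed at health-economics and policy-modeling analysts.  It
ships no survey microdata: a configuration-driven synthetic-population
module and a calibrated "world" builder reproduce the statistical structure
the analysis assumes (demographic margins, baseline prevalences, effect
sizes, cost and utility levels).

## Model

Simulated employees carry age, sex, race/ethnicity, occupational class,
insurance, BMI, habitual SSB intake (oz/day), and prevalent-state flags for
six outcomes: obesity (BMI ≥ 30), coronary heart disease, cerebrovascular
accident, type 2 diabetes, chronic kidney disease, and dental disease.
Each annual cycle applies, in order: other-cause mortality, cause-specific
mortality among prevalent cases, disease incidence among survivors,
employment transitions (attrition, retirement at 65), aging.  States are
absorbing.

The ban shifts each person's consumption by a population-mean reduction
Δ (oz/person/day), sampled per Monte Carlo replicate from the survey
estimate Δ ~ N(1.5, σ) truncated at 0 (95% CI 0.7–2.4), capped at the
person's baseline intake.  Per-outcome relative risks standardized at the
1.5 oz/day reference rescale log-linearly,

    RR_k(δ) = RR_k^(δ / 1.5),

and act on three channels while the person is exposed (employed): incidence,
cause-specific mortality, and the annual cost/disutility *burden* of a
prevalent case (a severity/management-intensity dose response; see
`docs/methods.md`).  Ban and control arms share identical random streams
(common random numbers), so their difference isolates the intervention.

A person-year's QALY weight is an age-declining baseline utility minus the
disutilities of active conditions (obesity via a BMI-band table), floored
at zero, half-cycle in the year of death.  Costs comprise per-condition
health-care spending (employer share while enrolled and under 65;
employee/public payers otherwise, including post-retirement Medicare),
productivity losses while employed, and a one-time premature-death
productivity cost.  Dollars are constant December-2019 USD; QALY and dollar
differences are discounted at 3%/year.

## Worked example

```python
from ssbsim import SSBBanModel, build_calibrated_world

world = build_calibrated_world()          # calibrated input bundle
model = SSBBanModel(world, n_persons=10_000, n_replicates=10)
results = model.fit(seed=11)
print(results.summary())
```

```
Workplace SSB sales-ban microsimulation
================================================================
persons/replicate:   10,000    replicates: 10
mean reduction draw: 1.47 oz/person/day

Baseline (no ban), per 10,000:
  employer 10y:        62,871 QALYs   $    28,016,985 costs
  healthcare lifetime:  205,569 QALYs   $   154,754,403 costs

Intervention effect (ban vs control), per 10,000 (discounted):
  employer 10y:       78.4 QALYs saved   $     325,449 saved
  healthcare lifetime:  331.6 QALYs saved   $     186,738 saved

Incidence+mortality reductions (10y): obesity 1.2%, chd 2.3%, cva 0.9%,
diabetes 3.7%, ckd 2.5%, dental 2.7%, other_mortality 2.1%
```

Reading the output: with no ban, 10,000 employees accrue ~62,900 QALYs and
~$28M of attributable employer-perspective costs over ten years.  The ban
(a ~1.5 oz/day mean consumption reduction) averts roughly 1–4% of new cases
per outcome, saving ~78 discounted QALYs and ~$325k per 10,000 employees
over ten years (estimates at 10 replicates carry a few percent of Monte
Carlo noise).  Sensitivity analyses hang off the same results object; at
this run's seed they print:

```python
results.sales_loss(no_offset=True)
# {'loss': 503882, 'ci_lo': 323563, 'ci_hi': 657638}   USD per 10,000 / 10y
results.icer_no_offset()
# {'icer': 2276, 'ci_lo': -484, 'ci_hi': 9230}         USD per QALY saved
results.breakeven()      # ~2.4 oz/day reduction for employer cost-neutrality
```

A command-line interface wraps the same pipeline:

```bash
ssbsim fixtures configs/                      # emit fixture + calibrated configs
ssbsim simulate --config configs/calibrated_run.yaml
ssbsim breakeven --world configs/calibrated_world --output out/ --replicates 20
ssbsim validate-config configs/calibrated_run.yaml
```

## Layout

- `ssbsim.population` — synthetic employee populations (config-driven)
- `ssbsim.intervention` — effect-size distribution, log-linear RR scaling
- `ssbsim.engine` — vectorized annual-cycle microsimulation, CRN pairing
- `ssbsim.economics` — utilities, costs, discounting, result aggregation
- `ssbsim.sensitivity` — sales losses, ICER, break-even bisection
- `ssbsim.expectation` — deterministic cohort-expectation model (calibration)
- `ssbsim.calibration` — target-driven world building, perturbation harness
- `ssbsim.model` — `SSBBanModel` / `SSBBanResults` facade
- `ssbsim.reporting`, `ssbsim.cli` — end-to-end runs, exhibits, CLI
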