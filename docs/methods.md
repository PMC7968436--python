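# Methods

## Model structure

The simulation is an individual-level annual-cycle state-transition model
of employed adults (16+) in large health-care organizations.  Each person
carries demographics, BMI, habitual SSB consumption, and absorbing
prevalent-state flags for six chronic outcomes: obesity, coronary heart
disease (CHD), cerebrovascular accident (CVA), type 2 diabetes, chronic
kidney disease (CKD), and dental disease.  Event order within a cycle is
fixed — (1) other-cause mortality, (2) cause-specific mortality among
prevalent cases (in the canonical outcome order), (3) incidence among
survivors, (4) employment transitions, (5) aging — with an age cap of 110.
There is no half-cycle correction in the state dynamics; instead the year
of death contributes half a cycle of QALYs and costs at the start-of-year
state.  Rates supplied as hazards are converted with p = 1 − exp(−r).

The cohort is closed: no replacement hires enter after policy start.  A
person leaves the employer plan by retirement (age 65) or by an annual
attrition draw; they remain simulated (health-care perspective) but stop
accruing employer-paid costs, productivity losses, and intervention
exposure.

## Intervention

The ban's effectiveness is a population-mean consumption reduction Δ
(oz/person/day) with mean 1.5 and 95% CI 0.7–2.4, interpreted from the
survey's sign convention as a reduction.  Each Monte Carlo replicate draws
one Δ (normal on the reduction scale, truncated at zero, σ = CI width /
(2·1.96)) as parameter uncertainty; within a replicate each person's
realized reduction is min(Δ, baseline intake).  Per-outcome relative risks
standardized at the 1.5 oz/day reference are rescaled to other doses
log-linearly, RR(δ) = RR_ref^(δ/1.5) — the conventional multiplicative
form, which keeps RR positive and is exact at the reference.

Effects act through three channels while a person is exposed (employed):

- **incidence** — annual incidence × RR;
- **mortality** — cause-specific mortality among prevalent cases × RR,
  plus a direct RR on other-cause (background) mortality;
- **burden** — the annual cost and disutility of an *existing* prevalent
  case scale with exposure (RR^β on costs, RR^β_q on disutility, with
  severity-response exponents β, β_q ∈ [0,1] shared across outcomes).

The burden channel represents severity/management-intensity dose response
(e.g. glycemic control, caries activity, weight-related symptom load
responding to sugar intake even though the diagnostic state persists).  It
is required by the published decompositions this model reproduces: with
incidence-only effects, a condition held by ~96% of the population (dental
disease) could never contribute a third of employer savings, and extended
longevity would make lifetime "savings" negative.  Averted states persist
after exposure ends; the burden and mortality effects revert to null at
employment exit.

Ban and control arms run under common random numbers: every cycle draws
fixed-shape uniform blocks for all persons in a fixed order, so arms from
the same seed consume identical streams and their difference isolates the
intervention.

## Valuation

QALY weight of an alive person-year: age-declining baseline utility
u(a) = u0 − s·(a − 40) minus the disutilities of active conditions
(obesity via a BMI-band table: 30–35, 35–40, 40+), floored at zero, with
the floor's shortfall attributed proportionally across conditions so the
per-outcome decomposition still sums exactly.  The age slope mirrors
population-norm utility decline (EQ-5D norms fall roughly 0.003–0.004 per
year of adult age) and carries the published decline in QALYs per
person-year (0.63 over ten years → 0.54 over the lifetime) without
requiring implausible disease disutilities.

Costs per prevalent condition-year: health-care spending with separate
working-age and post-retirement levels (care intensity for stroke, kidney
disease etc. concentrates in old age); the employer pays its share while
the person is enrolled and under 65, employee/public payers otherwise
(including post-retirement Medicare).  Productivity costs (absenteeism,
presenteeism, disability) accrue only while employed; a one-time
premature-death productivity cost applies to deaths from modeled causes
before retirement age.  All dollars are constant December-2019 USD (CPI
factors applied to cost tables at load time); QALY and cost *differences*
are discounted at 3%/year.  Baseline QALY totals are reported undiscounted,
matching the convention of the published totals they are calibrated to
(which equal undiscounted person-years times the published per-year ratios).

Perspectives: **employer** = employer share of health costs + all
productivity channels, 10-year horizon; **health-care** = all payers'
health costs, no productivity channels, lifetime horizon.  Results are
normalized per 10,000 persons at reporting time.  Point estimates are
replicate means; 95% CIs are 2.5/97.5 percentiles over replicates.

## Sensitivity analyses

Base case: lost SSB revenue is fully offset by compensatory non-SSB sales
(offset fraction 1.0, loss 0).  The pessimistic scenario sets the offset to
zero: annual loss per person = min(Δ, at-work ounces) × price/oz × employer
profit share × workdays, accrued while employed, discounted over the
employer horizon.  Because at-work purchases are a small fraction of daily
intake (calibrated work fraction ≈ 0.1, at-work mean ≈ 1.3 oz/day), the
loss curve saturates near the observed reduction — which is what makes a
break-even reduction above the observed effect size possible at all.  The
ICER divides net cost (loss − averted spending) by QALYs saved; negative
values mean the ban dominates.  Replicate-level sales losses carry a
lognormal revenue-parameter factor (CV 0.25) reflecting price/profit
uncertainty.

The break-even search rescans the model at forced reduction levels under
fixed CRN seeds.  The mean savings-minus-loss curve is then a deterministic
(piecewise-constant) function of the dose; bisection narrows the bracket
and the root is interpolated within it, so the reported savings and loss
at the root agree within the $100 tolerance.  Per-replicate roots,
interpolated over the evaluated grid, give the CI.

## The synthetic world and its calibration

No external microdata are used.  `build_calibrated_world` constructs
every input from published summary targets in documented stages:

1. **Demographics** directly from published margins: piecewise-uniform ages
   with quartiles at 28 and 52 (mean ≈ 40.9), 51.7% male, published
   race/ethnicity and occupational-class fractions (the Asian and white
   fractions, not published, are assumed at 18.1%/54.0%), insurance coverage
   0.92 (assumed), published baseline prevalences, truncated-lognormal BMI
   fitted so P(BMI ≥ 30) equals obesity prevalence, gamma SSB intake with
   mean 11.7 oz/day and shape 1.2.
2. **Background mortality**: Gompertz with slope 0.085/year, level solved
   so expected remaining life-years match the lifetime person-year total
   implied by the published QALY figures (≈ 38 years at mean age 40.8).
3. **Effect sizes**: per-outcome RR at the reference solved (two passes,
   absorbing competing-mortality interactions) so the simulated ten-year
   incidence+mortality reductions equal the published percentages exactly;
   the solve inverts the dose-cap and employment-exposure dilution.
4. **Costs**: solved exactly from the two published baseline cost
   decompositions — working-age health cost and productivity cost per
   condition from the employer-perspective shares (preset productivity
   fractions split each condition's employer burden; obesity and dental
   disease are productivity-heavy), post-retirement health cost from the
   lifetime all-payer shares.  Premature-death cost fixed at $30,000.
5. **Cost burden exponent β** solved against the published ten-year
   employer savings total.
6. **Utilities**: u0, the age slope, and the six disutilities solved by
   SLSQP with the two baseline QALY totals as equality constraints, the
   ten-year QALY savings as an upper bound, weak priors at
   utility-literature magnitudes, and the lifetime savings target as a
   soft objective.
7. **Simulator refinement**: the algebra above uses the deterministic
   cohort-expectation model (conditional independence of flags, no utility
   floor), which is ~1–2% biased against the Monte Carlo engine; two passes
   of control-arm simulation runs (10,000 persons × 12, then × 36) rescale
   utility and cost levels so the engine itself reproduces the four
   baseline totals to within ~0.1–0.4%.
8. **Disutility burden exponent β_q** solved against the ten-year QALYs
   saved; **sales parameters** (work fraction, price scale) fitted to the
   published sales-loss and break-even figures.

Structural constants the targets do not identify are fixed, documented
choices (`StructuralAssumptions`): incidence levels at age 45 with mild
working-age gradients and a steep common post-retirement gradient
(0.15/yr), age-graded case fatality for CHD/CVA/diabetes/CKD, attrition
3%/yr, employer cost share 0.80, retirement at 65.  Incidence levels are
deliberately low: the baseline constraints otherwise force ten-year QALY
savings above the published value for *any* admissible utility parameters
(a linear-programming check of the feasible range is part of the design
history), because averted-case persistence and longevity channels are
strong under absorbing states.

### What the calibration does and does not reproduce

Fitted within a few percent (microsimulation at 10,000 × 50): both baseline
QALY totals, both baseline cost totals and their published decompositions,
all seven incidence+mortality reduction percentages, ten-year QALYs and
dollars saved, the uncompensated sales loss, the ICER, and the break-even
reduction (model ≈ 2.3–2.4 vs 2.2 published, inside the published CI).

**Not reproduced, by structure**: the lifetime intervention totals
(≈ 330 vs 1,069 QALYs; ≈ $0.2–0.3M vs $0.71M per 10,000).  Their
published lifetime/ten-year ratios (~13.6× for QALYs) require the
consumption effect to keep acting long after employment ends; with exposure
ending at employment exit — the reading this package adopts, since the ban
is a workplace policy — no admissible parameter set reaches them while
simultaneously matching the ten-year figures.  The savings decomposition
*shares* (e.g. obesity's 56.6% of employer savings against a 1.0% incidence
reduction) are likewise jointly over-determined with the baseline shares
and are matched only loosely.  The calibration report stored in the world
metadata records every residual, with the unattainable targets flagged.

### What the generator does not emulate

Cross-condition correlation beyond age/sex (flags are conditionally
independent given age band and sex unless a conditional table is supplied);
secular trends in prevalence, costs, or wages; BMI trajectories (obesity is
a state, with incident cases assigned BMI 32); disease-severity staging;
new workforce entrants; and any claim of recovering the true survey joint
distributions.  Passing tests therefore demonstrate that the method
machinery is correct and that the calibrated world reproduces the published
summary structure — not that the parameters are externally valid estimates.

## Numerical choices

Annual probabilities clipped to [0,1]; age bands must partition [16, 110).
Sampling uses numpy PCG64 generators; paired runs derive per-replicate
child seeds (population, parameter draw, event stream) from the root seed,
and both arms re-create the identical event generator.  Bisection
tolerances: $100 (break-even), 5×10⁻³ oz bracket width.  Degenerate inputs
(zero-variance effect, single-person populations, empty category rows) are
exercised in the test suite.  Problem sizes for the shipped analyses —
10,000 persons × 50 replicates, with 20-replicate break-even scans — keep a
full reproduction to a few minutes on one CPU while leaving Monte Carlo
standard errors of the headline quantities at the few-percent level; the
quantitative acceptance checks account for that sampling error explicitly.

## Known limitations

Conditional-independence of comorbidities understates clustering of
cardiometabolic disease; the burden channel applies one global severity
exponent per value domain rather than outcome-specific dose responses; the
employer cost share, attrition, and sales parameters are single numbers
rather than distributions (only the revenue factor and the effect size are
sampled per replicate); and the lifetime perspective inherits the
structural shortfall described above.
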