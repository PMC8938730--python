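# Methods

## Model structure

`segsim` implements a discrete-time, individual-level state-transition
model (microsimulation) of hypertension in the healthcare workforce.  One
cycle is one year; workers enter at age 25 and exit at 64 (40 cycles).
Health states are mutually exclusive: normotensive, prehypertensive,
hypertensive, controlled, dead.  The clinical state definitions follow
JNC-7 blood-pressure categories, but the model tracks states only — no
continuous mmHg values are simulated.

Allowed transitions:

* normotensive → prehypertensive or hypertensive (risk-equation driven);
* prehypertensive → hypertensive (risk-equation driven, with the
  prehypertension indicator set, so onset risk is strictly higher than for
  a normotensive twin) or → controlled (a fixed annual
  behavioral-modification probability);
* hypertensive → controlled, only while medicated;
* controlled → prehypertensive or hypertensive, with the same
  probabilities as a normotensive twin;
* any living state → dead.

Prehypertensive workers never return to normotensive; hypertensive workers
never move back to prehypertensive or normotensive; these are asserted
over full simulated trajectories in the test suite.

### Probability algebra

The risk equations produce 5-year probabilities.  They are converted to
annual probabilities under a constant-hazard assumption (the DEALE
method): `r = −ln(1−p₅)/5`, `p₁ = 1−e^{−r}`, algebraically identical to
`p₁ = 1−(1−p₅)^{1/5}`.  The same exponential rate↔probability conversion
is applied uniformly to mortality rates.  The CVD hazard ratio for
hypertensives acts multiplicatively on the rate scale *before* conversion,
and competing causes (CVD, non-CVD, pregnancy-related for women) are
summed on the rate scale with a single annual death draw — standard
decision-model practice.

### Within-cycle event order

The order is fixed because it changes results slightly: **mortality →
behaviors (smoking, activity, BMI) → employment → health state → age
increment**.  Consequences of this choice:

* a worker who becomes unemployed this cycle already has zero effective
  PWE and work-status covariates in this cycle's risk equations;
* BMI drift uses the activity status *after* this cycle's activity toggle;
* the medication/control sub-step applies to workers hypertensive at the
  start of the health step.  Workers who become hypertensive within the
  cycle face their first prescription draw the following cycle, which also
  means baseline hypertensives face it in cycle 1;
* a newly prescribed worker may transition to controlled in the same
  cycle (prescription, adherence initiation, and the control draw are one
  sub-step).

### Treatment dynamics

Unmedicated hypertensives draw prescription each cycle with a
race-specific probability (Black > white, reflecting observed prescribing
patterns).  Adherence (high/medium/low, MPR bands >0.80 / 0.50–0.79 /
<0.50) is drawn once at initiation and retained for life — the initiation
distribution is specified, redrawing is not, and retention is the simpler
reading.  Once medicated, a worker stays medicated while hypertensive or
controlled; a controlled worker who relapses to hypertensive keeps the
prescription and adherence level.  A controlled worker whose state moves
to *prehypertensive* leaves the medicated pathway (medication status is
only defined on the hypertensive/controlled branch); if they later become
hypertensive again they face a fresh prescription draw.  Unmedicated
hypertensives have zero probability of becoming controlled.

### Numerical choices

* BMI is floored at 12 kg/m² to keep the log transform defined.
* All categorical draws use inverse-CDF sampling against explicit uniform
  arrays, and every cycle consumes a fixed number of draws per worker
  (dead workers consume but ignore draws).  This makes common-random-
  number (CRN) pairing exact: runs that share a seed stay synchronized
  draw-for-draw across scenarios, so a scenario that leaves a group's
  allocation row unchanged reproduces that group's output bit for bit
  (scenario C, white workers).
* Cohort random streams are keyed `SeedSequence([master_seed, race_code,
  cohort_index])` — independent across cohorts, identical across
  scenarios.
* If the two annual onset probabilities summed above 1 the stay
  probability would be clipped implicitly by the inverse-CDF draw
  (hypertension takes precedence); in practice their sum is far below 1.
* Perturbed sensitivity probabilities are clamped to [0, 1]: the +25% arm
  can push large control probabilities past 1, and clamping preserves
  validity.

## Parameters

All parameters live in a provenance-tagged `ParameterSet` (YAML
round-trippable).  The important groups, with fixture defaults:

| group | default | units / scale | note |
|---|---|---|---|
| risk equations | printed coefficients, exact | logit of 5-yr probability | the model's engine |
| allocation (status quo) | printed rows, exact | probability over 4 classes | the embodiment of segregation |
| composition weights | male share 0.180; white share 0.813 (men), 0.775 (women) | fractions | calibrated so mixture marginalization of status-quo rows reproduces the published scenario A/B rows within 0.005 |
| prescription | white 0.14, black 0.18 | per year | fixture; Black > white is a structural constraint |
| control by adherence | 0.43 / 0.34 / 0.33 (high/med/low) | per year | fixture, clinical-literature ballpark |
| adherence at initiation | 0.54 / 0.24 / 0.22 | distribution | fixture |
| prehyp → controlled | 0.05 | per year | behavioral-modification advice |
| mortality | geometric age ramps, e.g. non-CVD male 1.3→9.5 per 1000 | per year, 5-yr age bands | vital-statistics-like shape; Black excess ×1.4 (CVD/non-CVD), ×2.5 (pregnancy) |
| CVD hazard ratio (hypertensive) | men 1.8, women 2.0 | — | ≥ 1 enforced |
| smoking dynamics | initiation 1.5%→0.1%, cessation 4%→6% by age band | per year | fixture |
| BMI drift | +0.10 (active) / +0.25 (inactive) ± 0.10 | kg/m² per year | fixture |
| employment | class intercepts set from the published 1%/1%/3%/4% unemployment gradient | multinomial logit | age, gender, race, unemployment history, class |
| PWE scores | class-mean gradients, e.g. control +0.70→−0.60, sd 1.0 | standardized | control/support fall, demand (iso-strain) rises toward aides |
| baseline BP state at 25 | e.g. white women 2.5% / Black men 6% hypertensive | distribution | survey-like, see below |

## What the synthetic generator emulates — and what it does not

The original parameters were estimated from restricted cohort and survey
microdata (CARDIA, NHANES, NHIS, ACS linked with O*NET) or drawn from
clinical studies; none of those values except the ones listed as
"printed, exact" above are recoverable.  `segsim.fixtures` therefore
generates stand-ins that preserve the *structure* that drives the
analysis:

* occupational-class gradients in unemployment and PWE;
* race differentials in baseline BMI, smoking, activity, blood-pressure
  state, family history, prescription, and mortality;
* race-specific workforce gender mix, made internally consistent with the
  composition weights (white female share 0.813, Black 0.846);
* age-banded smoking dynamics.

Two generator knobs scale these features: `gradient_strength`
(occupational gradients) and `race_effect` (race differentials).  Setting
both to zero produces a fully exchangeable population, which the test
suite uses as a null: under a common allocation table the Black–white gap
must vanish to Monte-Carlo precision.

Fixture magnitudes were chosen once from the ballpark of the cited
literature and calibrated only against the *qualitative* published
pattern — prevalence rising monotonically with age from a few cases per
100 at ages 25–29, a positive Black–white gap of roughly two cases per
100, and gap-narrowing under desegregation.  In particular, the baseline
prehypertensive and hypertensive shares at age 25 were set small: the
printed prehypertension-onset equation contributes almost no inflow at
working ages (its age coefficient of −0.078 per year makes the 5-year
probability negligible beyond the mid-20s), so a large baseline
prehypertensive pool would drain early and produce a mid-career
prevalence dip that the published age-band table does not show.

Passing tests on this fixture therefore demonstrate that the *machinery*
— allocation, transition logic, CRN pairing, scenario construction,
aggregation — reproduces the structural findings, not that the shipped
numbers are estimates of the real-world quantities.  The headline
prevalence *levels* computed here (≈14.1 white / 16.1 Black per 100 under
the status quo) are fixture outputs, close to the published levels but
not reproductions of them.

## Scenario construction

The original allocation probabilities come from multinomial regressions
whose coefficients are not published; only the predicted rows are.
Scenarios A and B are therefore built by mixture-weight marginalization
of the status-quo rows (within-gender for A, overall for B) using the
composition weights above; the published scenario rows are shipped
alongside as a reference, and the two constructions agree within 0.005
per entry.  Scenarios C and D are exact row copies and need no weights.
Regression-based marginalization and mixture marginalization differ
slightly in general; the mixture form is the only one available from
printed values.

## Sensitivity analysis

One-way, ±25%, two blocks perturbed separately: the race-specific
prescription probabilities and the control-by-adherence probabilities.
Each arm reruns the *entire* experiment; the reported interval per
scenario × race is the min/max of career-average prevalence across
{base, −25%, +25%}, so it always contains the base value.  Because
simulated individuals are synthetic, classical standard errors and
significance tests are not meaningful; dispersion across cohorts is
reported as Monte-Carlo uncertainty and the sensitivity intervals bound
parameter uncertainty.

## Problem sizes

The shipped experiment defaults to the full design (500 cohorts of
100,000 workers per race).  The test suite and the acceptance script use
a scaled-down design of 10 cohorts × 10,000 workers per race (with
smaller auxiliary runs for the sensitivity and null checks), which keeps
every Monte-Carlo comparison inside 3-standard-error bands while running
in minutes on one CPU.  All reported checks state their `n`.

## Known limitations

* No interclass mobility, by construction; occupational class and the PWE
  profile are fixed at age 25.
* The PWE scores are on a synthetic standardized scale; the real
  ACS–O*NET score scale is unknown.
* Workplace discrimination, tokenism, education, income, and seniority
  effects are outside the model.
* Whether prehypertensive workers should also face the prehypertension
  equation (its own prehypertension coefficient suggests the original fit
  may have pooled all non-hypertensive workers) is undecidable from the
  printed material; here the equation applies only to normotensive and
  controlled workers, with the indicator forced to zero.
* Baseline hypertensives reuse the incident-case prescription
  probability; a distinct baseline-treatment parameter is not modeled.
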