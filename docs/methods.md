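# Methods

## Scope

`stroke_cea` estimates the cost-effectiveness of 14-day edaravone dexborneol
(ED) versus dl-3-n-butylphthalide (NBP) treatment for acute ischemic stroke
(AIS) from the Chinese healthcare payer perspective. The engine is a
two-stage cohort model — a 90-day decision tree feeding a lifetime annual
Markov model over three modified-Rankin-Scale (mRS) states — plus an
unanchored matching-adjusted indirect comparison (MAIC) stage for deriving
comparable day-90 outcome distributions from patient-level data, and
deterministic and probabilistic sensitivity analyses.

## Health states and time structure

Patients enter at age 60. Three states: mRS 0–1 (no disability, utility
0.84/year), mRS 2–5 (disability, 0.47/year), mRS 6 (dead, utility 0,
absorbing). The decision tree covers randomization to day 90; the day-90
state distribution then seeds a Markov chain of 1-year cycles to a 40-year
horizon. Cycle 0 spans the remaining 275/365 of the first model year at the
day-90 distribution, with no transition; cycles 1–39 each apply one
transition. Costs and QALYs of cycles ≥ 1 are half-cycle corrected (mean of
start- and end-of-cycle occupancy) and discounted at 5%/year via
(1 + r)^−t; year 1 (tree + cycle 0) is undiscounted.

## Transition composition

Within each cycle, events are ordered: recurrence first, then background
mortality.

1. A patient in alive state *s* suffers a recurrent stroke with the
   year-specific probability r(t) (5.9% in year 1 declining to 1.6% beyond
   year 9). The event's destination distribution carries its acute case
   fatality: from mRS 0–1 the patient returns to mRS 0–1 or worsens to
   mRS 2–5 (0.39495 each) or dies (0.2101); from mRS 2–5 they remain
   (0.7899) or die (0.2101). Recurrence never improves disability. The
   printed split from mRS 0–1 (39.50/39.50/21.01) sums to 100.01%; the
   package resolves it as an even split of the (1 − 0.2101) survivor mass.
2. Survivors of the recurrence step then face the age-band annual death
   probability (0.75% at 60–64 rising to 16.17% at ≥ 90, the last band
   applied through age 100) multiplied by the death hazard ratio of the
   state they occupy *after* the recurrence step (1.00 for mRS 0–1, 2.50
   for mRS 2–5), capped at 1.

Age for the band lookup is `start_age + cycle_index` (the age at the start
of the cycle being simulated). Recurrence-year indexing: cycle 1 uses the
year-0–1 rate, cycles ≥ 10 the terminal rate; cycle 0 carries no recurrence
(no 0–90-day rate exists and the tree already encodes day-90 outcomes).

## Accrual conventions

These are the package's central modeling choices; the published report
leaves them implicit, so each is config-exposed and the defaults are the
combination that reproduces the published base case.

**Decision tree (day 0–90).** Cost = 14-day drug course (unit price ×
units/dose × doses/day × 14) + one hospitalization episode at the day-90
state's cost + annual rehabilitation/secondary-prevention cost of alive
states prorated over the post-discharge window (90 − 9.9 days)/365. This
reproduces the published NBP cell (19,979.61) to the cent; the ED cell
computes 19,299.92 against a printed 19,302.20 — a 2.28 CNY residual not
derivable from the published inputs. QALY = state utility × 90/365 (the
printed day-90 QALYs, 0.1708/0.1694, are internally inconsistent with any
single convention on the day-90 distributions and are not reproduced; see
Limitations).

**Markov cycles.** Per cycle and discounted:

* QALYs: half-cycle-corrected occupancy × utilities, minus recurrence
  incidence × the 0.09 event disutility.
* Recurrence costs (`recurrence_event_costs`, default on): each event incurs
  the hospitalization episode of its destination state; fatal recurrences
  the mRS-6 admission (13,950.96).
* Death costs (`markov_death_costs`, default on): each background
  (non-recurrence) death incurs one terminal mRS-6 admission. Without this
  stream lifetime costs fall ~19% short of the published totals; with it
  both arms land within 1.4%.
* Continuing-care costs (`markov_state_costs`, default **off**): annual
  rehabilitation/secondary-prevention costs can be applied to alive states
  (`on`) or to mRS 2–5 only, but the source scopes those costs to days
  15–90, and applying them for life yields ≈5× the published totals.
* Cycle 0 (`cycle0_fill`, default **calendar-only**): the 275-day fill
  aligns the calendar without accruing; the `accrue` mode credits prorated
  utilities and continuing-care costs instead. With accrual, lifetime QALYs
  overshoot the published values by ~7%; without, they agree to ~0.6%.

All costs are 2021 CNY. `adjust_cost_to_base_year` applies a user-supplied
medical-CPI ratio for inputs from other price years; the shipped defaults
are taken as already converted.

## Incremental analysis

ΔC and ΔE are intervention − comparator. The intervention *dominates* when
ΔC < 0 and ΔE > 0 (is *dominated* in the mirror case); otherwise
ICER = ΔC/ΔE. Net monetary benefit NMB(λ) = λ·ΔE − ΔC is reported at λ of
1× and 3× 2021 Chinese GDP per capita (80,976 and 242,928 CNY/QALY). The raw
ICER is retained even under dominance because the tornado analysis tracks it.

## MAIC

Unanchored MAIC weights w_i = exp(α·x_ci), with covariates centred on the
aggregate targets, solve the moment conditions Σ w_i x_ci = 0 — the
stationarity conditions of the strictly convex objective Σ_i exp(α·x_ci).
The solver standardizes centred covariates to unit IPD standard deviation,
minimizes by BFGS with analytic gradient, and falls back to damped Newton;
convergence requires every standardized absolute moment gap ≤ 1e-8 (in
practice gaps land near 1e-10). First moments only are matched, for the
eight reported baseline variables; the published after-adjustment column
equals the comparator means exactly and reports no matched SDs. Targets
outside the IPD range (convex hull, per coordinate) and constant covariates
raise errors. Weights are reported rescaled to sum to the effective sample
size ESS = (Σw)²/Σw²; every downstream estimator is scale-invariant. The
weighted day-90 distribution is the Σ w·1[state]/Σ w estimator. The package
reports whatever rows it is given (it does not re-create the source trial's
585-of-599 efficacy exclusion).

## Synthetic cohort generator

Because the intervention trial's patient-level data are proprietary, the
generator emulates its published baseline margins: truncated-normal age
(mean 61.80, SD 9.46, ≥ 18), medication time window (28.01, 10.96, within
the 0–48 h eligibility window) and NIHSS (7.07, 2.96, bounded 0–42);
independent Bernoulli flags for male (67.45%), prior AIS (29.05%),
hypertension (65.11%), diabetes (25.21%), hyperlipidemia (7.35%); and a
3-category day-90 outcome: logit P(mRS 0–1 | alive) = intercept + Σ coef·x
(default intercept-only at 67.1%) with an independent death mass defaulting
to 0% (no day-90 deaths were reported in either arm). Covariates are drawn
independently — the sources publish only marginals — so tests passing on
synthetic data demonstrate solver correctness and estimand recovery under
known mechanisms, not robustness to the real trials' correlation structure,
non-normal covariates or missingness. Truncation bounds are package choices.
`oracle_weighted_outcome` computes, by Monte Carlo, the value of the outcome
model at the target baseline (location-shifted continuous covariates,
redrawn binaries): the estimand a correctly weighted first-moment MAIC
should recover under this generator. (Exponential tilting of a normal is an
exact location shift; truncation makes the equivalence approximate, which is
why recovery is asserted within Monte-Carlo error.)

## Sensitivity analyses

**One-way (tornado).** Every parameter with a published range is set to its
low and high bound in turn (all else at base), both arms re-run, and entries
ranked by the absolute swing of the outcome (raw ICER by default, NMB
optionally). The set comprises the two drug prices, five costs, three
utilities, two hazard ratios and the discount rate.

**Probabilistic.** Parameters with a distribution family are sampled
independently each draw: gamma for costs and beta for utilities, fitted by
method of moments with mean = base value and SD = (high − low)/(2·1.96)
(the range read as a central 95% interval); lognormal for hazard ratios
with median = base and σ = (ln high − ln low)/(2·1.96). Prices, recurrence
rates, mortality and the discount rate have no published distribution and
stay fixed. 1,000 iterations by default; per-draw two-arm results feed the
incremental scatter and the cost-effectiveness acceptability curve
(fraction of draws with NMB(λ) > 0 over a λ grid). The source states no
parameter correlations; none are imposed.

## Numerical choices

* Distribution sums validated to 1e-9; composed transition rows checked to
  lie in [0, 1] and renormalization is never silent.
* m(age)×HR capped at 1 before composition.
* MAIC tolerance 1e-8 on standardized moment gaps; optimizer gradient
  tolerance 1e-12; brute-force/Nelder-Mead cross-checks at 1e-6 in α.
* ICER with ΔE = 0 is flagged undefined and reported as signed infinity
  (NaN when ΔC is also 0).
* Degenerate inputs: an all-dead initial distribution, zero-width
  sensitivity ranges, zero drug duration and zero discount are all exact
  special cases covered by tests.

## Problem sizes used in tests

Property tests use 1,000 random valid parameter sets for conservation
checks, a 100,000-patient microsimulation twin for cohort agreement,
synthetic cohorts of 10,000 for estimand recovery with 200,000-draw oracle
estimates, and the full 1,000-iteration PSA. The whole suite runs in well
under a minute on one core.

## Known limitations

* The published day-90 QALYs and the 5-year row of the base-case table are
  not reproducible from the stated inputs under any consistent convention
  we could construct; lifetime results agree to 0.6% (QALYs) and 1.4%
  (costs) under the defaults above.
* The tornado's third-ranked driver is sensitive to the accrual
  conventions: under the defaults the discount rate (swing 3,748), the
  mRS 2–5 utility (3,551) and the mRS 0–1 utility (3,541) are separated by
  less than 6%, so their ordering should not be over-interpreted; the
  published report names the mRS 0–1 utility third.
* The cohort engine models no tunnel states or patient heterogeneity (the
  microsimulation exists only as a test oracle), and no treatment effect
  beyond the day-90 distribution difference.
* Variance estimation for MAIC is limited to the ESS diagnostic; no
  sandwich or bootstrap intervals are produced.
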