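# Base-case inputs for the acute-ischemic-stroke cost-effectiveness model
# (edaravone dexborneol vs dl-3-n-butylphthalide).  All costs in 2021 CNY.
#
# Note on the post-recurrence split from MRS01: the acute case fatality of a
# recurrent stroke is 21.01%; survivors are assumed to split evenly between
# returning to mRS 0-1 and worsening to mRS 2-5, i.e. (1 - 0.2101) / 2 =
# 0.39495 each (reported rounded as 39.50%).

model:
  start_age: 60
  horizon_years: 40
  cycle_length_years: 1.0
  discount_rate: 0.05
  short_term_days: 90
  wtp_gdp_per_capita: 80976.0       # Chinese GDP per capita, 2021 CNY
  wtp_multipliers: [1.0, 3.0]
  # Cost/QALY continuation policies beyond day 90 (see docs/methods.md):
  # rehabilitation + secondary-prevention costs cover days 15-90 only, each
  # recurrence incurs the destination state's hospitalization, each death a
  # terminal mRS-6 admission, and cycle 0 (the 275-day remainder of year 1)
  # aligns the calendar without accruing costs or utilities.
  markov_state_costs: "off"         # off | on | mrs25_only
  recurrence_event_costs: true
  markov_death_costs: true
  cycle0_fill: "calendar-only"      # calendar-only | accrue

arms:
  intervention:
    name: edaravone_dexborneol
    day90_distribution: {MRS01: 0.670, MRS25: 0.330, DEAD: 0.0}
    regimen: {unit_price: 33.00, units_per_dose: 3, doses_per_day: 2, duration_days: 14}
  comparator:
    name: dl-3-n-butylphthalide
    day90_distribution: {MRS01: 0.638, MRS25: 0.362, DEAD: 0.0}
    regimen: {unit_price: 116.76, units_per_dose: 1, doses_per_day: 2, duration_days: 14}

costs:
  cost_year: 2021
  hospitalization:
    MRS01: 12613.70
    MRS25: 17222.62
    DEAD: 13950.96
  annual_rehab_secondary_prevention:
    MRS01: 9264.26
    MRS25: 14238.24
  mean_length_of_stay_days: 9.9

utilities:
  by_state:
    MRS01: 0.84
    MRS25: 0.47
  recurrence_disutility: 0.09

transitions:
  death_hazard_ratio:
    MRS01: 1.00
    MRS25: 2.50
  post_recurrence:
    MRS01: {MRS01: 0.39495, MRS25: 0.39495, DEAD: 0.2101}
    MRS25: {MRS25: 0.7899, DEAD: 0.2101}

recurrence:
  # annual_rates[k] is the recurrence probability in year k -> k+1
  annual_rates: [0.059, 0.036, 0.025, 0.022, 0.022, 0.027, 0.027, 0.023, 0.028]
  terminal_rate: 0.016              # all years beyond the ninth

mortality:
  bands:
    - {lower: 60.0, upper: 65.0, rate: 0.0075}
    - {lower: 65.0, upper: 70.0, rate: 0.0117}
    - {lower: 70.0, upper: 75.0, rate: 0.0203}
    - {lower: 75.0, upper: 80.0, rate: 0.0356}
    - {lower: 80.0, upper: 85.0, rate: 0.0629}
    - {lower: 85.0, upper: 90.0, rate: 0.1028}
    - {lower: 90.0, upper: 101.0, rate: 0.1617}

sensitivity:
  # family "fixed": varied in one-way sensitivity analysis only, never
  # sampled in the probabilistic analysis.
  - {path: "arms.intervention.regimen.unit_price", low: 33.00, high: 48.80, family: fixed}
  - {path: "arms.comparator.regimen.unit_price", low: 116.76, high: 139.00, family: fixed}
  - {path: "costs.hospitalization.MRS01", low: 12428.04, high: 12801.87, family: gamma}
  - {path: "costs.hospitalization.MRS25", low: 16845.03, high: 17606.49, family: gamma}
  - {path: "costs.hospitalization.DEAD", low: 12819.43, high: 15155.26, family: gamma}
  - {path: "costs.annual_rehab_secondary_prevention.MRS01", low: 8976.99, high: 9557.81, family: gamma}
  - {path: "costs.annual_rehab_secondary_prevention.MRS25", low: 13460.47, high: 15048.63, family: gamma}
  - {path: "utilities.by_state.MRS01", low: 0.66, high: 0.92, family: beta}
  - {path: "utilities.by_state.MRS25", low: 0.24, high: 0.66, family: beta}
  - {path: "utilities.recurrence_disutility", low: 0.06, high: 0.11, family: beta}
  - {path: "transitions.death_hazard_ratio.MRS01", low: 1.00, high: 1.20, family: lognormal}
  - {path: "transitions.death_hazard_ratio.MRS25", low: 1.70, high: 3.80, family: lognormal}
  - {path: "model.discount_rate", low: 0.0, high: 0.08, family: fixed}
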