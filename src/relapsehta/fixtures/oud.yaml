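# Base-case parameter set: opioid use disorder pathway.
# Relapse bands are printed per cycle for this model. The treatment states
# are medically supervised withdrawal (msw, ~12 weeks) followed by
# medication for opioid use disorder (moud, open-ended maintenance).
# Oddities retained as published: treatment_seeking limits sit below the
# base estimate; sensitivity analysis takes min/max of the pair.
schema: relapsehta-params/1
model: oud
relapse_rate:
  - {first_cycle: 1, prob: 0.35}
  - {first_cycle: 2, prob: 0.06}
  - {first_cycle: 5, prob: 0.04}
  - {first_cycle: 9, prob: 0.02}
treatment_seeking: 0.9
treatment_continuation: 1.0
recovery_after_treatment: 0.02
spontaneous_recovery: 0.0
mortality_rr:
  abstinence: 1.0
  relapse: 6.14
  msw: 6.04
  moud: 3.55
baseline_annual_mortality_male: 0.0025
baseline_annual_mortality_female: 0.0016
prop_male: 0.73
state_cost_per_cycle:
  abstinence: 0.0
  relapse: 0.0
  msw: 2324.0
  moud: 2324.0
utility_full_year:
  abstinence: 0.9
  relapse: 0.57
  msw: 0.62
  moud: 0.62
discount_rate_costs: 0.035
discount_rate_outcomes: 0.035
wtp_per_qaly: 20000.0
app_effect_multiplier: 0.85
app_cost_per_cycle: 25.0
app_active_cycles: 4
seeking_effect_multiplier: 1.0
recovery_effect_multiplier: 1.0
limits:
  relapse_rate.band1: [0.28, 0.42]
  relapse_rate.band2: [0.05, 0.08]
  relapse_rate.band3: [0.03, 0.05]
  relapse_rate.band4: [0.02, 0.02]
  treatment_seeking: [0.72, 0.8]
  recovery_after_treatment: [0.01, 0.02]
  treatment_continuation: [0.8, 1.0]
  spontaneous_recovery: [0.0, 0.0]
  mortality_rr.msw: [4.83, 7.25]
  mortality_rr.moud: [2.84, 4.26]
  mortality_rr.relapse: [4.91, 7.36]
  app_effect_multiplier: [0.68, 1.02]
  seeking_effect_multiplier: [0.8, 1.2]
  recovery_effect_multiplier: [0.8, 1.2]
  state_cost_per_cycle.abstinence: [0.0, 0.0]
  state_cost_per_cycle.treatment: [1959.0, 2759.0]
  state_cost_per_cycle.relapse: [0.0, 0.0]
  app_cost_per_cycle: [25.0, 25.0]
  utility_full_year.abstinence: [0.72, 1.0]
  utility_full_year.treatment: [0.5, 0.74]
  utility_full_year.relapse: [0.46, 0.69]
  discount_rate_costs: [0.01, 0.05]
  discount_rate_outcomes: [0.01, 0.05]
  prop_male: [0.58, 0.87]
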