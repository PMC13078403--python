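# Base-case parameter set: alcohol use disorder pathway.
# Per-cycle probabilities refer to the model's 3-month cycle; the year-1
# relapse band covers cycles 1-4, years 2-3 cover cycles 5-12, year 4
# onwards applies from cycle 13.
schema: relapsehta-params/1
model: aud
relapse_rate:
  - {first_cycle: 1, prob: 0.13}
  - {first_cycle: 5, prob: 0.08}
  - {first_cycle: 13, prob: 0.03}
treatment_seeking: 0.8
treatment_continuation: 0.58
recovery_after_treatment: 1.0
spontaneous_recovery: 0.002
mortality_rr:
  abstinence: 1.04
  relapse: 1.24
  # No published estimate exists for the treatment states; the recently
  # drinking (relapse) relative rate is assumed to carry over.
  treatment_start: 1.24
  treatment_continuation: 1.24
baseline_annual_mortality_male: 0.0025
baseline_annual_mortality_female: 0.0016
prop_male: 0.74
state_cost_per_cycle:
  abstinence: 0.0
  relapse: 1223.0
  treatment_start: 2086.0
  treatment_continuation: 2086.0
utility_full_year:
  abstinence: 0.67
  relapse: 0.57
  treatment_start: 0.62
  treatment_continuation: 0.62
discount_rate_costs: 0.035
discount_rate_outcomes: 0.035
wtp_per_qaly: 20000.0
app_effect_multiplier: 0.85
app_cost_per_cycle: 25.0
app_active_cycles: 4
seeking_effect_multiplier: 1.0
recovery_effect_multiplier: 1.0
limits:
  relapse_rate.band1: [0.11, 0.16]
  relapse_rate.band2: [0.06, 0.09]
  relapse_rate.band3: [0.03, 0.04]
  treatment_seeking: [0.64, 0.8]
  recovery_after_treatment: [0.8, 1.0]
  treatment_continuation: [0.46, 0.7]
  spontaneous_recovery: [0.001, 0.002]
  mortality_rr.abstinence: [0.94, 1.16]
  mortality_rr.relapse: [1.07, 1.44]
  app_effect_multiplier: [0.68, 1.02]
  seeking_effect_multiplier: [0.8, 1.2]
  recovery_effect_multiplier: [0.8, 1.2]
  state_cost_per_cycle.abstinence: [0.0, 0.0]
  state_cost_per_cycle.treatment: [1668.0, 2503.0]
  state_cost_per_cycle.relapse: [979.0, 1468.0]
  app_cost_per_cycle: [25.0, 25.0]
  utility_full_year.abstinence: [0.53, 0.8]
  utility_full_year.treatment: [0.5, 0.74]
  utility_full_year.relapse: [0.46, 0.69]
  discount_rate_costs: [0.01, 0.05]
  discount_rate_outcomes: [0.01, 0.05]
  prop_male: [0.59, 0.89]
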