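parameters:
  population_init: 6910840.0
  diabetes_rate: 0.8
  hypertension_rate: 0.8
  diet_rate: 0.8
  lifestyle_rate: 0.8
  patient_bias_1: 0.05
  provider_bias_1: 0.8
  nephrologist_bias_1: 0.05
  system_bias_1: 0.05
  patient_bias_2: 0.05
  provider_bias_2: 0.08
  nephrologist_bias_2: 0.05
  system_bias_2: 0.05
  patient_bias_3: 0.05
  provider_bias_3: 0.16
  nephrologist_bias_3: 0.05
  system_bias_3: 0.05
  patient_bias_4: 0.05
  provider_bias_4: 0.073
  nephrologist_bias_4: 0.05
  system_bias_4: 0.05
  patient_bias_5: 0.05
  provider_bias_5: 0.152
  nephrologist_bias_5: 0.05
  system_bias_5: 0.05
  patient_bias_esrd: 0.05
  provider_bias_esrd: 0.33
  nephrologist_bias_esrd: 0.05
  system_bias_esrd: 0.05
  base_progression_rate_1: 8.0
  base_progression_rate_2: 7.0
  base_progression_rate_3: 6.0
  base_progression_rate_4: 5.0
  base_progression_rate_5: 4.0
  monitored_slowdown: 0.25
  screening_coverage: 0.3
  bias_to_unmonitored_gain: 0.5
  dialysis_rate: 40.0
  transplant_rate: 6.0
  esrd_death_rate: 15.0
simulation:
  t_start: 2010.0
  t_end: 2022.0
  dt: 0.0625
scenarios:
- name: current
  overrides:
    diabetes_rate: 1.15
    hypertension_rate: 1.25
- name: stage1-bias
  overrides:
    provider_bias_1: 1.3
- name: stage2-bias
  overrides:
    provider_bias_2: 1.55
- name: stage3-bias
  overrides:
    provider_bias_3: 1.32
- name: stage4-bias
  overrides:
    provider_bias_4: 1.151
- name: stage5-bias
  overrides:
    provider_bias_5: 0.275
- name: esrd-bias
  overrides:
    provider_bias_esrd: 0.72
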