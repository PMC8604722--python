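arms:
- label: placebo
  n: 23
  week8_change: -11.2
  autoimmune_shift: 0.0
  reactivity_change: 0.2
- label: feneb_50mg_qd
  n: 23
  week8_change: -11.7
  autoimmune_shift: -4.0
  reactivity_change: -0.44
- label: feneb_150mg_qd
  n: 24
  week8_change: -17.6
  autoimmune_shift: -3.0
  reactivity_change: -0.54
- label: feneb_200mg_bid
  n: 23
  week8_change: -20.7
  autoimmune_shift: 0.0
  reactivity_change: -0.44
visit_weeks:
- 0
- 1
- 2
- 3
- 4
- 5
- 6
- 7
- 8
- 9
- 10
- 11
- 12
baseline_uas7_mean: 27.5
baseline_uas7_sd: 7.3
onset_days: 7.0
ar1_rho: 0.6
daily_noise_sd: 1.0
session_noise_sd: 0.35
bhra_pos_prevalence: 0.41
dropout_rate: 0.14
session_missing_rate: 0.03
assay_noise_sd: 0.02
treatment_days: 56
followup_days: 84
mid_uas7: 11.0
mid_itch: 5.0
countries:
- - US
  - 0.4
- - Canada
  - 0.35
- - Germany
  - 0.25
seed: 0
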