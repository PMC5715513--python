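# Stochastic EMR scenario calibrated so the five shipped arms have expected
# PPVs of roughly 22 / 51 / 84 / 90 / 7 percent (see docs/methods.md for the
# derivation).  Values are SyntheticConfig fields; seed must be supplied.
n_patients: 25827
duplicate_patient_count: 2083
invalid_date_count: 22
female_fraction: 0.495
age_mean: 61.6
age_sd: 15.7
true_event_rate: 0.007769
history_coding_rate: 0.014962
mimic_rate: 0.001480
testonly_coding_rate: 0.011103
ruleout_suspected_rate: 0.008828
ruleout_true_fraction: 0.07
same_day_duplication_prob: 0.54
primary_position_fraction: 0.07
background_imaging_rate: 0.13
imaging_offset_model:
  true_event: {p_none: 0.0, ranges: [[-1, 1, 1.0]]}
  history_of_stroke: {p_none: 0.6, ranges: [[-365, -31, 0.5], [31, 365, 0.5]]}
  stroke_mimic: {p_none: 0.0, ranges: [[-1, 1, 0.58333], [2, 30, 0.41667]]}
  blood_or_imaging_tests: {p_none: 1.0, ranges: []}
  ruleout_suspected: {p_none: 0.0, ranges: [[-1, 1, 1.0]]}
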