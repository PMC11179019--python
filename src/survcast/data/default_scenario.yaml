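# Default synthetic-registry scenario: national lung-cancer-registry shape.
# Cohort sizes ramp linearly; stratum mixes drift linearly between the
# (first cohort, last cohort) shares; survival shifts per stratum are off.
cohort_start: 1997
cohort_end: 2017
size_start: 5762
size_end: 14529
follow_up_end: 2018-12-31
max_s: 5
anniversary_rule: calendar_end
mixes:
  sex:
    male: [0.701, 0.551]
    female: [0.299, 0.449]
  age_group:
    "<55": [0.148, 0.169]
    "55-64": [0.206, 0.264]
    "65-74": [0.390, 0.272]
    ">=75": [0.256, 0.295]
  histology:
    ADENO: [0.382, 0.704]
    SCC: [0.251, 0.128]
    SCLC: [0.087, 0.068]
    other: [0.280, 0.100]
  stage:
    I: [0.110, 0.293]
    II: [0.035, 0.040]
    III: [0.240, 0.143]
    IV: [0.575, 0.504]
    unknown: [0.040, 0.020]
stratum_shifts: {}
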