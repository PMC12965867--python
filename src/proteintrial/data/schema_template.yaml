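covariates:
- name: age
  kind: continuous
  levels: null
  ordered: false
  time_varying: false
- name: hei
  kind: continuous
  levels: null
  ordered: false
  time_varying: true
- name: alcohol
  kind: continuous
  levels: null
  ordered: false
  time_varying: true
- name: met
  kind: continuous
  levels: null
  ordered: false
  time_varying: true
- name: cesd
  kind: continuous
  levels: null
  ordered: false
  time_varying: true
- name: sleep_hours
  kind: continuous
  levels: null
  ordered: false
  time_varying: true
- name: diabetes
  kind: binary
  levels: null
  ordered: false
  time_varying: true
- name: cancer
  kind: binary
  levels: null
  ordered: false
  time_varying: true
- name: hispanic
  kind: binary
  levels: null
  ordered: false
  time_varying: false
- name: education
  kind: categorical
  levels:
  - hs_or_less
  - some_college
  - college
  - postgrad
  ordered: true
  time_varying: false
- name: income
  kind: categorical
  levels:
  - lt_35k
  - 35_75k
  - ge_75k
  ordered: true
  time_varying: false
- name: race
  kind: categorical
  levels:
  - white
  - black
  - asian
  - am_indian
  - multiple
  ordered: false
  time_varying: false
- name: marital
  kind: categorical
  levels:
  - never
  - divorced
  - widowed
  - married
  - marriage_like
  ordered: false
  time_varying: false
- name: smoking
  kind: categorical
  levels:
  - never
  - former
  - current
  ordered: false
  time_varying: true
outcomes:
- vat
- sat
- bodyfat_pct
- lean_pct
- weight
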