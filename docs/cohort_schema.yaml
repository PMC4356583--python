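format: ihtsa-cohort-csv
dialect:
  encoding: UTF-8
  separator: ','
  decimal: .
  missing_cell: empty string
notes:
- one header row; columns exactly as listed, one row per transplant
- units are taken as declared; no conversion is applied
- followup_years, death and era are mandatory and never missing
columns:
- name: recipient_age
  kind: continuous
  unit: years
  maskable: true
- name: recipient_sex
  kind: categorical
  levels:
  - female
  - male
  maskable: true
- name: recipient_height
  kind: continuous
  unit: cm
  maskable: true
- name: recipient_weight
  kind: continuous
  unit: kg
  maskable: true
- name: diagnosis
  kind: categorical
  levels:
  - ischemic_cm
  - non_ischemic_cm
  - congenital
  - graft_failure
  - valvular
  - other
  maskable: true
- name: diabetes
  kind: indicator
  maskable: true
- name: hypertension
  kind: indicator
  maskable: true
- name: infection_2wk
  kind: indicator
  maskable: true
- name: antiarrhythmics
  kind: indicator
  maskable: true
- name: amiodarone
  kind: indicator
  maskable: true
- name: prior_transfusion
  kind: indicator
  maskable: true
- name: prior_transplant
  kind: indicator
  maskable: true
- name: prior_cardiac_surgery
  kind: indicator
  maskable: true
- name: icu
  kind: indicator
  maskable: true
- name: ventilator
  kind: indicator
  maskable: true
- name: ecmo
  kind: indicator
  maskable: true
- name: vad
  kind: indicator
  maskable: true
- name: era
  kind: categorical
  levels:
  - 1991-1995
  - 1996-2000
  - 2001-2005
  - 2006-2010
  maskable: false
- name: spp
  kind: continuous
  unit: mmHg
  maskable: true
- name: pvr
  kind: continuous
  unit: Wood units
  maskable: true
- name: creatinine
  kind: continuous
  unit: umol/l
  maskable: true
- name: bilirubin
  kind: continuous
  unit: mg/dl
  maskable: true
- name: pra_gt10
  kind: indicator
  maskable: true
- name: hladr_mismatch
  kind: categorical
  levels:
  - 0
  - 1
  - 2
  maskable: true
- name: recipient_bg
  kind: categorical
  levels:
  - A
  - AB
  - B
  - O
  maskable: true
- name: donor_age
  kind: continuous
  unit: years
  maskable: true
- name: donor_sex
  kind: categorical
  levels:
  - female
  - male
  maskable: true
- name: donor_height
  kind: continuous
  unit: cm
  maskable: true
- name: donor_weight
  kind: continuous
  unit: kg
  maskable: true
- name: ischemia_min
  kind: continuous
  unit: minutes
  maskable: true
- name: codd_head_trauma
  kind: indicator
  maskable: true
- name: codd_cva
  kind: indicator
  maskable: true
- name: donor_bg
  kind: categorical
  levels:
  - A
  - AB
  - B
  - O
  maskable: true
- name: followup_years
  kind: continuous
  unit: years
  maskable: false
- name: death
  kind: indicator
  maskable: false
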