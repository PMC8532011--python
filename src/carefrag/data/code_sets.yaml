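# Diagnosis-code vocabulary used by the phenotype rules.
#
# One named code set per rule clause. Patterns use two wildcard notations:
#   - a trailing lowercase "x" or "*" matches the stem itself plus any
#     extension (e.g. "J45.x" matches J45, J45.0, J45.909, ...);
#   - an interior lowercase "x" matches exactly one character at that
#     position, with the remaining characters literal (e.g. "250.x2"
#     matches 250.02, 250.12, ... but not 250.01).
# Matching is dot- and case-insensitive. Edit this file to change the
# vocabulary; no code change is needed.
asthma_dx:
  icd9: ["493.0x", "493.8x", "493.1x", "493.9x"]
  icd10: ["J45.x"]
copd_dx:
  icd9: ["491.22", "491.21", "491.9", "491.8", "493.2x", "492.8", "496"]
  icd10: ["J42", "J41.8", "J44.*", "J43.*"]
respiratory_failure_dx:
  icd9: ["518.82", "518.81", "799.1", "518.84"]
  icd10: ["J96.0*", "J80", "J96.9*", "J96.2*", "R09.2"]
copd_exacerbation_dx:
  icd9: ["491.22", "491.21", "493.22", "493.21"]
  icd10: ["J44.1", "J44.0"]
diabetes_dx:
  icd9: ["250.x", "357.2", "362.0x", "366.41"]
  icd10: ["E10.x", "E11.x"]
t1d_dx:
  icd9: ["250.x3", "250.x1"]
  icd10: ["E10.x"]
t2d_dx:
  icd9: ["250.x2", "250.x0"]
  icd10: ["E11.x"]
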