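# Default clinical-priority rubric: five features, 0-2 points each, 10 max.
# A calibrated reconstruction of the published semi-quantitative scale for
# lacosamide cardiac signals (the published cut-points live in
# supplementary material); review before reuse on another drug.
#
# Step functions: the points of the highest "min" not exceeding the value.
cases:                    # number of reported cases for the signal
  - {min: 0, points: 0}
  - {min: 10, points: 1}
  - {min: 50, points: 2}
ror025:                   # lower bound of the ROR 95% CI
  - {min: 0, points: 0}
  - {min: 2, points: 1}
  - {min: 5, points: 2}
death_proportion:         # deaths / cases among the signal's reports
  - {min: 0, points: 0}
  - {min: 0.25, points: 1}
  - {min: 0.5, points: 2}
importance:               # EMA-style reference-list membership
  NA: 0
  IME: 1
  DME: 2
evidence:                 # literature evidence grade (input annotation)
  "+": 1
  "++": 2
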