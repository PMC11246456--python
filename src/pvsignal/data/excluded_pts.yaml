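# PT exclusion classes applied before SOC restriction: administrative or
# indication-disease terms that would distort a drug-event screen.
# Miniature fixture lists; extend per analysis.
off_label:
  - Off label use
product_issues:
  - Product quality issue
  - Product packaging issue
medication_errors:
  - Medication error
  - Product use error
  - Accidental overdose
epilepsy_disorders:
  - Seizure
  - Epilepsy
  - Status epilepticus
  - Partial seizures
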