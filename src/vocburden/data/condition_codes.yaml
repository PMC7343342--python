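# ICD-9-CM prefix stems for the baseline comorbid-condition flags.  The
# source tables print only condition names; these stems are the package's
# default operationalization and are deliberately editable.
version: 1
conditions:
  neoplasms:
    ranges: [["140", "239"]]
  seizures:
    prefixes: ["345", "7803"]
  asthma:
    prefixes: ["493"]
  upper_respiratory_infection:
    ranges: [["460", "466"]]
  acute_chest_syndrome:
    prefixes: ["5173"]
  infectious_disease:
    ranges: [["001", "139"]]
  fever:
    prefixes: ["7806"]
  constipation:
    prefixes: ["5640"]
  chronic_pain:
    prefixes: ["3382"]
  iron_overload:
    prefixes: ["2750"]
  avascular_necrosis:
    prefixes: ["7334"]
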