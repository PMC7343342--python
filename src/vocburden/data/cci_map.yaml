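# Charlson Comorbidity Index, Deyo ICD-9-CM adaptation with the original
# Charlson weights.  Codes are diagnosis-code *prefixes* in dotless,
# category-padded form ("4280" == 428.0); "ranges" expand inclusive spans
# of equal-width numeric prefixes.  The mapping is configuration, not
# code: edit or swap this file to score with a different adaptation.
version: 1
conditions:
  myocardial_infarction:
    weight: 1
    prefixes: ["410", "412"]
  congestive_heart_failure:
    weight: 1
    prefixes: ["39891", "40201", "40211", "40291", "428"]
  peripheral_vascular_disease:
    weight: 1
    prefixes: ["441", "4439", "7854", "V434"]
  cerebrovascular_disease:
    weight: 1
    ranges: [["430", "438"]]
  dementia:
    weight: 1
    prefixes: ["290"]
  chronic_pulmonary_disease:
    weight: 1
    prefixes: ["5064"]
    ranges: [["490", "496"], ["500", "505"]]
  rheumatologic_disease:
    weight: 1
    prefixes: ["7100", "7101", "7104", "7140", "7141", "7142", "71481", "725"]
  peptic_ulcer_disease:
    weight: 1
    ranges: [["531", "534"]]
  mild_liver_disease:
    weight: 1
    prefixes: ["5712", "5714", "5715", "5716"]
  diabetes:
    weight: 1
    prefixes: ["2500", "2501", "2502", "2503", "2507"]
  diabetes_with_complications:
    weight: 2
    prefixes: ["2504", "2505", "2506"]
  hemiplegia_paraplegia:
    weight: 2
    prefixes: ["342", "3441"]
  renal_disease:
    weight: 2
    prefixes: ["582", "585", "586", "588"]
    ranges: [["5830", "5837"]]
  any_malignancy:
    weight: 2
    ranges: [["140", "172"], ["174", "195"], ["200", "208"]]
  moderate_severe_liver_disease:
    weight: 3
    prefixes: ["4560", "4561", "4562", "5722", "5723", "5724", "5728"]
  metastatic_solid_tumor:
    weight: 6
    ranges: [["196", "199"]]
  aids:
    weight: 6
    ranges: [["042", "044"]]
# When both members of a pair are present, only the severe form scores
# (mild form suppressed).
hierarchies:
  - [diabetes, diabetes_with_complications]
  - [mild_liver_disease, moderate_severe_liver_disease]
  - [any_malignancy, metastatic_solid_tumor]
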