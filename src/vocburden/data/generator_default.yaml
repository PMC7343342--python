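# Default synthetic-generator parameters, version-controlled so runs can
# cite the exact configuration.  Demographic and setting-mix marginals
# follow the published cohort summaries; the distributional forms and
# their dispersion/scale parameters are stand-ins chosen for realistic
# shape (overdispersed counts, right-skewed costs), not calibrated to any
# restricted dataset.
version: 1
n_patients: 1000
seed: 0
prop_female: 0.673
race_probs: {white: 0.063, black: 0.740, hispanic: 0.101, other: 0.029, unknown: 0.067}
region_probs: {northeast: 0.446, south: 0.266, west: 0.189, north_central: 0.099}
plan_probs: {FFS: 0.498, managed_care: 0.502}
age_band_probs: {"18-30": 0.519, "31-45": 0.296, "46-64": 0.179, "65+": 0.006}
episode_rate_mean: 2.0
episode_dispersion: 0.35
claims_per_episode_mean: 2.0
gap_within_episode_max_days: 3
setting_probs: {inpatient: 0.378, er: 0.362, outpatient: 0.182, office: 0.058, other: 0.020}
inpatient_stay_mean_days: 4.5
cost_lognormal_params:
  inpatient: [8.11, 1.0]
  er: [5.75, 1.0]
  outpatient: [5.33, 1.0]
  office: [4.51, 1.0]
  other: [4.11, 1.0]
  background: [4.60, 1.0]
  pharmacy: [3.70, 0.8]
background_claim_rate: 12.0
pharmacy_fill_rate: 10.0
drug_class_probs:
  antibiotic: 0.20
  acetaminophen: 0.20
  folic_acid: 0.13
  opioid: 0.13
  nsaid: 0.12
  hydroxyurea: 0.05
  other: 0.17
transfusion_prob: 0.03
baseline_voc_prob: 0.25
enrollment_dropout_prob: 0.12
clinical_trial_prob: 0.01
death_prob: 0.003
cpi_factors: {2009: 1.1318, 2010: 1.0945, 2011: 1.0622, 2012: 1.0246, 2013: 1.0}
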