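# Calibration preset: synthetic GBM cohort emulating the published
# 279-patient institutional cohort summaries.  Sizes in cm / cm3,
# times in months, betas on the log-hazard-ratio scale.
n_patients: 279
age_median: 62.0
age_q1: 55.0
age_q3: 68.0
age_min: 31.0
age_max: 85.0
p_female: 0.3870967741935484          # 108/279
surgery_probs:                         # biopsy, 100%, >=90%, <90% resected
  - 0.25448028673835127                # 71/279
  - 0.20430107526881722                # 57/279
  - 0.3082437275985663                 # 86/279
  - 0.23297491039426524                # 65/279
oncology_probs:                        # no Stupp, full Stupp, partial Stupp
  - 0.5376344086021505                 # 150/279
  - 0.20788530465949823                # 58/279
  - 0.25448028673835127                # 71/279
p_mgmt_methylated_given_known: 0.3992248062015504   # 103/258
p_mgmt_missing: 0.07526881720430108                 # 21/279
diameter_median: 4.4
diameter_q1: 3.3
diameter_q3: 5.4
cv_median: 28.1
cv_q1: 12.6
cv_q3: 50.3
wv_median: 103.3
wv_q1: 45.6
wv_q3: 160.1
size_copula_corr:
  - [1.00, 0.90, 0.80]
  - [0.90, 1.00, 0.85]
  - [0.80, 0.85, 1.00]
surgery_size_assoc: 0.4
baseline_shape: 1.0
baseline_scale: 18.0                   # calibrated: marginal KM median OS = 12 months
betas:
  log_wv: 0.226                        # per ln(cm3); ~0.21 per SD of ln(WV)
  age: 0.012
  female: -0.05
  surgery_resection_100: -0.45
  surgery_resection_ge90: -0.25
  surgery_resection_lt90: -0.10
  oncology_full_stupp: -0.55
  oncology_partial_stupp: -0.30
  mgmt_methylated: -0.30
censor_lo: 13.0                        # calibrated: ~236/279 deaths before censoring
censor_hi: 70.0
enforce_nesting: false
seed: 0
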