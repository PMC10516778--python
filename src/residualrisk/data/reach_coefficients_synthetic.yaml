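# SYNTHETIC REACH-style coefficient set (not the published model).
#
# A 20-month recurrent-cardiovascular-event proportional-hazards score for
# secondary-prevention ASCVD patients.  Coefficient signs and magnitudes are
# literature-plausible for this covariate set; the baseline survival and
# reference score are calibrated once against the package's default
# synthetic cohort so the median predicted 10-year risk in the LDL-C >= 70
# mg/dl stratum is ~32% (see docs/methods.md, "Baseline risk engine").
# Replace this file with a transcription of a published coefficient table to
# use a real recalibration; the engine validates the schema on load.
name: reach-style-synthetic-v1
baseline:
  form: survival
  s0: 0.937745            # baseline 20-month event-free probability
  reference_score: 0.6833 # calibrated to the default >=70 stratum median score
terms:
  - name: age
    coefficient: 0.022
    encoding: {kind: linear, field: age, center: 68.3}
  - name: sex
    coefficient: 0.13
    encoding: {kind: categorical, field: sex, levels: {female: 0.0, male: 1.0}}
  - name: smoking
    coefficient: 1.0
    encoding:
      kind: categorical
      field: smoking
      levels: {non: 0.0, ex: 0.10, light: 0.28, moderate: 0.38, heavy: 0.52}
  - name: diabetes
    coefficient: 0.38
    encoding: {kind: indicator, field: diabetes}
  - name: hypertension
    coefficient: 0.12
    encoding: {kind: indicator, field: hypertension}
  - name: chf
    coefficient: 0.48
    encoding: {kind: indicator, field: chf}
  - name: af
    coefficient: 0.30
    encoding: {kind: indicator, field: af}
  - name: event_within_1y
    coefficient: 0.35
    encoding: {kind: indicator, field: event_within_1y}
  - name: ckd_ge3
    coefficient: 0.32
    encoding: {kind: indicator, field: ckd_ge3}
  - name: extra_vascular_beds
    coefficient: 0.28
    encoding: {kind: linear, field: n_vascular_beds, center: 1.0}
  - name: sbp
    coefficient: 0.004
    encoding: {kind: linear, field: sbp, center: 135.0}
  - name: bmi
    coefficient: -0.012
    encoding: {kind: linear, field: bmi, center: 27.8}
  - name: region
    coefficient: 1.0
    encoding:
      kind: categorical
      field: region
      levels: {western_europe: 0.0, eastern_europe: 0.12, other: 0.0}
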