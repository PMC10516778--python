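"""Score one patient with the 20-month risk equation and extrapolate to 10 years.

The equation is a proportional-hazards score over encoded covariates; the
20-month event probability is converted to any horizon assuming a constant
event rate (exponential survival), with 10 years = 120 months.
"""

from residualrisk import (
    AscvdSubtype,
    LLTRegimen,
    PatientRecord,
    Sex,
    Smoking,
    StatinIntensity,
    convert_risk_horizon,
    linear_predictor,
    load_coefficients,
    ten_year_risk,
)

patient = PatientRecord(
    patient_id="example",
    ascvd_subtype=AscvdSubtype.CAD,
    ldl_c=93.0,
    age=68.0,
    sex=Sex.male,
    smoking=Smoking.ex,
    diabetes=True,
    hypertension=True,
    chf=False,
    af=False,
    sbp=135.0,
    dbp=77.0,
    bmi=27.8,
    ckd_ge3=False,
    n_vascular_beds=2,
    event_within_1y=False,
    region="western_europe",
    llt=LLTRegimen(statin_intensity=StatinIntensity.moderate),
)

coeffs = load_coefficients()  # packaged synthetic REACH-style coefficient set
score = linear_predictor(patient, coeffs)
est = ten_year_risk(patient, coeffs)
print(f"linear predictor (log-hazard scale): {score:.3f}")
print(f"20-month event probability: {est.p20:.3f}")
print(f"constant hazard: {est.hazard:.5f} events/month")
print(f"10-year (120-month) risk: {est.p120:.3f}")
print("check: convert_risk_horizon(p20, 20, 120) =",
      round(convert_risk_horizon(est.p20, 20, 120), 3))
print("-> a diabetic ex-smoker with two diseased vascular beds carries a")
print("   10-year recurrent-event risk of roughly 40%, before any LDL-C lowering.")
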