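"""Score one patient record through the clinical rules.

Builds a single female record, computes her BMI class, IDF component
flags, metabolic-syndrome status and Mediterranean Diet Score, and prints
each with the rule it came from.
"""

from olfmap import PatientRecord, classify_idf_flags, classify_mets, compute_bmi, score_mds

record = PatientRecord(
    id="demo-F", sex="F", age=58.0, height=1.60, weight=88.0, wc=103.0,
    sbp=134.0, dbp=82.0, fpg=104.0, hdl=47.0, tg=132.0,
    treated_diabetes=False, treated_dyslipidemia=False,
    treated_hypertension=False, smoker=False,
    mds_components=(4, 3, 5, 4, 3, 2, 4, 2, 3, 1, 4),
    t_score=6.25, d_count=11, i_count=12,
)

bmi, bmi_class = compute_bmi(record.weight, record.height)
flags = classify_idf_flags(record)
mets = classify_mets(flags)
mds_total, mds_high = score_mds(record.mds_components)

print(f"BMI {bmi:.2f} kg/m^2 -> {bmi_class}  (>=25 overweight, >=30 obesity)")
print(f"waist {record.wc} cm elevated: {flags.wc_elevated}  (cut-off 80 cm for women, strict)")
print(f"high BP: {flags.high_bp}  high glucose: {flags.high_gly}  "
      f"high TG: {flags.high_tg}  low HDL: {flags.low_hdl}")
print(f"metabolic syndrome: {mets}  (elevated waist plus >=2 component flags)")
print(f"MDS total {mds_total}/55, high adherence (>=30): {mds_high}")
print(f"TDI = {record.t_score} + {record.d_count} + {record.i_count} = {record.tdi}")
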