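"""Score one day of raw physiology into the six SOFA subscores.

A septic-looking day: low platelets, rising creatinine, ventilated with a
poor oxygenation ratio, and a small norepinephrine dose. Each organ system
contributes 0 (normal) to 4 (failure); the total is their sum.
"""

from icuforecast import DailyPhysiology, score_day

day = DailyPhysiology(
    patient_id="demo", day=3,
    thrombocytes_min=45,      # x10^3/uL  -> coagulation 3
    creatinine_max=2.1,       # mg/dL     -> renal 2
    urine_sum=900,            # mL/24h
    bilirubin_max=1.0,        # mg/dL     -> liver 0
    gcs_min=13,               #           -> CNS 1
    pf_ratio_min=180,         # mm Hg, ventilated -> respiratory 3
    ventilated=True,
    map_mean=68,              # mm Hg
    norepinephrine_max=0.08,  # ug/kg/min -> cardiovascular 3
)

sofa = score_day(day)
print("subscores (coag, renal, liver, cns, resp, cardio):", sofa.as_tuple())
print("total SOFA:", sofa.total)

unmonitored = DailyPhysiology(patient_id="demo", day=4)
print("fully unmonitored day scores", score_day(unmonitored).total,
      "- absent channels mean the organ was judged healthy")
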