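"""Absolute treatment benefit on the competing-risks scale.

Treatment log hazard ratios are external configuration (trial meta-analysis
values shipped in the model file, not estimated from the registry refit);
benefits are differences in the adjusted breast-cancer mortality Rb, shown
cumulatively in the conventional display order (hormone, then chemotherapy).
"""

import predictbc as pb

patient = pb.PatientRecord(age=40, size_mm=15, nodes=2, grade=2, er="pos")
untreated = pb.score_patient(patient, t=10.0)
print(f"10-year breast cancer mortality untreated: {100 * untreated.risk_breast:.1f}%\n")

for step in pb.treatment_benefit(patient, ("hormone", "chemotherapy"), t=10.0):
    print(
        f"+ {step.treatment:13s} (log HR {step.log_hr:+.3f}): "
        f"Rb = {100 * step.risk_breast_treated:5.1f}%, "
        f"gain vs untreated {100 * step.benefit_over_untreated:.1f} per 100 women"
    )

print(
    "\nEach line adds one adjuvant treatment; the gains are absolute reductions\n"
    "in 10-year breast-cancer death risk, so they depend on the patient's own\n"
    "baseline risk, not only on the relative treatment effect."
)
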