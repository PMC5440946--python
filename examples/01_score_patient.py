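"""Score a single patient: prognostic index and 10-year absolute mortality.

A 40-year-old with a 15 mm, grade 2, ER-positive tumour, 2 positive nodes,
clinically detected.  The prognostic index (PI) is the Cox linear predictor;
H_B and H_O are the cause-specific cumulative risks; Rb and Ro adjust each
for the competing cause (Rb = H_B(1-H_O), Ro = H_O(1-H_B)).
"""

import predictbc as pb

patient = pb.PatientRecord(age=40, size_mm=15, nodes=2, grade=2, screen=False, er="pos")
r = pb.score_patient(patient, t=10.0)

print(f"prognostic index PI       : {r.pi:8.4f}")
print(f"other-mortality index MI  : {r.mi:8.4f}")
print(f"H_B (breast, no competing): {r.h_breast:8.4f}")
print(f"H_O (other, no competing) : {r.h_other:8.4f}")
print(f"Rb  (breast, adjusted)    : {r.risk_breast:8.4f}")
print(f"Ro  (other, adjusted)     : {r.risk_other:8.4f}")
print()
print(
    f"Of 100 such women, about {100 * r.risk_breast:.1f} are expected to die "
    f"of breast cancer and {100 * r.risk_other:.1f} of other causes within 10 years."
)
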