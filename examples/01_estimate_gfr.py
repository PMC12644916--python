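"""Estimate GFR for one patient with every registered equation.

A 68-year-old man, 178 cm / 80 kg, creatinine 1.1 mg/dL, cystatin C 1.3 mg/L.
Prints each equation's BSA-indexed estimate (mL/min/1.73 m2) and the absolute
estimate (mL/min) used for drug dosing; Cockcroft-Gault natively returns an
absolute creatinine clearance.
"""

from gfrconcord import Anthropometrics, MarkerPanel, evaluate_all

panel = MarkerPanel(age=68, sex="male", scr=1.1, scys=1.3)
anthro = Anthropometrics(height_cm=178, weight_kg=80)

print(f"BSA (Du Bois): {anthro.bsa:.3f} m2   BMI: {anthro.bmi:.1f} kg/m2\n")
print(f"{'equation':20s} {'indexed':>10s} {'absolute':>10s}")
for r in evaluate_all(panel, anthro):
    indexed = f"{r.egfr_indexed:.1f}" if r.egfr_indexed is not None else "-"
    print(f"{r.equation_id:20s} {indexed:>10s} {r.egfr_nonindexed:>10.1f}")

print("\nCreatinine-based and cystatin-based estimates disagree when the "
      "markers' non-GFR determinants pull in different directions; the "
      "combined (cr-cys) estimates usually sit between them.")
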