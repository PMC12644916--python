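"""Accuracy of each equation against measured GFR on a synthetic cohort.

Simulates 2,000 determinations with the default non-GFR perturbations
(muscle loss lowering creatinine in metastatic disease, inflammation and
glucocorticoids raising cystatin C), then reports P30/P15, median bias and
IQR precision per equation on the absolute (mL/min) scale.
"""

import io

from gfrconcord import (
    DEFAULT_SELECTION, SimulationParams, load_cohort, simulate_cohort, summarize,
)
from gfrconcord.pipeline import apply_equations
from gfrconcord.synthetic import cohort_to_csv

cohort = simulate_cohort(SimulationParams(n=2000, seed=1))
determinations, exclusions = load_cohort(io.StringIO(cohort_to_csv(cohort)))
print(f"{len(determinations)} determinations retained, {len(exclusions)} excluded\n")

egfr = apply_equations(determinations, DEFAULT_SELECTION)
mgfr = determinations["mgfr"].to_numpy()

print(f"{'equation':18s} {'P30%':>6s} {'P15%':>6s} {'bias':>7s} {'IQR':>6s}  grade")
for eq in DEFAULT_SELECTION:
    s = summarize(egfr[f"egfr_{eq}"].to_numpy(), mgfr)
    print(f"{eq:18s} {s.p30:6.1f} {s.p15:6.1f} {s.bias_median:7.2f} "
          f"{s.precision_iqr:6.2f}  {s.p30_grade}/{s.bias_grade}")

print("\nP30/P15: share of estimates within 30%/15% of measured GFR "
      "(>90% P30 is optimal). Bias: median of eGFR - mGFR in mL/min "
      "(positive = overestimation); IQR: spread of those differences. "
      "Creatinine-based equations are biased upward, cystatin-based "
      "downward, and the combined estimates are the most precise.")
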