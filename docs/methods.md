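# Methods

## Problem and design

The package compares GFR-estimating equations against measured GFR (mGFR,
as obtained by iohexol plasma clearance) on a per-determination basis: one
record is one mGFR event with concurrent serum creatinine and cystatin C,
demographics, anthropometrics and cancer context. All agreement statistics
are computed on the absolute (non-indexed, mL/min) scale, which matches the
units of the Calvert dosing formula; BSA-indexed values (mL/min/1.73 m²)
are carried alongside. Repeated determinations of the same person are
treated as independent observations — the statistics are descriptive, and
no within-person clustering adjustment is applied.

## Equations

Eight equations are registered (see README for forms). Conventions that are
genuinely choices rather than published facts:

- **No race coefficient** in any equation.
- **EKFC Q values**: adult constants from age 18 (creatinine Q = 0.70
  mg/dL female / 0.90 mg/dL male; cystatin Q = 0.83 mg/L below age 50,
  0.83 + 0.005·(age − 50) above, sex-independent). The published
  age-interpolated Q for ages 18–25 is not implemented; the intended cohort
  is adults with median age near 70, where it never applies.
- **EKFC 2023 cystatin C is sex-free**; a sex-adjusted Q variant exists in
  the literature but is not implemented here.
- **EKFC 2023 combined** is the arithmetic mean of the EKFC creatinine and
  cystatin estimates, by definition.
- Creatinine unit conversion uses 88.42 µmol/L per mg/dL.
- Equation outputs are never clamped; the 125 mL/min ceiling belongs to the
  dosing step only.

Coefficients are stored in `data/equation_coefficients.csv` (one row per
constant) so they can be audited line by line against the source
publications and new equations can be added without touching evaluator
code.

**Marker inversion.** Every single-marker equation is a strictly decreasing
two-piece power law in the marker, hence a bijection of (0, ∞). The
inverse is computed branch by branch in closed form: the branch is selected
by comparing the target eGFR with the equation's value at its knot
(marker = κ or Q), where both branches coincide. A Brent root-bracketing
fallback guards the closed form; round-trip accuracy is verified to 1e-10
relative in the tests.

## Concordance statistics

- **P30/P15**: inclusive boundaries, |e − m| ≤ tol·m. Because the criterion
  is a ratio it is invariant to de-indexing both members of a pair by the
  same BSA; a test asserts this on random cohorts.
- **Bias** = median(eGFR − mGFR); **precision** = IQR of the differences.
  All quantiles use linear interpolation (the numpy default). The rule
  matters near band edges and is therefore fixed and documented; it is the
  only interpolation convention used anywhere.
- **Grades**: P30 > 90 optimal, 80–90 acceptable (exact 80 and 90 assigned
  to acceptable, i.e. the better class at 80 and the non-optimal class at
  90, following the strict ">90%" reading), < 80 unacceptable. Bias
  |b| ≤ 5 small, ≤ 10 medium, > 10 mL/min large (boundaries to the smaller
  class).
- **Bands**: left-closed [0,30), [30,45), [45,60), [60,90), [90,120),
  [120,∞) mL/min. Contingency tables are row-normalised by mGFR band;
  percent agreement is the diagonal share of raw pair counts, not the mean
  of row percentages.

## Cohort screening

Rules run in a fixed order (schema, lab window, anthropometric window,
diagnosis window, mGFR plausibility) and each excluded row records the
first rule it failed, so exclusion counts are reproducible and sum with the
retained count to the input count. Windows are inclusive: |Δ| ≤ 30 days for
labs and anthropometrics, 0 ≤ mGFR date − diagnosis date ≤ 730 days. The
same-day requirement for the two markers is encoded structurally as a
single shared lab date per row. If both indexed and non-indexed mGFR are
supplied, the non-indexed value wins and the pair must agree within 1% via
the Du Bois BSA, otherwise the row is excluded as implausible.

## Dosing

Achieved AUC is defined through the dose ratio,
`target AUC × dose(eGFR) / dose(mGFR)`, with the 125 mL/min cap applied to
*both* doses by default (`cap_reference=False` switches to an uncapped
physiologic reference, since the original capping behaviour for the
reference dose is ambiguous). Overdose/underdose bounds are strict (> 6,
< 4 mg/mL/min at target 5); note they are multiplicatively asymmetric about
the target (ratios 1.2 and 0.8, whose reciprocals are 0.833 and 1.25), so
swapping estimate and reference maps every underdose to an overdose but
maps an overdose to an underdose only when the achieved AUC exceeds 6.25.
Determinations with mGFR < 30 mL/min are excluded from dosing analyses
(carboplatin contraindicated); their count is reported, not silently
dropped. Rates carry traffic-light labels: Green ≤ 5%, Amber > 5–10%,
Red > 10%.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real registry. Margins (defaults): 38.5% female; age ~ N(68, 9²) years
truncated to [18, 95]; BMI ~ N(25.3, 4.5²) kg/m² truncated to [14, 55];
true GFR ~ N(75, 30²) mL/min truncated to (0, 150]; 17% metastatic, 16.7%
unknown stage; 33.8% glucocorticoid use. Height is drawn per sex
(mean 178 cm male / 165 cm female, SD 7 cm — typical Northern-European
adult values, chosen because the emulated margins specify BMI but not
height) and weight is derived from BMI and height, so BMI has the stated
distribution exactly.

Markers are generated by *inverting* reference equations (defaults:
EKFC 2021 creatinine, EKFC 2023 cystatin C) at the true BSA-indexed GFR and
multiplying by explicit non-GFR factors:

- creatinine × exp(ε_m), ε_m ~ N(δ_m·1{metastatic}, σ_m²) with δ_m = −0.15,
  σ_m = 0.15 — muscle loss lowers creatinine;
- cystatin C × exp(ε_c), ε_c ~ N(δ_c·(1{steroid} + 1{metastatic}), σ_c²)
  with δ_c = +0.12, σ_c = 0.15 — inflammation/steroids raise cystatin C;
- both markers × a lognormal assay error (CV 4%);
- observed mGFR = true GFR × lognormal biologic noise (CV 5%, half the
  ~10% upper bound usually quoted for within-person mGFR variability).

σ_m, σ_c, δ_m, δ_c and the assay CV are tuning constants of the generator,
not estimates of any population; they are sized so that P30 values land in
the realistic 80–95% range. The (true GFR, biologic noise) pair is
rejection-sampled jointly so the *observed* mGFR also falls in (0, 150],
and all dates are emitted on the index date, so default cohorts pass the
eligibility screen with zero exclusions; `messy=True` deliberately injects
one violation of each screening rule into ~10% of rows to exercise the
exclusion log.

**What the idealisation buys and costs.** Because markers come from
inverting the same family of equations later evaluated, "truth" is
attainable: with all noise off, the matched equations (EKFC creatinine,
EKFC cystatin, and their mean) return mGFR exactly, record by record —
P30 = P15 = 100%, zero bias, zero dose errors end-to-end. That makes every
downstream computation testable against an exact identity. The cost is that
accuracy differences between equations on synthetic data are pure functions
of the injected noise plus inter-equation functional differences
(cross-family results, e.g. CKD-EPI equations evaluated on EKFC-generated
markers, include a model-mismatch term). Passing tests therefore
demonstrate that the statistics, screening and dosing machinery are
correct and that the directional error pattern (creatinine-based estimates
biased up, cystatin-based down, combined most precise and least
overdose-prone) follows from the encoded mechanisms — they do not validate
any equation's real-world accuracy, which only registry or trial data can.

## Reproducibility and numerics

Identical generator parameters (including seed, a numpy `default_rng`
seed) give byte-identical cohort tables; identical pipeline input + config
give byte-identical report bundles (no timestamps enter any report; the
manifest carries a SHA-256 of the serialised config). Pattern-recovery
checks run at 5,000 determinations, moment checks at 10,000, end-to-end
identities at 400–1,000 — sizes at which median-based statistics have
standard errors well below the asserted margins. Degenerate inputs are
handled explicitly: empty paired series raise, empty strata are reported
with n = 0, zero-count contingency rows are all-zero rather than NaN.

## Known limitations

- The seven additional supplementary-literature equations (MDRD, FAS,
  Lund-Malmö, CAPA, …) are not implemented; the registry format is the
  extension point.
- No confidence intervals or formal tests between equations; all statistics
  are descriptive, and repeated determinations per person are not
  clustered.
- The generator's non-GFR determinant structure is deliberately synthetic;
  it encodes directions and plausible magnitudes, not an estimated joint
  distribution.
- Pediatric anthropometrics, alternative BSA formulas, and sex-adjusted
  EKFC cystatin Q are out of scope.
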