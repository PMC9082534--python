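"""Externally validate a risk model on a study-sized synthetic cohort.

Simulates a 970-person prison-release cohort with the Tajik validation
case-mix whose true outcome model differs from the scoring model (higher
baseline risk, re-estimated incarceration effects), then reports the full
validation suite: Brier score, AUC with DeLong CI, calibration-in-the-large
(CITL), calibration slope, E:O ratio, and the threshold table.
"""

from oxval import CohortSpec, OutcomeSpec, presets, sample_cohort, simulate_outcomes
from oxval.updating import simple_validation

cohort = sample_cohort(CohortSpec(n=970, seed=11))
truth = presets.tajik_recalibrated_coefficients()
cohort, _ = simulate_outcomes(cohort, OutcomeSpec(true_model=truth, seed=12))

original = presets.sweden_synthetic_coefficients()
_, report = simple_validation(cohort, original)

cal = report.calibration
print(f"n = {report.n}, events = {report.events} "
      f"(incidence {100 * report.incidence:.1f}%)")
print(f"Brier = {report.brier:.3f}   "
      f"AUC = {report.auc:.3f} ({report.auc_ci[0]:.3f}-{report.auc_ci[1]:.3f})")
print(f"CITL = {cal.citl:.3f}   slope = {cal.slope:.3f}   E:O = {cal.eo_ratio:.3f}")
print()
print(report.threshold_markdown())
print("\nA positive CITL and E:O below 1 say the original model "
      "underestimates risk in this population: it needs recalibration.")
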