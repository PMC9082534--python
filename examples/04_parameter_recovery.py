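"""Recover known miscalibration parameters from synthetic outcomes.

Generates outcomes whose true complementary-log-log model applies a known
baseline survival (0.4708) and multiplicative shape (0.8093) to the
original model's linear predictor, then shows the intercept+slope cloglog
refit recovering both — the package's core correctness demonstration.
"""

import math

from oxval import (
    Cohort,
    CohortSpec,
    fit_multiplicative_value,
    linear_predictors,
    presets,
    sample_cohort,
)
import numpy as np

S_TRUE, SHAPE_TRUE = 0.4708, 0.8093

original = presets.sweden_synthetic_coefficients()
cohort = sample_cohort(CohortSpec(n=50_000, seed=31))
lp = linear_predictors(cohort, original)
eta = math.log(-math.log(S_TRUE)) + SHAPE_TRUE * lp
probs = -np.expm1(-np.exp(eta))
rng = np.random.default_rng(32)
df = cohort.data.assign(outcome=(rng.random(len(lp)) < probs).astype(float),
                        outcome_available=True)
cohort = Cohort(df, cohort.schema)

params = fit_multiplicative_value(cohort, original)
print(f"true baseline survival  S = {S_TRUE}   "
      f"recovered S' = {params.baseline_survival:.4f}")
print(f"true multiplicative shape = {SHAPE_TRUE}   "
      f"recovered    = {params.shape:.4f}")
print("\nBoth recovered values should sit within Monte-Carlo error of the "
      "truth at this sample size.")
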