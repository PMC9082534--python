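# Methods

## Model form

A coefficient set parameterises a fixed-horizon (default 1-year) binary
outcome model

    risk = 1 − S^exp(λ·LP),        LP = Σ β·RF + Σⱼ βⱼ·mⱼ

with baseline survival `S ∈ (0,1)` (the event-free probability of an
individual with `LP = 0`), a multiplicative recalibration shape `λ > 0`,
predictor coefficients `β` (categorical predictors carry one coefficient
per non-reference level; the declared first level is the reference with
implicit 0), and a mean-imputation constant `Σⱼ βⱼ·mⱼ` for predictors that
the validation setting cannot collect: assigning every individual the
derivation-sample mean `mⱼ` collapses the predictor's contribution to a
constant shift of `LP`, identical across individuals.

The outcome is modelled as a fixed-horizon binary event, not time-to-event:
the validation design follows everyone for the same 12 months and analyses
complete cases (individuals with an observed outcome), so censoring
machinery adds nothing here.  The form is the discrete-horizon analogue of
a survival model evaluated at the horizon, which is why it is linear on
the complementary log-log scale:

    cloglog(risk) = log(−log(1−risk)) = log(−log S) + λ·LP.

`λ` multiplies the *entire* linear predictor, including the imputed
constant and (after selective re-estimation) the refitted dummies, which
sit inside the λ-multiplied bracket as `γ/λ`; this keeps every updated
model expressible — and exactly round-trippable — in the same
`1 − S^exp(λ·LP)` form.

## Performance measures

* **Brier score** — mean squared difference between predicted probability
  and outcome; the constant-prevalence predictor scores `prev·(1−prev)`.
* **Discrimination** — the c-index computed by midrank concordance
  (ties ½), which equals the trapezoidal ROC area.  The 95% CI uses the
  DeLong placement-variance estimator with a normal approximation,
  truncated to [0,1]; a zero variance (e.g. perfect separation) collapses
  the interval onto the point estimate.  A stratified percentile bootstrap
  with seeded RNG is available as an alternative.  Inside the updating
  ladder, reports rank the c-index on the linear predictor rather than the
  transformed risks: the ordering is identical in exact arithmetic, and
  ranking on `LP` avoids spurious 1e−5-scale AUC movement caused by
  floating-point ties when a discrete coefficient grid makes distinct
  predictor patterns real-equal in `LP` but one ulp apart.
* **Calibration** — CITL is the intercept of a maximum-likelihood logistic
  regression of outcomes on `logit(risk)` with the slope pinned at 1
  (offset formulation); the calibration slope is the coefficient of
  `logit(risk)` with free intercept; E:O is `Σ risk / Σ outcome`; the
  calibration curve uses 10 quantile bins (deciles) formed by stable rank
  order, so boundary ties resolve deterministically.
* **Threshold metrics** — classification at `risk ≥ t` (boundary counts
  positive) for prespecified thresholds, default 5/10/15/20%; sensitivity,
  specificity, PPV and NPV carry Wilson score 95% intervals, which behave
  sensibly at boundary counts; empty denominators are reported as missing
  with an `undefined` flag rather than silently dropped.  Whole-percent
  rounding happens only in the Markdown presentation layer; stored values
  keep full precision.

Risks are clipped to `[1e−10, 1−1e−10]` before any logit/cloglog
transform; no boundary risks arise from finite linear predictors, but
file-supplied risks might.

## The updating ladder

Because the model is linear on the cloglog scale, every updating stage is
a binomial GLM with cloglog link fitted on the validation cohort (IRLS via
statsmodels, tolerance 1e−8, at most 100 iterations; non-convergence or
coefficient blow-up — a separation symptom — raises with diagnostics):

1. **simple** — no refit; the original model is applied and reported.
2. **baseline** — intercept-only refit with `λ·LP` as offset; the new
   baseline survival is `S′ = exp(−exp(a))`.  The cloglog score equation
   balances a *weighted* residual, so the post-update E:O is close to but
   not exactly 1 (≈±0.003 at n = 50,000 in our simulations); the mean
   predicted risk matches the observed incidence to ~1e−3.
3. **slope** — intercept + slope refit on `LP`, yielding `S′` and the
   single multiplicative recalibration value `λ′`.
4. **selective** — intercept, slope on the *partial* linear predictor
   (full `LP` minus the chosen predictor's contribution) and free dummy
   coefficients for the chosen categorical predictor's non-reference
   levels.

Stages 1–3 are monotone transforms of an unchanged `LP`: they repair
calibration and cannot change the rank order of predictions or the AUC.
Stage 4 can.  Each stage's model nests the previous one, so the in-sample
log-likelihood is non-decreasing along the ladder.  Updating is fitted and
reported in-sample (the standard practice this workflow mirrors); nothing
prevents the caller from fitting on one cohort and reporting on another,
since stages accept any conforming cohort.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
matching the published 970-person Tajik validation cohort:

* Predictors are sampled **independently** from categorical/binary
  marginals derived from the published baseline-table counts (e.g. 13%
  female, 63% violent index offence, 8% previous violent crime, 85.8% in
  the ≥24-month incarceration band).  Real risk factors are correlated;
  only marginals are published, so no dependence structure is imposed.
  Consequences for interpretation: passing tests demonstrate correct
  *estimation* under the stated case-mix, not robustness to predictor
  correlation.
* Age bands (18–29 / 30–39 / ≥40, probabilities 0.30 / 0.38 / 0.32) were
  chosen once to match the published median 35 (IQR 28–43); banded age is
  used throughout because the original model's functional form for age is
  not public.
* Outcomes are Bernoulli draws from a true model distorted on the cloglog
  scale: `cloglog(p) = log(−log S) + δ₀ + δ₁·λ·LP*`, where `δ₀` shifts the
  baseline, `δ₁ > 0` distorts the slope and `LP*` may use per-predictor
  coefficient overrides — the three axes along which transported models
  fail (incidence, effect strength, individual effects).  True
  per-individual risks are returned out-of-band so test oracles never leak
  into the cohort file format.
* Outcome missingness marks a seeded Bernoulli subset as unobserved
  (expected count `rate·n`, matching the study's 33 of 1,003); validation
  then uses complete cases.
* An effective-sample-size helper warns when min(events, nonevents) < 100,
  the conventional rule of thumb for validation cohorts.
* All randomness flows from explicit integer seeds; there is no global RNG
  state, and regeneration is byte-identical.

The shipped predictor weights are synthetic stand-ins (the original
Swedish weights are user-supplied configuration).  They were fixed once so
that the implied 1-year incidence is realistic (~13% under the
approximate derivation case-mix, ~16% under the validation case-mix) and
so that scoring the validation case-mix with the original-model fixture
underestimates risk — the direction observed in the study this workflow
models.  The published constants (S = 0.7992 and 0.4708, λ = 0.8093, the
two imputation terms, the re-estimated incarceration dummies) are carried
verbatim in the fixtures.

## Numerical choices

* Risk evaluation uses `−expm1(exp(λ·LP)·log S)` for stability at extreme
  linear predictors; risks saturate at exactly 0/1 in double precision
  beyond |λ·LP| ≈ 5, where strict monotonicity necessarily degrades to
  weak.
* Quantile bins split the stable argsort into near-equal groups
  (`array_split`), so `n` not divisible by the bin count distributes the
  remainder deterministically.
* Wilson intervals come from statsmodels `proportion_confint`; GLMs from
  statsmodels with the default IRLS.
* Thresholds are validated to be strictly ascending in (0,1); rows in the
  threshold table are always emitted in ascending order.

## Problem sizes and known limitations

Simulation-based tests use n = 50,000 with 20 seed replicates for
parameter-recovery checks and n = 100,000 × 20 seeds for marginal
recovery; these sizes put Monte-Carlo error well inside the asserted
tolerances (e.g. the cloglog slope's standard error is ≈0.014 at
n = 50,000 under the default case-mix).

The selective re-estimation of incarceration-band coefficients is weakly
identified under the validation case-mix: the reference band (<6 months)
covers only ~0.3% of individuals, so a 50,000-person draw contains ~150
reference individuals and a handful of reference events.  Per-draw dummy
estimates therefore carry a joint offset with standard deviation ≈0.4–0.8
and a finite-sample MLE bias of order +0.1–0.2; recovery is demonstrated
on averages over seed replicates (with the cohort redrawn per replicate so
the reference-band composition also averages).  This mirrors the real
difficulty of re-estimating a predictor whose reference category is nearly
empty in the validation population.

Other limitations: no time-to-event structure (no censoring, no 2-year
horizon); no sex-stratified validation; predictor independence in the
generator as noted above; recalibration assumes the validation outcome is
exchangeable with Bernoulli draws from some cloglog-linear model in `LP` —
genuine link misspecification is only partially absorbed by `λ′`.
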