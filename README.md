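# oxval

External validation and recalibration of fixed-horizon recidivism risk
models of the OxRec family.

## The problem

Structured risk assessment tools such as OxRec estimate the probability
that a person released from prison will be reimprisoned for a violent
offence within a fixed horizon (here 1 year), from routinely collected
risk factors: criminal history (length of incarceration, violent index
offence, previous violent crime), sociodemographic items (sex, age, civil
status, education, employment, income, immigrant status, neighbourhood
deprivation) and clinical items (alcohol misuse, drug misuse, mental
disorder).  Such tools are developed in one population and must be
*externally validated* — and usually *recalibrated* — before use in
another, because case-mix, outcome incidence and predictor effects all
shift between settings.

`oxval` implements that whole workflow as a library (plus a thin CLI), for
analysts validating a risk model in a new cohort:

* **Scoring** (`oxval.model_core`): risk in the baseline-survival form

  ```
  risk = 1 − S^exp(λ·LP),   LP = Σ β·RF + Σⱼ βⱼ·mⱼ
  ```

  where `S` is the baseline event-free probability at `LP = 0`, `λ` a
  multiplicative recalibration shape, and the constant `Σⱼ βⱼ·mⱼ` mean-imputes
  predictors unavailable in the validation setting.  On the complementary
  log-log scale the model is exactly linear:
  `cloglog(risk) = log(−log S) + λ·LP`.

* **Performance measures** (`oxval.metrics`): Brier score; AUC / c-index
  (midrank concordance) with a DeLong 95% CI (seeded bootstrap optional);
  calibration-in-the-large (CITL), calibration slope, E:O ratio and decile
  calibration bins; sensitivity / specificity / PPV / NPV with Wilson 95%
  intervals at prespecified risk thresholds (default 5/10/15/20%).

* **Model updating** (`oxval.updating`): the incremental ladder —
  *simple validation* → *baseline-risk update* (refit `S`) → *single
  multiplicative recalibration value* (refit `S` and `λ`) → *selective
  re-estimation* of one predictor's coefficients — each stage a binomial
  GLM with cloglog link, emitting a new coefficient set in the same
  `1 − S^exp(λ·LP)` form.

* **Synthetic cohorts** (`oxval.synthetic`): cohorts with configurable
  predictor marginals (defaults follow the published baseline table of a
  970-person Tajik prison-release validation cohort) and outcomes drawn
  from a true model with injectable miscalibration (baseline shift, slope
  distortion, per-predictor coefficient overrides), so every pipeline
  stage is testable end to end with known ground truth.

The shipped fixture coefficient sets carry the published constants of the
Tajik OxRec validation (baseline survival 0.7992 original / 0.4708
recalibrated, shape 0.8093, mean-imputation terms, re-estimated
incarceration-band coefficients −0.0098 / 0.5949 / −0.1066); the remaining
predictor weights are clearly-labelled synthetic stand-ins, since the
original Swedish weights are supplied by the user as configuration.

## Worked example

```python
from oxval import CohortSpec, OutcomeSpec, presets, sample_cohort, simulate_outcomes
from oxval.updating import simple_validation

cohort = sample_cohort(CohortSpec(n=970, seed=11))
truth = presets.tajik_recalibrated_coefficients()
cohort, _ = simulate_outcomes(cohort, OutcomeSpec(true_model=truth, seed=12))
_, report = simple_validation(cohort, presets.sweden_synthetic_coefficients())
```

Running `python examples/02_external_validation.py` (the script behind the
snippet) prints:

```
n = 970, events = 171 (incidence 17.6%)
Brier = 0.147   AUC = 0.703 (0.660-0.746)
CITL = 1.291   slope = 0.718   E:O = 0.367
```

The original model discriminates well (AUC 0.70) but the positive CITL and
E:O far below 1 show it underestimates risk in this population — the
signature that recalibration is needed.  `examples/03_recalibration_ladder.py`
then runs the updating ladder on deliberately distorted data:

```
| Stage     | S'     | shape  | AUC   | CITL  | Slope | Brier  | E:O   |
| simple    | 0.7992 | 1.0000 | 0.721 | 0.429 | 0.778 | 0.0746 | 0.697 |
| baseline  | 0.7215 | 1.0000 | 0.721 | 0.023 | 0.758 | 0.0744 | 0.981 |
| slope     | 0.7681 | 0.7646 | 0.721 | 0.001 | 1.002 | 0.0738 | 0.999 |
| selective | 0.6308 | 0.7825 | 0.729 | 0.001 | 1.003 | 0.0732 | 0.999 |
```

Calibration is restored (CITL → 0, slope → 1, E:O → 1) without touching
discrimination until the selective stage, which alone may change the AUC.
`examples/04_parameter_recovery.py` shows the refit recovering a known
truth (S = 0.4708, shape = 0.8093) within Monte-Carlo error.

A command-line pipeline wraps the same functions:

```bash
oxval simulate --n 970 --seed 1 --out-cohort cohort.csv --out-truth truth.json
oxval score    --cohort cohort.csv --coefficients model.json --out scored.csv
oxval validate --cohort cohort.csv --coefficients model.json --out-dir report/
oxval update   --cohort cohort.csv --coefficients model.json --out-dir ladder/
```

## File formats

* **Cohort CSV** — `id`, one column per predictor (level names as strings,
  binaries as 0/1), `outcome` (0/1, empty when unobserved),
  optional `outcome_available`.
* **Coefficient JSON** — `label`, `horizon_years`, `baseline_survival`,
  `recalibration_shape`, `coefficients` (predictor → value, or
  predictor → level → value with the reference level omitted),
  `imputed_terms` (predictor → `{beta, mean}`), `schema`.
* **Reports** — full-precision JSON, a Markdown threshold table
  (whole-percent presentation) and a calibration-bin TSV.

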