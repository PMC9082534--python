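"""Reference schema, cohort summaries and fixture coefficient sets.

The default predictor schema follows the OxRec risk-factor list: criminal
history (length of incarceration, violent index offense, previous violent
crime), sociodemographic (sex, age, civil status, education, employment,
income, plus the imputable immigrant status and neighbourhood deprivation)
and clinical items (alcohol misuse, drug misuse, any mental disorder, any
severe mental disorder).  For every categorical predictor the first level
is the reference.

``TAJIK_TABLE1`` holds the published baseline counts of the Tajik
validation cohort (n = 970); marginal presets for the synthetic-cohort
generator are derived from these counts, so the generator's defaults match
the validation cohort's case-mix.

The predictor weights in the fixture coefficient sets are SYNTHETIC
stand-ins: the original Swedish OxRec weights are not public here and are
expected to arrive via a user-supplied coefficient JSON.  The baseline
survival values (0.7992 Sweden, 0.4708 recalibrated), the multiplicative
recalibration shape 0.8093, the mean-imputation terms for the two omitted
predictors, and the re-estimated prison-duration dummies (−0.0098, 0.5949,
−0.1066) are the published constants.  The synthetic weights were chosen
once so that the implied 1-year incidence is realistic (~13% under the
Swedish case-mix, ~17% under the Tajik case-mix) and so that scoring the
Tajik case-mix with the original-model fixture underestimates risk, the
direction observed in the validation study.
"""

from __future__ import annotations

from .model_core import (
    CoefficientSet,
    ImputedTerm,
    Predictor,
    PredictorSchema,
)

__all__ = [
    "TAJIK_TABLE1",
    "COHORT_FLOW",
    "default_schema",
    "tajik_marginals",
    "sweden_marginals",
    "sweden_synthetic_coefficients",
    "tajik_recalibrated_coefficients",
    "TAJIK_PRISON_DUMMIES",
    "IMPUTED_TERMS",
]

# Published baseline characteristics of the Tajik validation cohort
# (counts out of n = 970 complete cases).
TAJIK_TABLE1: dict[str, dict[str, int]] = {
    "sex": {"male": 846, "female": 124},
    "length_of_incarceration": {"lt6m": 3, "6to12m": 13, "12to24m": 122, "ge24m": 832},
    "violent_index_offense": {"no": 362, "yes": 608},
    "previous_violent_crime": {"no": 894, "yes": 76},
    "civil_status": {"other": 578, "unmarried": 392},
    "education": {"lt9y": 57, "9to11y": 784, "ge12y": 129},
    "employment": {"unemployed": 345, "employed": 625},
    "income": {"low": 423, "stable": 547},
    "alcohol_misuse": {"no": 612, "yes": 358},
    "drug_misuse": {"no": 886, "yes": 84},
    "any_mental_disorder": {"no": 500, "yes": 470},
    "any_severe_mental_disorder": {"no": 926, "yes": 44},
}

# Participant flow of the validation study: consented individuals, those
# with missing 1-year outcome data, the resulting complete-case sample,
# and observed violent-reoffending events within 1 year.
COHORT_FLOW = {
    "consented": 1003,
    "outcome_missing": 33,
    "final_n": 970,
    "events": 144,
}

# Published recalibration constants (complementary log-log scale model).
TAJIK_BASELINE_SURVIVAL = 0.4708
SWEDEN_BASELINE_SURVIVAL = 0.7992
TAJIK_SHAPE = 0.8093
TAJIK_PRISON_DUMMIES = {"6to12m": -0.0098, "12to24m": 0.5949, "ge24m": -0.1066}
IMPUTED_TERMS = {
    "immigrant_status": ImputedTerm(beta=-0.0348, mean=0.3075),
    "neighborhood_deprivation": ImputedTerm(beta=0.0259, mean=0.39),
}

_AGE_BANDS = ("18to29", "30to39", "ge40")


def default_schema() -> PredictorSchema:
    """The 14-predictor schema with age in bands (reference = youngest).

    Immigrant status and neighbourhood deprivation are ``required=False``:
    unavailable in the validation setting and handled by mean imputation.
    """
    return PredictorSchema(
        (
            Predictor("sex", "categorical", ("male", "female")),
            Predictor("age", "categorical", _AGE_BANDS),
            Predictor(
                "length_of_incarceration",
                "categorical",
                ("lt6m", "6to12m", "12to24m", "ge24m"),
            ),
            Predictor("violent_index_offense", "binary"),
            Predictor("previous_violent_crime", "binary"),
            Predictor("civil_status", "categorical", ("other", "unmarried")),
            Predictor("education", "categorical", ("lt9y", "9to11y", "ge12y")),
            Predictor("employment", "categorical", ("unemployed", "employed")),
            Predictor("income", "categorical", ("low", "stable")),
            Predictor("alcohol_misuse", "binary"),
            Predictor("drug_misuse", "binary"),
            Predictor("any_mental_disorder", "binary"),
            Predictor("any_severe_mental_disorder", "binary"),
            Predictor("immigrant_status", "binary", required=False),
            Predictor("neighborhood_deprivation", "continuous", required=False),
        )
    )


def tajik_marginals() -> dict:
    """Predictor marginals of the Tajik validation cohort.

    Categorical/binary marginals are the ``TAJIK_TABLE1`` counts divided by
    n = 970.  Age bands are not published as counts (only median 35,
    IQR 28–43); the band probabilities below were chosen once to match that
    summary.
    """
    n = COHORT_FLOW["final_n"]
    margs: dict = {}
    for name, counts in TAJIK_TABLE1.items():
        if set(counts) == {"no", "yes"}:  # binary predictor: P(flag = 1)
            margs[name] = counts["yes"] / n
        else:
            margs[name] = {level: c / n for level, c in counts.items()}
    margs["age"] = {"18to29": 0.30, "30to39": 0.38, "ge40": 0.32}
    return margs


def sweden_marginals() -> dict:
    """Approximate derivation-cohort marginals (labelled approximate).

    The published derivation summary prints five income bands; this preset
    collapses them onto the two-band validation schema (negative/zero/low
    -> low, medium/high -> stable), hence "approx".
    """
    return {
        "sex": {"male": 0.93, "female": 0.07},
        "age": {"18to29": 0.28, "30to39": 0.34, "ge40": 0.38},
        "length_of_incarceration": {
            "lt6m": 0.69,
            "6to12m": 0.16,
            "12to24m": 0.10,
            "ge24m": 0.05,
        },
        "violent_index_offense": 0.38,
        "previous_violent_crime": 0.53,
        "civil_status": {"other": 0.35, "unmarried": 0.65},
        "education": {"lt9y": 0.48, "9to11y": 0.46, "ge12y": 0.06},
        "employment": {"unemployed": 0.75, "employed": 0.25},
        "income": {"low": 0.60, "stable": 0.40},
        "alcohol_misuse": 0.22,
        "drug_misuse": 0.23,
        "any_mental_disorder": 0.22,
        "any_severe_mental_disorder": 0.03,
    }


# Synthetic predictor weights shared by both fixture coefficient sets
# (see module docstring: stand-ins, not the published Swedish weights).
_SYNTHETIC_BETAS = {
    "sex": {"female": -0.60},
    "age": {"30to39": -0.55, "ge40": -1.15},
    "violent_index_offense": 0.15,
    "previous_violent_crime": 0.90,
    "civil_status": {"unmarried": 0.20},
    "education": {"9to11y": -0.85, "ge12y": -1.20},
    "employment": {"employed": -1.35},
    "income": {"stable": -0.60},
    "alcohol_misuse": 0.35,
    "drug_misuse": 0.55,
    "any_mental_disorder": 0.30,
    "any_severe_mental_disorder": 0.40,
}

_SWEDEN_PRISON_DUMMIES = {"6to12m": 0.10, "12to24m": 0.25, "ge24m": 0.40}


def sweden_synthetic_coefficients() -> CoefficientSet:
    """Original-model fixture: published S = 0.7992, shape 1, synthetic
    predictor weights (the true Swedish weights are config input, not
    shipped)."""
    coeffs = dict(_SYNTHETIC_BETAS)
    coeffs["length_of_incarceration"] = dict(_SWEDEN_PRISON_DUMMIES)
    return CoefficientSet(
        schema=default_schema(),
        baseline_survival=SWEDEN_BASELINE_SURVIVAL,
        coefficients=coeffs,
        recalibration_shape=1.0,
        imputed_terms=dict(IMPUTED_TERMS),
        label="sweden-synthetic",
        horizon_years=1.0,
    )


def tajik_recalibrated_coefficients() -> CoefficientSet:
    """Recalibrated-model fixture: published S = 0.4708, shape 0.8093 and
    re-estimated prison-duration dummies; other weights are the same
    synthetic stand-ins as :func:`sweden_synthetic_coefficients`."""
    coeffs = dict(_SYNTHETIC_BETAS)
    coeffs["length_of_incarceration"] = dict(TAJIK_PRISON_DUMMIES)
    return CoefficientSet(
        schema=default_schema(),
        baseline_survival=TAJIK_BASELINE_SURVIVAL,
        coefficients=coeffs,
        recalibration_shape=TAJIK_SHAPE,
        imputed_terms=dict(IMPUTED_TERMS),
        label="tajikistan-recalibrated",
        horizon_years=1.0,
    )
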