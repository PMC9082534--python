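"""Synthetic prison-release cohorts for end-to-end pipeline testing.

The generator emulates the statistical structure the validation analysis
assumes: predictors drawn independently from configurable categorical
marginals (defaults = the Tajik validation cohort's case-mix), and binary
1-year outcomes drawn from a configurable true risk model on the
complementary log-log scale with injectable miscalibration along the three
axes that break model transportability — outcome incidence (baseline
shift), predictor-effect strength (slope distortion) and individual
predictor effects (coefficient overrides):

    cloglog(true risk) = log(-log S) + delta0 + delta1 * lambda * lp*

where ``lp*`` uses the override coefficients where present.  True
per-individual risks are returned out-of-band so tests can compute oracle
quantities without polluting the cohort file format.

All randomness flows from explicit integer seeds; no global RNG state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model_core import (
    CoefficientSet,
    Cohort,
    ImputedTerm,
    Predictor,
    PredictorSchema,
    ValidationError,
    linear_predictors,
)
from .presets import default_schema, tajik_marginals

__all__ = [
    "CohortSpec",
    "OutcomeSpec",
    "sample_cohort",
    "simulate_outcomes",
    "apply_outcome_missingness",
    "make_worked_fixture",
    "check_events_rule",
    "EVENTS_RULE_MIN",
]

# Conventional effective-sample-size rule for external validation studies:
# at least 100 events or non-events (whichever is less frequent).
EVENTS_RULE_MIN = 100


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic cohort's case-mix.

    ``marginals`` maps a categorical predictor to ``{level: probability}``
    and a binary predictor to ``P(flag = 1)``.  Defaults to the Tajik
    validation-cohort marginals.
    """

    n: int
    marginals: Mapping = field(default_factory=tajik_marginals)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        for name, marg in self.marginals.items():
            if isinstance(marg, Mapping):
                total = float(sum(marg.values()))
                if abs(total - 1.0) > 1e-9:
                    raise ValidationError(
                        f"marginal for {name!r} sums to {total}, not 1"
                    )
                if any(p < 0 for p in marg.values()):
                    raise ValidationError(f"negative probability in {name!r}")
            else:
                if not (0.0 <= float(marg) <= 1.0):
                    raise ValidationError(f"binary marginal for {name!r} not in [0,1]")


def sample_cohort(spec: CohortSpec, schema: PredictorSchema | None = None) -> Cohort:
    """Draw ``spec.n`` records with mutually independent predictors.

    Deterministic for a fixed seed.  Outcomes are left unobserved; attach
    them with :func:`simulate_outcomes`.
    """
    schema = schema or default_schema()
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n)))
    data: dict = {"id": [f"r{i:0{width}d}" for i in range(1, spec.n + 1)]}
    for pred in schema:
        if pred.name not in spec.marginals:
            if pred.required:
                raise ValidationError(f"no marginal given for required {pred.name!r}")
            continue
        marg = spec.marginals[pred.name]
        if pred.kind == "categorical":
            if not isinstance(marg, Mapping):
                raise ValidationError(f"{pred.name!r} needs a level->probability map")
            unknown = set(marg) - set(pred.levels)
            if unknown:
                raise ValidationError(f"{pred.name!r}: unknown levels {sorted(unknown)}")
            levels = list(marg)
            probs = np.array([marg[l] for l in levels], dtype=float)
            data[pred.name] = rng.choice(levels, size=spec.n, p=probs)
        elif pred.kind == "binary":
            data[pred.name] = (rng.random(spec.n) < float(marg)).astype(int)
        else:
            raise ValidationError(
                f"continuous predictor {pred.name!r} has no sampler; "
                "supply values directly"
            )
    df = pd.DataFrame(data)
    df["outcome"] = np.nan
    df["outcome_available"] = False
    return Cohort(df, schema)


@dataclass(frozen=True)
class OutcomeSpec:
    """True outcome model plus miscalibration distortions.

    ``baseline_shift`` (delta0) adds to the cloglog intercept,
    ``slope_factor`` (delta1, > 0) multiplies the linear predictor, and
    ``coefficient_overrides`` replaces chosen predictors' coefficients in
    the truth (same nested layout as ``CoefficientSet.coefficients``).
    """

    true_model: CoefficientSet
    baseline_shift: float = 0.0
    slope_factor: float = 1.0
    coefficient_overrides: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.slope_factor > 0:
            raise ValidationError("slope_factor must be positive")


def true_risks(cohort: Cohort, spec: OutcomeSpec) -> np.ndarray:
    """Per-individual true event probabilities under the distorted model."""
    model = spec.true_model
    if spec.coefficient_overrides:
        coeffs = {
            name: (dict(v) if isinstance(v, Mapping) else v)
            for name, v in model.coefficients.items()
        }
        for name, v in spec.coefficient_overrides.items():
            coeffs[name] = dict(v) if isinstance(v, Mapping) else v
        model = model.replace(coefficients=coeffs)
    lp = linear_predictors(cohort, model)
    eta = (
        math.log(-math.log(model.baseline_survival))
        + spec.baseline_shift
        + spec.slope_factor * model.recalibration_shape * lp
    )
    risk = -np.expm1(-np.exp(eta))
    if not np.isfinite(risk).all():
        bad = int(np.flatnonzero(~np.isfinite(risk))[0])
        raise ValidationError(f"non-finite true risk for record {cohort.ids[bad]!r}")
    if ((risk <= 0) | (risk >= 1)).any():
        bad = int(np.flatnonzero((risk <= 0) | (risk >= 1))[0])
        raise ValidationError(f"degenerate true risk for record {cohort.ids[bad]!r}")
    return risk


def simulate_outcomes(cohort: Cohort, spec: OutcomeSpec) -> tuple[Cohort, np.ndarray]:
    """Draw Bernoulli outcomes from the true risks.

    Returns the cohort with observed outcomes plus the truth vector
    (kept out of the cohort so file round-trips never leak it).
    """
    risk = true_risks(cohort, spec)
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(len(cohort)) < risk).astype(float)
    df = cohort.data.copy()
    df["outcome"] = y
    df["outcome_available"] = True
    return Cohort(df, cohort.schema), risk


def apply_outcome_missingness(cohort: Cohort, rate: float, seed: int = 0) -> Cohort:
    """Mark a seeded random subset (expected size ``rate * n``) as having
    unobserved outcomes; downstream validation uses complete cases only."""
    if not (0.0 <= rate < 1.0):
        raise ValidationError(f"missingness rate must lie in [0, 1), got {rate}")
    if rate == 0.0:
        return cohort
    rng = np.random.default_rng(seed)
    missing = rng.random(len(cohort)) < rate
    df = cohort.data.copy()
    df.loc[missing, "outcome"] = np.nan
    df.loc[missing, "outcome_available"] = False
    df["outcome_available"] = df["outcome_available"].astype(bool)
    return Cohort(df, cohort.schema)


def check_events_rule(events: int, nonevents: int) -> bool:
    """Effective-sample-size check: warn when min(events, nonevents) < 100.

    Returns True when the rule is satisfied.
    """
    smallest = min(int(events), int(nonevents))
    if smallest < EVENTS_RULE_MIN:
        warnings.warn(
            f"only {smallest} {'events' if events <= nonevents else 'nonevents'}; "
            f"the {EVENTS_RULE_MIN}-events rule of thumb for validation "
            "cohorts is not met",
            UserWarning,
            stacklevel=2,
        )
        return False
    return True


def make_worked_fixture() -> tuple[Cohort, CoefficientSet]:
    """Deterministic 12-record cohort + tiny coefficient set with
    hand-computable linear predictors and risks, for regression tests.

    The schema is a 3-predictor miniature (incarceration bands, previous
    violent crime, alcohol misuse) with one imputed term; every
    incarceration band is represented.
    """
    schema = PredictorSchema(
        (
            Predictor(
                "length_of_incarceration",
                "categorical",
                ("lt6m", "6to12m", "12to24m", "ge24m"),
            ),
            Predictor("previous_violent_crime", "binary"),
            Predictor("alcohol_misuse", "binary"),
            Predictor("immigrant_status", "binary", required=False),
        )
    )
    coefs = CoefficientSet(
        schema=schema,
        baseline_survival=0.80,
        coefficients={
            "length_of_incarceration": {"6to12m": 0.1, "12to24m": 0.2, "ge24m": 0.3},
            "previous_violent_crime": 0.5,
            "alcohol_misuse": 0.25,
        },
        recalibration_shape=1.0,
        imputed_terms={"immigrant_status": ImputedTerm(beta=-0.01, mean=0.5)},
        label="worked-fixture",
    )
    bands = ["lt6m", "6to12m", "12to24m", "ge24m"] * 3
    prev = [0, 1] * 6
    alco = [0, 0, 1, 1] * 3
    outc = [0, 1, 0, 0, 1, 0, 1, 0, 0, 1, 1, 0]
    df = pd.DataFrame(
        {
            "id": [f"f{i:02d}" for i in range(1, 13)],
            "length_of_incarceration": bands,
            "previous_violent_crime": prev,
            "alcohol_misuse": alco,
            "outcome": [float(v) for v in outc],
            "outcome_available": True,
        }
    )
    return Cohort(df, schema), coefs
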