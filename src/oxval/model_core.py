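"""Risk-model representation and scoring.

A coefficient set parameterises a fixed-horizon binary-outcome risk model of
the form

    risk = 1 - S ** exp(lambda * lp),      lp = sum(beta * RF) + offset

where ``S`` is the baseline survival (event-free probability at lp = 0 for
the model horizon), ``lambda`` a multiplicative recalibration shape applied
to the whole linear predictor, and ``offset`` a constant absorbing
mean-imputed predictors that are unavailable in the validation setting
(each contributes ``beta_j * mean_j``).

On the complementary log-log scale the model is exactly linear,

    cloglog(risk) = log(-log(S)) + lambda * lp,

which is the algebraic bridge the :mod:`oxval.updating` ladder exploits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "Predictor",
    "PredictorSchema",
    "ImputedTerm",
    "CoefficientSet",
    "Cohort",
    "PredictionResult",
    "imputed_offset",
    "linear_predictor",
    "linear_predictors",
    "predict_risk",
    "score_cohort",
    "clip_probabilities",
    "coefficient_set_from_dict",
    "coefficient_set_to_dict",
    "load_coefficient_set",
    "save_coefficient_set",
    "load_cohort",
    "save_cohort",
]

PROB_EPS = 1e-10  # clip bound for probabilities entering logit/cloglog


class SchemaError(ValueError):
    """A record or coefficient refers to a predictor/level the schema lacks."""


class ValidationError(ValueError):
    """A coefficient set or cohort violates a structural invariant."""


@dataclass(frozen=True)
class Predictor:
    """One risk factor definition.

    For categorical predictors the first level is the reference and carries
    an implicit coefficient of zero.  ``required=False`` marks predictors
    that may be absent from the cohort (handled by mean imputation).
    """

    name: str
    kind: str  # "binary" | "categorical" | "continuous"
    levels: tuple[str, ...] = ()
    required: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValidationError(f"predictor {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValidationError(
                    f"categorical predictor {self.name!r} needs >= 2 levels"
                )
            if len(set(self.levels)) != len(self.levels):
                raise ValidationError(f"predictor {self.name!r}: duplicate levels")
        elif self.levels:
            raise ValidationError(
                f"predictor {self.name!r}: levels only allowed for categorical kind"
            )

    @property
    def reference(self) -> str | None:
        return self.levels[0] if self.kind == "categorical" else None


@dataclass(frozen=True)
class PredictorSchema:
    """Ordered collection of predictor definitions with unique names."""

    predictors: tuple[Predictor, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ValidationError("predictor names must be unique")

    def __iter__(self):
        return iter(self.predictors)

    def __contains__(self, name: str) -> bool:
        return any(p.name == name for p in self.predictors)

    def __getitem__(self, name: str) -> Predictor:
        for p in self.predictors:
            if p.name == name:
                return p
        raise SchemaError(f"unknown predictor {name!r}")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.predictors]

    @property
    def required_names(self) -> list[str]:
        return [p.name for p in self.predictors if p.required]


@dataclass(frozen=True)
class ImputedTerm:
    """Mean-imputation entry: the absent predictor's coefficient and the
    derivation-sample mean assigned to every individual."""

    beta: float
    mean: float


@dataclass(frozen=True)
class CoefficientSet:
    """A fully parameterised risk model (see module docstring for the form).

    ``coefficients`` maps a binary/continuous predictor name to a float, and
    a categorical predictor name to a ``{level: beta}`` map that omits the
    reference level (implicit zero).
    """

    schema: PredictorSchema
    baseline_survival: float
    coefficients: Mapping[str, Union[float, Mapping[str, float]]]
    recalibration_shape: float = 1.0
    imputed_terms: Mapping[str, ImputedTerm] = field(default_factory=dict)
    label: str = ""
    horizon_years: float = 1.0

    def __post_init__(self) -> None:
        s = self.baseline_survival
        if not (0.0 < s < 1.0):
            raise ValidationError(f"baseline_survival must lie in (0, 1), got {s}")
        if not self.recalibration_shape > 0:
            raise ValidationError(
                f"recalibration_shape must be positive, got {self.recalibration_shape}"
            )
        for name, value in self.coefficients.items():
            if name not in self.schema:
                raise SchemaError(f"coefficient for unknown predictor {name!r}")
            pred = self.schema[name]
            if pred.kind == "categorical":
                if not isinstance(value, Mapping):
                    raise ValidationError(
                        f"categorical predictor {name!r} needs a level->beta map"
                    )
                for level in value:
                    if level not in pred.levels:
                        raise SchemaError(f"unknown level {level!r} for {name!r}")
                    if level == pred.reference:
                        raise ValidationError(
                            f"{name!r}: reference level {level!r} must not carry a "
                            "coefficient (it is implicitly 0)"
                        )
            elif isinstance(value, Mapping):
                raise ValidationError(f"{pred.kind} predictor {name!r} needs a scalar beta")
        overlap = set(self.imputed_terms) & set(self.coefficients)
        if overlap:
            raise ValidationError(
                f"imputed predictors also present in coefficients: {sorted(overlap)}"
            )

    def replace(self, **changes) -> "CoefficientSet":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class PredictionResult:
    """Per-individual linear predictor and predicted risk."""

    id: str
    lp: float
    risk: float


class Cohort:
    """A validation cohort: one row per released individual.

    Wraps a :class:`pandas.DataFrame` with columns ``id``, one column per
    schema predictor, ``outcome`` (0/1, NaN when unobserved) and
    ``outcome_available`` (bool).  Rows with unavailable outcomes are kept
    but excluded by :meth:`complete_cases`, mirroring a complete-case
    validation analysis.
    """

    def __init__(self, data: pd.DataFrame, schema: PredictorSchema):
        self.schema = schema
        self.data = data.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.data
        if "id" not in df.columns:
            raise ValidationError("cohort table needs an 'id' column")
        if "outcome_available" not in df.columns:
            avail = df["outcome"].notna() if "outcome" in df.columns else pd.Series(
                False, index=df.index
            )
            self.data = df = df.assign(outcome_available=avail)
        if "outcome" not in df.columns:
            self.data = df = df.assign(outcome=np.nan)
        for name in self.schema.required_names:
            if name not in df.columns:
                raise SchemaError(f"cohort lacks required predictor column {name!r}")
            pred = self.schema[name]
            col = df[name]
            if pred.kind == "categorical":
                bad = ~col.isin(pred.levels)
                if bad.any():
                    rid = df.loc[bad, "id"].iloc[0]
                    val = col[bad].iloc[0]
                    raise SchemaError(
                        f"record {rid!r}: value {val!r} not a level of {name!r}"
                    )
            elif pred.kind == "binary":
                vals = pd.unique(col)
                if not np.isin(vals, [0, 1]).all():
                    raise SchemaError(f"binary predictor {name!r} has non-0/1 values")
        avail = df["outcome_available"].astype(bool)
        has_outcome = df["outcome"].notna()
        if (avail != has_outcome).any():
            rid = df.loc[avail != has_outcome, "id"].iloc[0]
            raise ValidationError(
                f"record {rid!r}: outcome present iff outcome_available"
            )
        ok = df.loc[avail, "outcome"].isin([0, 1])
        if not ok.all():
            raise ValidationError("outcomes must be 0/1 where available")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> list[str]:
        return self.data["id"].astype(str).tolist()

    def complete_cases(self) -> "Cohort":
        """Restrict to individuals with an observed outcome."""
        mask = self.data["outcome_available"].astype(bool)
        return Cohort(self.data.loc[mask].reset_index(drop=True), self.schema)

    @property
    def outcomes(self) -> np.ndarray:
        """Outcome vector (complete cases only raise no NaN)."""
        return self.data["outcome"].to_numpy(dtype=float)

    @property
    def n_events(self) -> int:
        return int(np.nansum(self.outcomes))


# ---------------------------------------------------------------------------
# scoring


def imputed_offset(coefs: CoefficientSet) -> float:
    """Constant added to every individual's linear predictor.

    Mean imputation of an absent predictor assigns all individuals the
    derivation-sample mean, so its contribution collapses to the constant
    ``beta_j * mean_j`` summed over imputed predictors.
    """
    return float(sum(t.beta * t.mean for t in coefs.imputed_terms.values()))


def _predictor_contribution(values: pd.Series, pred: Predictor, beta) -> np.ndarray:
    if pred.kind == "categorical":
        mapping = {level: 0.0 for level in pred.levels}
        mapping.update({k: float(v) for k, v in beta.items()})
        out = values.map(mapping)
        if out.isna().any():
            bad = values[out.isna()].iloc[0]
            raise SchemaError(f"value {bad!r} is not a level of {pred.name!r}")
        return out.to_numpy(dtype=float)
    return values.to_numpy(dtype=float) * float(beta)


def linear_predictors(
    cohort: Cohort, coefs: CoefficientSet, exclude: Iterable[str] = ()
) -> np.ndarray:
    """Vectorised ``sum(beta * RF) + imputed offset`` for every record.

    ``exclude`` drops named predictors' contributions (used by selective
    re-estimation to form the partial linear predictor).
    """
    excluded = set(exclude)
    lp = np.full(len(cohort), imputed_offset(coefs))
    for name, beta in coefs.coefficients.items():
        if name in excluded:
            continue
        pred = coefs.schema[name]
        if name not in cohort.data.columns:
            raise SchemaError(f"cohort lacks predictor column {name!r}")
        lp += _predictor_contribution(cohort.data[name], pred, beta)
    return lp


def linear_predictor(record: Mapping[str, object], coefs: CoefficientSet) -> float:
    """Linear predictor for a single record (mapping of predictor -> value)."""
    frame = pd.DataFrame([dict(record)])
    if "id" not in frame.columns:
        frame["id"] = "_"
    cohort = Cohort(frame, coefs.schema)
    return float(linear_predictors(cohort, coefs)[0])


def predict_risk(lp, coefs: CoefficientSet):
    """Predicted event probability ``1 - S**exp(lambda * lp)``.

    Strictly increasing in ``lp``; tends to 0 (resp. 1) as lp -> -inf
    (resp. +inf).  Accepts scalars or arrays; rejects non-finite input.
    """
    lp_arr = np.asarray(lp, dtype=float)
    if not np.isfinite(lp_arr).all():
        raise ValueError("linear predictor must be finite")
    s = coefs.baseline_survival
    lam = coefs.recalibration_shape
    # computed on the cloglog scale for numerical stability at extreme lp
    risk = -np.expm1(np.exp(lam * lp_arr) * math.log(s))
    risk = np.clip(risk, 0.0, 1.0)
    return float(risk) if np.isscalar(lp) or lp_arr.ndim == 0 else risk


def score_cohort(cohort: Cohort, coefs: CoefficientSet) -> list[PredictionResult]:
    """Score every record; order preserved, deterministic."""
    if len(cohort) == 0:
        return []
    lp = linear_predictors(cohort, coefs)
    risk = predict_risk(lp, coefs)
    risk = np.atleast_1d(risk)
    return [
        PredictionResult(id=str(i), lp=float(l), risk=float(r))
        for i, l, r in zip(cohort.ids, lp, risk)
    ]


def clip_probabilities(p, eps: float = PROB_EPS) -> np.ndarray:
    """Clip probabilities into ``[eps, 1-eps]`` ahead of logit/cloglog."""
    return np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)


# ---------------------------------------------------------------------------
# serialisation


def _schema_to_list(schema: PredictorSchema) -> list[dict]:
    out = []
    for p in schema:
        d: dict = {"name": p.name, "kind": p.kind, "required": p.required}
        if p.kind == "categorical":
            d["levels"] = list(p.levels)
        out.append(d)
    return out


def _schema_from_list(items: Sequence[Mapping]) -> PredictorSchema:
    preds = []
    for item in items:
        try:
            preds.append(
                Predictor(
                    name=item["name"],
                    kind=item["kind"],
                    levels=tuple(item.get("levels", ())),
                    required=bool(item.get("required", True)),
                )
            )
        except KeyError as exc:
            raise ValidationError(f"schema entry missing key {exc.args[0]!r}") from exc
    return PredictorSchema(tuple(preds))


def coefficient_set_to_dict(coefs: CoefficientSet) -> dict:
    return {
        "label": coefs.label,
        "horizon_years": coefs.horizon_years,
        "baseline_survival": coefs.baseline_survival,
        "recalibration_shape": coefs.recalibration_shape,
        "coefficients": {
            name: (dict(v) if isinstance(v, Mapping) else float(v))
            for name, v in coefs.coefficients.items()
        },
        "imputed_terms": {
            name: {"beta": t.beta, "mean": t.mean}
            for name, t in coefs.imputed_terms.items()
        },
        "schema": _schema_to_list(coefs.schema),
    }


def coefficient_set_from_dict(doc: Mapping) -> CoefficientSet:
    for key in ("baseline_survival", "coefficients", "schema"):
        if key not in doc:
            raise ValidationError(f"coefficient document missing key {key!r}")
    schema = _schema_from_list(doc["schema"])
    imputed = {}
    for name, entry in (doc.get("imputed_terms") or {}).items():
        try:
            imputed[name] = ImputedTerm(beta=float(entry["beta"]), mean=float(entry["mean"]))
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"imputed_terms[{name!r}] malformed") from exc
    return CoefficientSet(
        schema=schema,
        baseline_survival=float(doc["baseline_survival"]),
        coefficients=doc["coefficients"],
        recalibration_shape=float(doc.get("recalibration_shape", 1.0)),
        imputed_terms=imputed,
        label=str(doc.get("label", "")),
        horizon_years=float(doc.get("horizon_years", 1.0)),
    )


def load_coefficient_set(path: str | Path) -> CoefficientSet:
    """Load a coefficient-set JSON document (see package README for layout)."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed coefficient JSON: {exc}") from exc
    return coefficient_set_from_dict(doc)


def save_coefficient_set(coefs: CoefficientSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(coefficient_set_to_dict(coefs), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_cohort(path: str | Path, schema: PredictorSchema) -> Cohort:
    """Read a cohort CSV: ``id``, one column per predictor, ``outcome``.

    ``outcome_available`` is inferred from empty outcome cells when absent.
    """
    df = pd.read_csv(path, dtype={"id": str})
    return Cohort(df, schema)


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    df = cohort.data.copy()
    # write outcomes as 0/1 with empty cells where unavailable
    df["outcome"] = df["outcome"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    df.to_csv(path, index=False)
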