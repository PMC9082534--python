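"""Incremental model-updating ladder for transported risk models.

Because the risk model is exactly linear on the complementary log-log
scale, ``cloglog(risk) = log(-log S) + lambda * lp``, every updating stage
is a binomial GLM with cloglog link fitted on the validation cohort:

* ``simple``    — no refit; apply the original model as-is and report.
* ``baseline``  — refit the intercept only (new baseline survival
                  ``S' = exp(-exp(a))``), slope pinned at the current shape.
* ``slope``     — refit intercept and a single multiplicative recalibration
                  value ``lambda'`` applied to the whole linear predictor.
* ``selective`` — additionally re-estimate the dummy coefficients of one
                  categorical predictor whose effect differs between the
                  derivation and validation populations, keeping the rest
                  of the model fixed up to recalibration.

Stages ``simple -> baseline -> slope`` are monotone transforms of the
linear predictor and therefore cannot change discrimination (AUC);
``selective`` can.  Each successive stage's model nests the previous one,
so the in-sample log-likelihood is non-decreasing along the ladder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .metrics import ValidationReport, build_report
from .model_core import (
    CoefficientSet,
    Cohort,
    clip_probabilities,
    linear_predictors,
    predict_risk,
)

__all__ = [
    "STAGES",
    "RecalibrationParams",
    "UpdateLadderResult",
    "fit_cloglog_recalibration",
    "simple_validation",
    "update_baseline_risk",
    "fit_multiplicative_value",
    "reestimate_predictor",
    "apply_recalibration",
    "run_ladder",
    "bernoulli_loglik",
    "stage_comparison_markdown",
]

STAGES = ("simple", "baseline", "slope", "selective")

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class RecalibrationParams:
    """Fitted updating-stage parameters, expressible as a new coefficient
    set in the ``1 - S'**exp(lambda' * lp)`` form."""

    stage: str
    baseline_survival: float
    shape: float
    reestimated: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not (0.0 < self.baseline_survival < 1.0):
            raise ValueError("baseline survival must lie in (0, 1)")
        if self.stage in ("slope", "selective") and not self.shape > 0:
            raise ValueError("recalibration shape must be positive")
        if self.reestimated and self.stage != "selective":
            raise ValueError("re-estimated coefficients only at the selective stage")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "baseline_survival": self.baseline_survival,
            "shape": self.shape,
            "reestimated": {k: dict(v) for k, v in self.reestimated.items()},
        }


@dataclass
class UpdateLadderResult:
    """Per-stage parameters and reports, plus the final coefficient set."""

    stages: list[tuple[RecalibrationParams, ValidationReport]]
    final_coefficients: CoefficientSet

    @property
    def stage_names(self) -> list[str]:
        return [p.stage for p, _ in self.stages]


class FitError(RuntimeError):
    """Recalibration GLM failed to converge (or the data are separated)."""


def _fit_glm_cloglog(y, design, offset=None):
    model = sm.GLM(
        y,
        design,
        family=sm.families.Binomial(link=sm.families.links.CLogLog()),
        offset=offset,
    )
    try:
        res = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise FitError(f"cloglog recalibration failed: {exc}") from exc
    if not res.converged:
        raise FitError(
            "cloglog recalibration did not converge within 100 IRLS iterations "
            f"(deviance {res.deviance:.6g})"
        )
    if np.max(np.abs(res.params)) > 30:
        raise FitError(
            "cloglog recalibration diverged (coefficient magnitude > 30); "
            "the outcome is likely separated"
        )
    return res


def fit_cloglog_recalibration(
    lp, outcomes, free: str = "intercept", fixed_slope: float = 1.0
) -> tuple[float, float]:
    """Maximum-likelihood cloglog regression of outcomes on the linear
    predictor.

    ``free='intercept'`` fits the intercept with the slope pinned at
    ``fixed_slope`` (offset formulation); ``free='intercept_slope'`` fits
    both.  Returns ``(a, b)``: intercept and slope on the cloglog scale.
    The implied baseline survival is ``exp(-exp(a))``.
    """
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if lp.shape != y.shape:
        raise ValueError("lp and outcomes must have equal length")
    if len(y) == 0:
        raise ValueError("empty input")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("recalibration requires both outcome classes")
    if free == "intercept":
        res = _fit_glm_cloglog(y, np.ones((len(y), 1)), offset=fixed_slope * lp)
        return float(res.params[0]), float(fixed_slope)
    if free == "intercept_slope":
        if np.ptp(lp) == 0:
            raise ValueError("slope unidentifiable: linear predictor is constant")
        res = _fit_glm_cloglog(y, sm.add_constant(lp))
        return float(res.params[0]), float(res.params[1])
    raise ValueError(f"unknown free specification {free!r}")


def _complete(cohort: Cohort) -> Cohort:
    cc = cohort.complete_cases()
    if len(cc) == 0:
        raise ValueError("cohort has no complete cases")
    return cc


def apply_recalibration(
    coefs: CoefficientSet, params: RecalibrationParams
) -> CoefficientSet:
    """Express fitted stage parameters as a new coefficient set.

    Re-estimated dummies are stored inside the shape-multiplied bracket,
    i.e. as ``gamma / lambda'``, so that re-scoring through the model form
    reproduces the fitter's probabilities exactly.
    """
    coeffs = {
        name: (dict(v) if isinstance(v, Mapping) else v)
        for name, v in coefs.coefficients.items()
    }
    for predictor, levels in params.reestimated.items():
        coeffs[predictor] = {lvl: g / params.shape for lvl, g in levels.items()}
    return coefs.replace(
        baseline_survival=params.baseline_survival,
        recalibration_shape=params.shape,
        coefficients=coeffs,
        label=f"{coefs.label}+{params.stage}" if coefs.label else params.stage,
    )


def simple_validation(
    cohort: Cohort,
    coefs: CoefficientSet,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[RecalibrationParams, ValidationReport]:
    """Apply the original model unchanged and report its performance."""
    cc = _complete(cohort)
    lp = linear_predictors(cc, coefs)
    risks = predict_risk(lp, coefs)
    # discrimination ranks on the linear predictor: identical ordering to
    # the risks in exact arithmetic, immune to float tie noise
    report = build_report(risks, cc.outcomes, thresholds, label="simple", scores=lp)
    params = RecalibrationParams(
        stage="simple",
        baseline_survival=coefs.baseline_survival,
        shape=coefs.recalibration_shape,
    )
    return params, report


def update_baseline_risk(cohort: Cohort, coefs: CoefficientSet) -> RecalibrationParams:
    """Refit only the baseline risk (intercept), slope fixed at the current
    shape.  By the cloglog score equation, the updated model's mean
    predicted risk matches the observed incidence on the fitting cohort."""
    cc = _complete(cohort)
    lp = linear_predictors(cc, coefs)
    a, b = fit_cloglog_recalibration(
        lp, cc.outcomes, free="intercept", fixed_slope=coefs.recalibration_shape
    )
    return RecalibrationParams(
        stage="baseline", baseline_survival=math.exp(-math.exp(a)), shape=b
    )


def fit_multiplicative_value(cohort: Cohort, coefs: CoefficientSet) -> RecalibrationParams:
    """Refit the baseline risk together with a single multiplicative
    recalibration value applied to the whole linear predictor."""
    cc = _complete(cohort)
    lp = linear_predictors(cc, coefs)
    a, b = fit_cloglog_recalibration(lp, cc.outcomes, free="intercept_slope")
    return RecalibrationParams(
        stage="slope", baseline_survival=math.exp(-math.exp(a)), shape=b
    )


def reestimate_predictor(
    cohort: Cohort, coefs: CoefficientSet, predictor: str
) -> RecalibrationParams:
    """Selectively re-estimate one categorical predictor's coefficients.

    Fits intercept, a slope on the partial linear predictor (the full lp
    minus the chosen predictor's contribution) and free dummy coefficients
    for the predictor's non-reference levels.  Unlike the earlier stages
    this may change the rank order of predicted risks.
    """
    pred = coefs.schema[predictor]
    if pred.kind != "categorical":
        raise ValueError(f"selective re-estimation needs a categorical predictor, "
                         f"got {pred.kind!r} {predictor!r}")
    cc = _complete(cohort)
    values = cc.data[predictor]
    empty = [lvl for lvl in pred.levels if not (values == lvl).any()]
    if empty:
        raise ValueError(
            f"no individuals at level(s) {empty} of {predictor!r}; "
            "cannot re-estimate"
        )
    partial_lp = linear_predictors(cc, coefs, exclude=(predictor,))
    non_ref = list(pred.levels[1:])
    dummies = np.column_stack([(values == lvl).to_numpy(float) for lvl in non_ref])
    design = np.column_stack([np.ones(len(cc)), partial_lp, dummies])
    y = cc.outcomes
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("re-estimation requires both outcome classes")
    res = _fit_glm_cloglog(y, design)
    a = float(res.params[0])
    b = float(res.params[1])
    gammas = {lvl: float(g) for lvl, g in zip(non_ref, res.params[2:])}
    return RecalibrationParams(
        stage="selective",
        baseline_survival=math.exp(-math.exp(a)),
        shape=b,
        reestimated={predictor: gammas},
    )


def bernoulli_loglik(risks, outcomes) -> float:
    """In-sample Bernoulli log-likelihood of predicted risks."""
    p = clip_probabilities(risks)
    y = np.asarray(outcomes, dtype=float)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def run_ladder(
    cohort: Cohort,
    coefs: CoefficientSet,
    stages: Sequence[str] = STAGES,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    selective_predictor: str = "length_of_incarceration",
) -> UpdateLadderResult:
    """Execute the requested updating stages in their fixed order.

    Each stage is fitted on the (complete-case) cohort and re-reported;
    the returned final coefficient set reproduces the last stage's fitted
    risks when re-applied through :func:`oxval.model_core.predict_risk`.
    Partial results are retained up to a failing stage by the caller
    catching :class:`FitError`.
    """
    stages = list(stages)
    order = [STAGES.index(s) if s in STAGES else -1 for s in stages]
    if -1 in order:
        raise ValueError(f"unknown stage in {stages}")
    if order != sorted(order) or len(set(order)) != len(order):
        raise ValueError(
            f"stages must respect the order {STAGES}, got {tuple(stages)}"
        )
    cc = _complete(cohort)
    current = coefs
    out: list[tuple[RecalibrationParams, ValidationReport]] = []
    for stage in stages:
        if stage == "simple":
            params, report = simple_validation(cc, current, thresholds)
            out.append((params, report))
            continue
        if stage == "baseline":
            params = update_baseline_risk(cc, current)
        elif stage == "slope":
            params = fit_multiplicative_value(cc, current)
        else:
            params = reestimate_predictor(cc, current, selective_predictor)
        current = apply_recalibration(current, params)
        lp = linear_predictors(cc, current)
        risks = predict_risk(lp, current)
        report = build_report(risks, cc.outcomes, thresholds, label=stage, scores=lp)
        out.append((params, report))
    return UpdateLadderResult(stages=out, final_coefficients=current)


def stage_comparison_markdown(result: UpdateLadderResult) -> str:
    """Markdown table comparing stages: S', shape, AUC, CITL, slope, Brier, E:O."""
    lines = [
        "| Stage | S' | shape | AUC | CITL | Slope | Brier | E:O |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for params, report in result.stages:
        cal = report.calibration
        lines.append(
            f"| {params.stage} | {params.baseline_survival:.4f} | "
            f"{params.shape:.4f} | {report.auc:.3f} | {cal.citl:.3f} | "
            f"{cal.slope:.3f} | {report.brier:.4f} | {cal.eo_ratio:.3f} |"
        )
    return "\n".join(lines)
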