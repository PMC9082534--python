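"""Performance measures for externally validated risk models.

Covers the standard triad reported in prediction-model validation studies:

* overall accuracy — Brier score;
* discrimination — AUC (c-index) with a DeLong 95% interval (seeded
  bootstrap available as an alternative);
* calibration — calibration-in-the-large (CITL, intercept of a logistic
  regression of outcomes on logit(risk) with slope pinned at 1),
  calibration slope (free intercept), expected:observed ratio, and
  quantile-bin calibration curves;

plus threshold classification metrics (sensitivity / specificity / PPV /
NPV with Wilson score intervals) at prespecified risk cutoffs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

from .model_core import clip_probabilities

__all__ = [
    "ThresholdMetrics",
    "CalibrationBins",
    "ValidationReport",
    "brier_score",
    "auc",
    "auc_ci",
    "auc_ci_bootstrap",
    "calibration_intercept_large",
    "calibration_slope",
    "eo_ratio",
    "calibration_bins",
    "threshold_metrics",
    "build_report",
]


def _as_arrays(risks, outcomes):
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if r.shape != y.shape:
        raise ValueError(f"length mismatch: {r.shape} vs {y.shape}")
    return r, y


def _require_both_classes(y: np.ndarray, what: str) -> None:
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"{what} undefined: outcomes contain a single class")


def brier_score(risks, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome.

    0 is perfect, 1 worst; the uninformative constant-prevalence predictor
    scores ``prev * (1 - prev)``.
    """
    r, y = _as_arrays(risks, outcomes)
    if len(r) == 0:
        raise ValueError("brier_score needs at least one observation")
    return float(np.mean((r - y) ** 2))


def auc(scores, outcomes) -> float:
    """Concordance (c-index) via midranks: the probability that a random
    event individual outscores a random non-event individual, ties at 1/2.

    Equals the trapezoidal area under the ROC curve.
    """
    s, y = _as_arrays(scores, outcomes)
    _require_both_classes(y, "AUC")
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(s)  # average midranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """DeLong variance of the AUC estimator via midrank placements."""
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    # placement of each event among non-events, and vice versa
    v01 = (all_ranks[:m] - pos_ranks) / n
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(s01 / m + s10 / n)


def auc_ci(scores, outcomes, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation interval for the AUC, truncated to [0, 1].

    A degenerate (zero) DeLong variance — e.g. perfect separation —
    collapses the interval onto the point estimate.
    """
    s, y = _as_arrays(scores, outcomes)
    point = auc(s, y)
    var = _delong_variance(s, y)
    if var <= 0:
        return (point, point)
    z = norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return (max(0.0, point - half), min(1.0, point + half))


def auc_ci_bootstrap(
    scores, outcomes, level: float = 0.95, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval for the AUC (stratified resampling)."""
    s, y = _as_arrays(scores, outcomes)
    _require_both_classes(y, "AUC")
    rng = np.random.default_rng(seed)
    pos = s[y == 1]
    neg = s[y == 0]
    stats = np.empty(n_boot)
    ones = np.ones(len(pos))
    zeros = np.zeros(len(neg))
    yy = np.concatenate([ones, zeros])
    for b in range(n_boot):
        sp = rng.choice(pos, size=len(pos), replace=True)
        sn = rng.choice(neg, size=len(neg), replace=True)
        stats[b] = auc(np.concatenate([sp, sn]), yy)
    alpha = 1 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


def _logit(p: np.ndarray) -> np.ndarray:
    p = clip_probabilities(p)
    return np.log(p / (1 - p))


def calibration_intercept_large(risks, outcomes) -> float:
    """Calibration-in-the-large: intercept of a maximum-likelihood logistic
    regression of outcomes on logit(risk) with the slope pinned at 1
    (offset formulation).  0 means average predicted risk matches observed
    incidence; positive values indicate underestimated risk.
    """
    r, y = _as_arrays(risks, outcomes)
    _require_both_classes(y, "CITL")
    model = sm.GLM(
        y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=_logit(r)
    )
    res = model.fit()
    if not res.converged:
        raise RuntimeError(
            f"CITL fit did not converge after {res.fit_history['iteration']} iterations"
        )
    return float(res.params[0])


def calibration_slope(risks, outcomes) -> float:
    """Calibration slope: coefficient of logit(risk) in a logistic
    regression of outcomes with free intercept.  1 means predictor effects
    transport; <1 indicates overfitting (risks too extreme).
    """
    r, y = _as_arrays(risks, outcomes)
    _require_both_classes(y, "calibration slope")
    x = _logit(r)
    if np.ptp(x) == 0:
        raise ValueError("calibration slope unidentifiable: logit(risk) is constant")
    design = sm.add_constant(x)
    res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    if not res.converged:
        raise RuntimeError(
            f"slope fit did not converge after {res.fit_history['iteration']} iterations"
        )
    return float(res.params[1])


def eo_ratio(risks, outcomes) -> float:
    """Expected:observed event ratio, ``sum(risk) / sum(outcome)``; 1 is
    perfect average calibration, <1 underestimation."""
    r, y = _as_arrays(risks, outcomes)
    observed = y.sum()
    if observed == 0:
        raise ValueError("E:O undefined: no observed events")
    return float(r.sum() / observed)


@dataclass(frozen=True)
class CalibrationBin:
    mean_predicted: float
    observed: float
    count: int


@dataclass(frozen=True)
class CalibrationBins:
    """Quantile-bin calibration curve plus global calibration summaries."""

    bins: tuple[CalibrationBin, ...]
    citl: float
    slope: float
    eo_ratio: float

    def to_rows(self) -> list[dict]:
        return [
            {
                "bin": i + 1,
                "mean_predicted": b.mean_predicted,
                "observed": b.observed,
                "n": b.count,
            }
            for i, b in enumerate(self.bins)
        ]


def calibration_bins(risks, outcomes, n_bins: int = 10) -> CalibrationBins:
    """Rank individuals by predicted risk and cut into ``n_bins`` quantile
    groups (deciles by default); ties at boundaries resolved by stable rank
    order so the grouping is deterministic."""
    r, y = _as_arrays(risks, outcomes)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(r) < n_bins:
        raise ValueError(f"need at least {n_bins} observations for {n_bins} bins")
    order = np.argsort(r, kind="stable")
    groups = np.array_split(order, n_bins)
    bins = tuple(
        CalibrationBin(
            mean_predicted=float(r[g].mean()),
            observed=float(y[g].mean()),
            count=len(g),
        )
        for g in groups
    )
    return CalibrationBins(
        bins=bins,
        citl=calibration_intercept_large(r, y),
        slope=calibration_slope(r, y),
        eo_ratio=eo_ratio(r, y),
    )


@dataclass(frozen=True)
class ProportionCI:
    estimate: float  # NaN when the denominator is empty
    lower: float
    upper: float
    undefined: bool = False


def _wilson(count: int, nobs: int) -> ProportionCI:
    if nobs == 0:
        return ProportionCI(math.nan, math.nan, math.nan, undefined=True)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return ProportionCI(count / nobs, float(lo), float(hi))


@dataclass(frozen=True)
class ThresholdMetrics:
    """2x2 classification table at one risk cutoff (positive = risk >= t)."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: ProportionCI
    specificity: ProportionCI
    ppv: ProportionCI
    npv: ProportionCI


def threshold_metrics(risks, outcomes, threshold: float) -> ThresholdMetrics:
    """Classification metrics at ``threshold`` with Wilson 95% intervals.

    The boundary counts as positive (risk >= threshold).  Empty denominators
    (e.g. no predicted positives) yield NaN estimates flagged undefined.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    r, y = _as_arrays(risks, outcomes)
    _require_both_classes(y, "threshold metrics")
    positive = r >= threshold
    event = y == 1
    tp = int(np.sum(positive & event))
    fp = int(np.sum(positive & ~event))
    fn = int(np.sum(~positive & event))
    tn = int(np.sum(~positive & ~event))
    return ThresholdMetrics(
        threshold=threshold,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_wilson(tp, tp + fn),
        specificity=_wilson(tn, tn + fp),
        ppv=_wilson(tp, tp + fp),
        npv=_wilson(tn, tn + fn),
    )


@dataclass(frozen=True)
class ValidationReport:
    """All performance measures for one validation (or updating) stage."""

    label: str
    n: int
    events: int
    incidence: float
    brier: float
    auc: float
    auc_ci: tuple[float, float]
    calibration: CalibrationBins
    thresholds: tuple[ThresholdMetrics, ...]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_ci"] = list(self.auc_ci)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def threshold_markdown(self) -> str:
        """Markdown threshold table (whole-percent presentation)."""

        def cell(ci: ProportionCI) -> str:
            if ci.undefined:
                return "—"
            return (
                f"{round(ci.estimate * 100)}% "
                f"({round(ci.lower * 100)}–{round(ci.upper * 100)})"
            )

        lines = [
            "| Risk threshold | Sensitivity | Specificity | PPV | NPV |",
            "|---|---|---|---|---|",
        ]
        for t in self.thresholds:
            lines.append(
                f"| {round(t.threshold * 100)}% | {cell(t.sensitivity)} | "
                f"{cell(t.specificity)} | {cell(t.ppv)} | {cell(t.npv)} |"
            )
        return "\n".join(lines)

    def calibration_tsv(self, path: str | Path | None = None) -> str:
        lines = ["bin\tmean_predicted\tobserved\tn"]
        for row in self.calibration.to_rows():
            lines.append(
                f"{row['bin']}\t{row['mean_predicted']:.10g}"
                f"\t{row['observed']:.10g}\t{row['n']}"
            )
        text = "\n".join(lines)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def build_report(
    risks,
    outcomes,
    thresholds: Sequence[float] = (0.05, 0.10, 0.15, 0.20),
    label: str = "",
    n_bins: int = 10,
    scores=None,
) -> ValidationReport:
    """Assemble the full report: accuracy, discrimination, calibration and
    the threshold table (rows ascending in threshold).

    ``scores`` optionally supplies the ranking variable for the c-index
    (e.g. the linear predictor, whose ordering the risk transform preserves
    exactly); discrimination defaults to ranking on the risks themselves.
    """
    r, y = _as_arrays(risks, outcomes)
    _require_both_classes(y, "validation report")
    s = r if scores is None else np.asarray(scores, dtype=float)
    ordered = tuple(sorted(thresholds))
    return ValidationReport(
        label=label,
        n=len(y),
        events=int(y.sum()),
        incidence=float(y.mean()),
        brier=brier_score(r, y),
        auc=auc(s, y),
        auc_ci=auc_ci(s, y),
        calibration=calibration_bins(r, y, n_bins=n_bins),
        thresholds=tuple(threshold_metrics(r, y, t) for t in ordered),
    )
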