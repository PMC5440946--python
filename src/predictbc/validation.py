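"""Calibration, goodness of fit and discrimination for scored cohorts.

Implements the registry-validation methodology: observed vs predicted event
counts overall and within printed strata (age decades, size and node bands,
grade, risk quintiles), a chi-square goodness-of-fit test on quintiles of
predicted risk (5 df), and 10-year discrimination (AUC) with the DeLong
test for comparing two correlated AUCs on the same patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FittingError, InvalidInputError
from .model import ModelCoefficients, default_model, score_cohort

__all__ = [
    "STRATIFIERS",
    "PredictedEvents",
    "CalibrationTable",
    "GoodnessOfFit",
    "DiscriminationResult",
    "DeLongComparison",
    "predicted_events",
    "calibration_table",
    "gof_quintiles",
    "auc_10yr",
    "delong_compare",
    "observed_events",
]

# Stratum bands as conventionally printed in registry validation tables.
_AGE_EDGES = [20, 30, 40, 50, 60, 70, 80]
_AGE_LABELS = ["20-29", "30-39", "40-49", "50-59", "60-69", "70-79"]
_SIZE_EDGES = [0, 10, 20, 30, 50, np.inf]
_SIZE_LABELS = ["0-9", "10-19", "20-29", "30-49", "50+"]
_NODE_EDGES = [0, 1, 2, 5, 10, np.inf]
_NODE_LABELS = ["0", "1", "2-4", "5-9", "10+"]

STRATIFIERS = ("age", "size", "nodes", "grade", "quintile")

_CAUSE_COLUMN = {"breast": "risk_breast", "other": "risk_other"}


def observed_events(cohort: pd.DataFrame, cause: str, t: float) -> np.ndarray:
    """Indicator of death from ``cause`` within ``t`` years.

    Patients censored before ``t`` count in the denominator (the observed-
    count framing of registry calibration tables); see ``calibration_table``'s
    ``complete_followup_only`` for the sensitivity variant.
    """
    time = cohort["time_years"].to_numpy(dtype=float)
    ev = cohort["event"].astype(str).to_numpy()
    return ((ev == cause) & (time <= t)).astype(float)


@dataclass
class PredictedEvents:
    expected_breast: float
    expected_other: float
    risks: pd.DataFrame  # per-patient pi/mi/h/r columns from score_cohort


def predicted_events(
    cohort: pd.DataFrame,
    model: ModelCoefficients | None = None,
    t: float = 10.0,
    use_treatment_flags: bool = True,
) -> PredictedEvents:
    """Expected deaths by cause: sums of competing-risks-adjusted risks."""
    model = model or default_model()
    risks = score_cohort(cohort, t=t, model=model, use_treatment_flags=use_treatment_flags)
    return PredictedEvents(
        expected_breast=float(risks["risk_breast"].sum()),
        expected_other=float(risks["risk_other"].sum()),
        risks=risks,
    )


def poisson_pvalue(observed: float, expected: float) -> float:
    """Two-sided observed-vs-expected test, observed ~ Poisson(expected).

    Exact doubled-tail probability for expected <= 50, normal approximation
    above (the printed tables never name their per-stratum test; this choice
    is documented and isolated here).
    """
    if expected < 0:
        raise InvalidInputError("expected", "expected count must be >= 0")
    if expected == 0:
        return 1.0 if observed == 0 else 0.0
    if expected <= 50:
        lower = stats.poisson.cdf(observed, expected)
        upper = stats.poisson.sf(observed - 1, expected)
        return float(min(1.0, 2.0 * min(lower, upper)))
    z = (observed - expected) / np.sqrt(expected)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class CalibrationTable:
    """Observed vs predicted deaths by stratum, with a totals row."""

    table: pd.DataFrame
    stratifier: str
    cause: str
    horizon: float


def _stratum_labels(cohort: pd.DataFrame, risks: pd.DataFrame, stratifier: str):
    if stratifier == "age":
        x = cohort["age"].to_numpy(dtype=float)
        cut = pd.cut(x, _AGE_EDGES, right=False, labels=_AGE_LABELS)
        if cut.isna().any():
            bad = x[np.asarray(cut.isna())][0]
            raise InvalidInputError("age", f"value {bad:g} outside the printed bands 20-79")
        return cut.astype(str), _AGE_LABELS
    if stratifier == "size":
        x = cohort["size_mm"].to_numpy(dtype=float)
        cut = pd.cut(x, _SIZE_EDGES, right=False, labels=_SIZE_LABELS)
        if cut.isna().any():
            bad = x[np.asarray(cut.isna())][0]
            raise InvalidInputError("size_mm", f"value {bad:g} outside the printed bands")
        return cut.astype(str), _SIZE_LABELS
    if stratifier == "nodes":
        x = cohort["nodes"].to_numpy(dtype=float)
        cut = pd.cut(x, _NODE_EDGES, right=False, labels=_NODE_LABELS)
        if cut.isna().any():
            bad = x[np.asarray(cut.isna())][0]
            raise InvalidInputError("nodes", f"value {bad:g} outside the printed bands")
        return cut.astype(str), _NODE_LABELS
    if stratifier == "grade":
        x = cohort["grade"].to_numpy(dtype=int)
        if not np.isin(x, (1, 2, 3)).all():
            raise InvalidInputError("grade", "grade outside {1,2,3}")
        return pd.Series(x, index=cohort.index).astype(str), ["1", "2", "3"]
    if stratifier == "quintile":
        labels = [f"Q{i}" for i in range(1, 6)]
        order = np.argsort(risks["risk_breast"].to_numpy(), kind="stable")
        q = np.empty(len(cohort), dtype=object)
        for i, chunk in enumerate(np.array_split(order, 5)):
            q[chunk] = labels[i]
        return pd.Series(q, index=cohort.index), labels
    raise InvalidInputError("stratifier", f"unknown stratifier {stratifier!r}")


def calibration_table(
    cohort: pd.DataFrame,
    model: ModelCoefficients | None = None,
    t: float = 10.0,
    stratifier: str = "age",
    cause: str = "breast",
    use_treatment_flags: bool = True,
    complete_followup_only: bool = False,
) -> CalibrationTable:
    """Per-stratum observed deaths, predicted deaths, % difference, p-value.

    ``complete_followup_only`` restricts to patients whose follow-up reaches
    the horizon or who died before it (sensitivity mode for cohorts with
    substantial administrative censoring before ``t``).
    """
    model = model or default_model()
    if cause not in _CAUSE_COLUMN:
        raise InvalidInputError("cause", "must be 'breast' or 'other'")
    if complete_followup_only:
        time = cohort["time_years"].to_numpy(dtype=float)
        died = cohort["event"].astype(str).to_numpy() != "censored"
        cohort = cohort.loc[(time >= t) | (died & (time <= t))]
    risks = score_cohort(cohort, t=t, model=model, use_treatment_flags=use_treatment_flags)
    pred = risks[_CAUSE_COLUMN[cause]].to_numpy()
    obs = observed_events(cohort, cause, t)
    labels, level_order = _stratum_labels(cohort, risks, stratifier)
    labels = np.asarray(labels).astype(str)
    rows = []
    for label in level_order:
        mask = labels == label
        if not mask.any():
            continue
        o, p = float(obs[mask].sum()), float(pred[mask].sum())
        rows.append(
            {
                "stratum": label,
                "n": int(mask.sum()),
                "observed": o,
                "predicted": p,
                "pct_difference": 100.0 * (p - o) / o if o > 0 else np.nan,
                "p_value": poisson_pvalue(o, p),
            }
        )
    o_tot, p_tot = float(obs.sum()), float(pred.sum())
    rows.append(
        {
            "stratum": "Total",
            "n": len(cohort),
            "observed": o_tot,
            "predicted": p_tot,
            "pct_difference": 100.0 * (p_tot - o_tot) / o_tot if o_tot > 0 else np.nan,
            "p_value": poisson_pvalue(o_tot, p_tot),
        }
    )
    return CalibrationTable(
        table=pd.DataFrame(rows), stratifier=stratifier, cause=cause, horizon=t
    )


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


@dataclass
class GoodnessOfFit:
    chi2: float
    pvalue: float
    observed: np.ndarray
    expected: np.ndarray


def gof_from_counts(observed, expected) -> GoodnessOfFit:
    """Chi-square observed-vs-expected over risk groups, 5 df by convention."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise FittingError("every group must have a positive expected count")
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return GoodnessOfFit(
        chi2=chi2, pvalue=float(stats.chi2.sf(chi2, 5)), observed=observed, expected=expected
    )


def gof_quintiles(risks, events) -> GoodnessOfFit:
    """Goodness of fit on quintiles of predicted risk (chi-square, 5 df)."""
    risks = np.asarray(risks, dtype=float)
    events = np.asarray(events, dtype=float)
    if risks.shape != events.shape:
        raise InvalidInputError("events", "risks and events must have equal length")
    if np.unique(risks).size < 5:
        raise FittingError("need at least 5 distinct predicted risks for quintiles")
    order = np.argsort(risks, kind="stable")  # stable tie-breaking, documented
    groups = np.array_split(order, 5)
    observed = np.array([events[g].sum() for g in groups])
    expected = np.array([risks[g].sum() for g in groups])
    return gof_from_counts(observed, expected)


# ---------------------------------------------------------------------------
# Discrimination: AUC and the DeLong comparison
# ---------------------------------------------------------------------------


@dataclass
class DiscriminationResult:
    auc: float
    se: float
    pvalue: float | None = None


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10 per case, V01 per control (ties 1/2)."""
    neg_sorted = np.sort(neg)
    less = np.searchsorted(neg_sorted, pos, side="left")
    leq = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (less + 0.5 * (leq - less)) / neg.size
    pos_sorted = np.sort(pos)
    greater = pos.size - np.searchsorted(pos_sorted, neg, side="right")
    geq = pos.size - np.searchsorted(pos_sorted, neg, side="left")
    v01 = (greater + 0.5 * (geq - greater)) / pos.size
    return v10, v01


def _split(risks: np.ndarray, outcomes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    outcomes = np.asarray(outcomes).astype(bool)
    risks = np.asarray(risks, dtype=float)
    if risks.shape != outcomes.shape:
        raise InvalidInputError("outcomes", "risks and outcomes must have equal length")
    pos, neg = risks[outcomes], risks[~outcomes]
    if pos.size == 0 or neg.size == 0:
        raise FittingError("AUC undefined: both outcome classes must be present")
    return pos, neg


def auc_10yr(risks, outcomes) -> DiscriminationResult:
    """Concordance between predicted risk and the 10-year death indicator.

    AUC over all (death, survivor) pairs with ties counted one half; the
    standard error is the (single-model) DeLong estimate.
    """
    pos, neg = _split(risks, outcomes)
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = 0.0
    if pos.size > 1:
        var += float(np.var(v10, ddof=1)) / pos.size
    if neg.size > 1:
        var += float(np.var(v01, ddof=1)) / neg.size
    return DiscriminationResult(auc=auc, se=float(np.sqrt(var)))


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    delta: float
    se_delta: float
    pvalue: float


def delong_compare(risks_a, risks_b, outcomes) -> DeLongComparison:
    """Paired DeLong test for the difference of two correlated AUCs."""
    risks_a = np.asarray(risks_a, dtype=float)
    risks_b = np.asarray(risks_b, dtype=float)
    if risks_a.shape != risks_b.shape:
        raise InvalidInputError("risks_b", "both risk vectors must score the same patients")
    pos_a, neg_a = _split(risks_a, outcomes)
    pos_b, neg_b = _split(risks_b, outcomes)
    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    delta = auc_a - auc_b
    m, n = pos_a.size, neg_a.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        pvalue = 1.0 if delta == 0.0 else 0.0
    else:
        pvalue = float(2.0 * stats.norm.sf(abs(delta) / se))
    return DeLongComparison(auc_a=auc_a, auc_b=auc_b, delta=delta, se_delta=se, pvalue=pvalue)
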