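"""Outcome analysis: Kaplan-Meier, log-rank, dichotomization, Cox regression
and stepwise backward elimination.

Overall survival (OS) is the interval from the start of therapy to death
from any cause, censored at the last visit.  Continuous baseline covariates
are dichotomized at fixed clinical cutoffs before modeling (age 65 years,
ECOG 2, hemoglobin 13 g/dL, ALP 220 U/L, baseline TLP 5710 mL x SUV,
baseline PSA 145 ng/mL, cumulative activity 14 GBq), and each response
assessment is dichotomized as PR versus SD/PD.  The modeling workflow is:
univariate Cox screen (entry at p < 0.1), then a multivariable model pruned
by backward elimination (removal at p >= 0.05), reporting both the full
entry model and the eliminated final model.

Estimation is delegated to lifelines: product-limit curves with log-log
(exponential Greenwood) confidence bands, the standard log-rank chi-square
test, and Cox proportional-hazards fits with Efron tie handling and Wald
confidence intervals / p-values.  Median follow-up uses the reverse
Kaplan-Meier method (censoring treated as the event).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

from .response import ResponseCategory

__all__ = [
    "DichotomizationRule",
    "DEFAULT_RULES",
    "KaplanMeierResult",
    "LogRankResult",
    "CoxResult",
    "EliminationStep",
    "EliminationResult",
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "univariate_screen",
    "backward_eliminate",
    "median_follow_up",
]


# ---------------------------------------------------------------------------
# dichotomization


@dataclass(frozen=True)
class DichotomizationRule:
    """Maps one covariate to a binary risk indicator.

    ``op`` compares the covariate value against ``cutoff``; the indicator is
    1 when the comparison holds, and ``risk_label`` names that level the way
    a results table would print it (e.g. ">= 220 U/L").
    """

    name: str
    column: str
    op: str  # 'ge', 'gt', 'le', 'lt', 'bool', 'not_pr'
    cutoff: float | None
    risk_label: str
    reference_label: str

    def apply(self, values: pd.Series) -> pd.Series:
        if self.op == "ge":
            ind = values >= self.cutoff
        elif self.op == "gt":
            ind = values > self.cutoff
        elif self.op == "le":
            ind = values <= self.cutoff
        elif self.op == "lt":
            ind = values < self.cutoff
        elif self.op == "bool":
            ind = values.astype(bool)
        elif self.op == "not_pr":
            ind = values.astype(str) != ResponseCategory.PR.value
        else:  # pragma: no cover - guarded by construction
            raise ValueError(f"unknown op {self.op!r}")
        return ind.astype(int)


#: Cutoff directions follow the printed risk-group labels of the source
#: analysis: ALP ">= 220 U/L", "ECOG >= 2", hemoglobin "< 13 g/dL",
#: activity "<= 14 GBq", age ">= 65 years", TLP ">= 5710", PSA ">= 145".
DEFAULT_RULES: tuple[DichotomizationRule, ...] = (
    DichotomizationRule("tlp_response_sdpd", "molecular", "not_pr", None, "SD/PD", "PR"),
    DichotomizationRule("psa_response_sdpd", "biochemical", "not_pr", None, "SD/PD", "PR"),
    DichotomizationRule("alp_ge_220", "alp", "ge", 220.0, ">= 220 U/L", "< 220 U/L"),
    DichotomizationRule("ecog_ge_2", "ecog", "ge", 2.0, "ECOG >= 2", "ECOG < 2"),
    DichotomizationRule("visceral_metastases", "visceral_metastases", "bool", None, "yes", "no"),
    DichotomizationRule("psa_ge_145", "psa_baseline", "ge", 145.0, ">= 145 ng/mL", "< 145 ng/mL"),
    DichotomizationRule("age_ge_65", "age", "ge", 65.0, ">= 65 years", "< 65 years"),
    DichotomizationRule("prior_chemotherapy", "prior_chemotherapy", "bool", None, "yes", "no"),
    DichotomizationRule("hemoglobin_lt_13", "hemoglobin", "lt", 13.0, "< 13 g/dL", ">= 13 g/dL"),
    DichotomizationRule("tlp_ge_5710", "tlp_baseline", "ge", 5710.0, ">= 5710 mL x SUV", "< 5710 mL x SUV"),
    DichotomizationRule("activity_le_14", "cumulative_activity", "le", 14.0, "<= 14 GBq", "> 14 GBq"),
)


def dichotomize(
    cohort: pd.DataFrame,
    rules: Sequence[DichotomizationRule] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Binary risk-factor table, one 0/1 column per rule (1 = risk level)."""
    out = pd.DataFrame(index=cohort.index)
    for rule in rules:
        if rule.column not in cohort.columns:
            raise KeyError(f"covariate {rule.column!r} missing for rule {rule.name!r}")
        out[rule.name] = rule.apply(cohort[rule.column])
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass
class KaplanMeierResult:
    """Product-limit estimate with the median and its 95% CI.

    ``median`` is ``inf`` when the curve never reaches 0.5 ("not reached");
    CI bounds may likewise be ``inf``.
    """

    timeline: np.ndarray
    survival: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be equal-length 1-D sequences")
    if t.size == 0:
        raise ValueError("empty survival data")
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    return t, e


def km_estimate(times, events, alpha: float = 0.05) -> KaplanMeierResult:
    """Kaplan-Meier curve with the median survival time and its CI.

    The median is the earliest time at which the curve drops to <= 0.5; its
    confidence interval comes from the log-log-transformed confidence band
    (Brookmeyer-Crowley style).  All-censored input yields an unreached
    (infinite) median rather than an error.
    """
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, event_observed=e)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KaplanMeierResult(
        timeline=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        median=median,
        median_ci=(lo, hi),
        n=int(t.size),
        n_events=int(e.sum()),
    )


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank chi-square test."""
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must align with times")
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"log-rank needs exactly two non-empty groups, got {levels.size}")
    a, b = (g == levels[0]), (g == levels[1])
    res = _ll_logrank(t[a], t[b], event_observed_A=e[a], event_observed_B=e[b])
    return LogRankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def median_follow_up(times, events) -> float:
    """Median follow-up by reverse Kaplan-Meier: censoring is the event.

    With every subject dead this reduces to the KM median of the follow-up
    distribution with events flipped (here: no 'events', median infinite is
    impossible only if some censoring exists; all-dead cohorts return inf).
    """
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=~e)
    return float(kmf.median_survival_time_)


# ---------------------------------------------------------------------------
# Cox regression


@dataclass
class CoxResult:
    """Per-variable hazard ratios with Wald 95% CIs and p-values."""

    summary: pd.DataFrame  # index: variable; columns: hazard_ratio, ci_lower, ci_upper, p
    n: int
    n_events: int

    def hr(self, variable: str) -> float:
        return float(self.summary.loc[variable, "hazard_ratio"])

    def p(self, variable: str) -> float:
        return float(self.summary.loc[variable, "p"])

    @property
    def variables(self) -> list[str]:
        return list(self.summary.index)


def cox_fit(
    data: pd.DataFrame,
    variables: Sequence[str],
    duration_col: str = "os_months",
    event_col: str = "event",
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Wald inference).

    Duplicated (perfectly collinear) covariate columns and non-convergence
    (e.g. complete separation) raise explicit errors.
    """
    variables = list(variables)
    if not variables:
        raise ValueError("no covariates supplied")
    X = data[variables].astype(float)
    n_events = int(data[event_col].astype(bool).sum())
    if n_events < len(variables) + 1:
        raise ValueError(
            f"too few events ({n_events}) for {len(variables)} covariates"
        )
    # perfect collinearity check before handing to the optimizer
    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr - arr.mean(axis=0)) < len(variables):
        raise ValueError("covariates are collinear (rank-deficient design)")
    df = data[[duration_col, event_col, *variables]].copy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hazard_ratio": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    summary.index.name = "variable"
    return CoxResult(summary=summary, n=len(df), n_events=n_events)


def univariate_screen(
    data: pd.DataFrame,
    variables: Sequence[str],
    duration_col: str = "os_months",
    event_col: str = "event",
    p_entry: float = 0.1,
) -> pd.DataFrame:
    """One Cox fit per variable; flags candidates with p < ``p_entry``."""
    rows = []
    for var in variables:
        res = cox_fit(data, [var], duration_col, event_col)
        row = res.summary.loc[var].to_dict()
        row["variable"] = var
        row["selected"] = bool(row["p"] < p_entry)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("variable")
    return out[["hazard_ratio", "ci_lower", "ci_upper", "p", "selected"]]


@dataclass(frozen=True)
class EliminationStep:
    removed: str
    p_value: float
    remaining: tuple[str, ...]


@dataclass
class EliminationResult:
    """Backward-elimination outcome: the full entry model, the pruned final
    model (None when every candidate was removed), and the removal trace."""

    full_model: CoxResult
    final_model: CoxResult | None
    trace: list[EliminationStep] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return self.final_model.variables if self.final_model is not None else []


def backward_eliminate(
    data: pd.DataFrame,
    candidates: Sequence[str],
    duration_col: str = "os_months",
    event_col: str = "event",
    p_removal: float = 0.05,
) -> EliminationResult:
    """Stepwise backward elimination of a multivariable Cox model.

    Starting from the full model over ``candidates`` (normally the p < 0.1
    univariate survivors), repeatedly drops the covariate with the highest
    Wald p >= ``p_removal`` and refits, until all remaining covariates are
    below the removal threshold.  Each removal is recorded.
    """
    remaining = list(candidates)
    if not remaining:
        raise ValueError("empty candidate set")
    full = cox_fit(data, remaining, duration_col, event_col)
    trace: list[EliminationStep] = []
    current = full
    while True:
        worst = current.summary["p"].idxmax()
        worst_p = float(current.summary.loc[worst, "p"])
        if worst_p < p_removal:
            break
        remaining.remove(worst)
        trace.append(EliminationStep(removed=str(worst), p_value=worst_p, remaining=tuple(remaining)))
        if not remaining:
            current = None
            break
        current = cox_fit(data, remaining, duration_col, event_col)
    return EliminationResult(full_model=full, final_model=current, trace=trace)
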