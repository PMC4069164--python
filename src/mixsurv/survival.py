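"""Survival statistics: median split, Kaplan-Meier, log-rank, Cox, chi-square.

The estimators are the standard ones for a retrospective overall-survival
analysis of a dichotomised biomarker: samples are split at the median of a
continuous score (< median = Low, >= median = High), group survival is
estimated by the product-limit method and compared with the log-rank test,
and independence of prognostic factors is assessed by multivariate Cox
proportional-hazards regression (Efron tie handling, Wald confidence
intervals on the log-hazard scale).  Computations are delegated to
``lifelines``; enrichment of a binary outcome across groups uses Pearson's
chi-square without continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test as _ll_mv_logrank

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class GroupAssignment:
    """Low/High labels from a median split and the median used."""

    labels: pd.Series          # "Low" (< median) or "High" (>= median)
    split_value: float


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray      # S(t) just after each event time


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass
class CoxResult:
    """Per-covariate Cox estimates; check ``converged`` before use.

    ``summary`` has one row per covariate with columns ``coef``, ``hr``,
    ``ci_low``, ``ci_high``, ``se`` and ``p`` (Wald); ``log_likelihood`` is
    the maximised log partial likelihood.
    """

    summary: pd.DataFrame | None
    log_likelihood: float
    converged: bool
    message: str = ""


def median_split(values: pd.Series) -> GroupAssignment:
    """Dichotomise at the sample median: Low < median, High >= median."""
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("median split needs at least two samples")
    if not np.isfinite(values).all():
        raise ValueError("median split requires finite values")
    med = float(values.median())  # mean of middle pair for even n
    labels = pd.Series(np.where(values < med, "Low", "High"), index=values.index)
    if (labels == "High").all():
        logger.warning("all values >= median (ties at the median): Low group is empty")
    return GroupAssignment(labels=labels, split_value=med)


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit curve S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty group: cannot estimate a survival curve")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    has_event = table["observed"] > 0
    event_times = table.index[has_event].to_numpy(dtype=float)
    at_risk = table.loc[has_event, "at_risk"].to_numpy(dtype=float)
    d = table.loc[has_event, "observed"].to_numpy(dtype=float)
    survival = np.cumprod(1.0 - d / at_risk)
    return KMCurve(event_times=event_times, at_risk=at_risk, events=d, survival=survival)


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank test; chi2 = (sum(O-E))^2 / sum(V), df = 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    a, b = (groups == labels[0]), (groups == labels[1])
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("empty group in log-rank test")
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(times[a], times[b], event_observed_A=events[a],
                      event_observed_B=events[b])
    return LogRankResult(chi2=float(res.test_statistic), df=1, p=float(res.p_value))


def logrank_test_k(times, events, groups) -> LogRankResult:
    """k-group log-rank test (df = k-1); reduces to the two-group test at k=2."""
    groups = np.asarray(groups)
    k = len(pd.unique(groups))
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = _ll_mv_logrank(np.asarray(times, dtype=float), groups,
                         np.asarray(events, dtype=int))
    return LogRankResult(chi2=float(res.test_statistic), df=k - 1, p=float(res.p_value))


def cox_fit(cohort: pd.DataFrame, covariates: list[str],
            duration_col: str = "os_months", event_col: str = "event") -> CoxResult:
    """Multivariate Cox proportional-hazards fit (Efron ties, Wald CIs).

    ``covariates`` are numeric (binary/dummy-coded) columns of ``cohort``.
    Non-convergence or a monotone likelihood yields a flagged result
    (``converged=False``) rather than silent numbers.
    """
    if not covariates:
        raise ValueError("cox_fit needs at least one covariate")
    df = cohort[[duration_col, event_col, *covariates]].astype(float)
    if df[event_col].sum() < 1:
        raise ValueError("cox_fit needs at least one event")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        # tight Newton tolerance: coefficients good to ~1e-8
        cph.fit(df, duration_col=duration_col, event_col=event_col,
                fit_options={"precision": 1e-11})
    except ConvergenceError as exc:
        logger.warning("Cox model failed to converge: %s", exc)
        return CoxResult(summary=None, log_likelihood=float("nan"),
                         converged=False, message=str(exc))
    coef = cph.params_
    se = cph.standard_errors_
    z = scipy.stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": coef,
            "hr": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "se": se,
            "p": cph.summary["p"],
        }
    )
    summary.index.name = "covariate"
    return CoxResult(summary=summary, log_likelihood=float(cph.log_likelihood_),
                     converged=True)


def chi_square_2xk(table) -> dict[str, float]:
    """Pearson chi-square of independence, no continuity correction."""
    table = np.asarray(table)
    if not np.issubdtype(table.dtype, np.integer):
        if not np.all(np.asarray(table, dtype=float) == np.floor(table)):
            raise ValueError("contingency table must hold integer counts")
        table = table.astype(int)
    if np.any(table < 0):
        raise ValueError("contingency table counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, df, _exp = scipy.stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def univariate_screen(
    cohort: pd.DataFrame,
    factors: list[str],
    alpha: float = DEFAULT_ALPHA,
    exclude_categories: tuple[str, ...] = ("NA", "Not sure"),
    duration_col: str = "os_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Log-rank screen of categorical factors; select those with p < alpha.

    Samples whose category for a factor is in ``exclude_categories`` are
    dropped from that factor's test only (they stay in the cohort).  Returns
    a table with one row per factor: n used, chi2, df, p and a ``selected``
    flag.  Factors left with fewer than two categories are reported with
    ``p = nan`` and never selected.
    """
    rows = []
    for factor in factors:
        if factor not in cohort.columns:
            raise KeyError(f"factor {factor!r} not in cohort")
        sub = cohort[~cohort[factor].isin(exclude_categories)]
        k = sub[factor].nunique()
        if k < 2 or sub[event_col].sum() == 0:
            logger.warning("factor %r: not testable (%d usable level(s))", factor, k)
            rows.append({"factor": factor, "n": len(sub), "chi2": np.nan,
                         "df": max(k - 1, 0), "p": np.nan, "selected": False})
            continue
        res = logrank_test_k(sub[duration_col], sub[event_col], sub[factor])
        rows.append({"factor": factor, "n": len(sub), "chi2": res.chi2,
                     "df": res.df, "p": res.p, "selected": bool(res.p < alpha)})
    return pd.DataFrame(rows).set_index("factor")


def dummy_code(cohort: pd.DataFrame, factor: str, reference: str,
               exclude_categories: tuple[str, ...] = ("NA", "Not sure")) -> pd.DataFrame:
    """Dummy-code a categorical factor against ``reference``.

    Returns indicator columns ``{factor}[{level} vs {reference}]`` for each
    non-reference level, with NaN for samples in an excluded category (they
    drop out of any model using the factor).
    """
    col = cohort[factor]
    levels = [l for l in pd.unique(col) if l not in exclude_categories]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {levels}")
    out = pd.DataFrame(index=cohort.index)
    for level in levels:
        if level == reference:
            continue
        ind = (col == level).astype(float)
        ind[col.isin(exclude_categories)] = np.nan
        out[f"{factor}[{level} vs {reference}]"] = ind
    return out
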