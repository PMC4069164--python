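"""Two-means stratification of samples on an MHC-like expression panel.

Samples are clustered into exactly two groups by Lloyd's k-means on the raw
panel intensities (Euclidean distance over the panel genes, no gene scaling),
the cluster with the smaller mean centroid level is labelled "Low" — low
antigen presentation — and the labels are handed to the survival machinery
(log-rank, Cox adjusted for clinical covariates, chi-square enrichment of
relapse in the Low group).

Lloyd's algorithm is written out here because the stratification contract
needs its internals: a per-iteration objective trace (within-cluster sum of
squares, non-increasing) and a farthest-point reseed when a cluster empties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import survival as ss

logger = logging.getLogger(__name__)


@dataclass
class StratificationResult:
    """Two-cluster assignment of samples over an m-gene panel."""

    assignments: np.ndarray        # 0/1 cluster index per sample
    centroids: np.ndarray          # 2 x m
    inertia: float                 # within-cluster sum of squares
    n_iter: int
    seed: int
    sample_ids: list[str]
    objective_trace: np.ndarray    # WCSS after each assignment step
    labels: pd.Series | None = None  # "Low"/"High" once label_low_high has run


def euclidean_distance(u, v) -> float:
    """d(u, v) = sqrt(sum_g (e_gu - e_gv)^2) over the m panel genes."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 1:
        raise ValueError("expression vectors must be 1-D of equal length >= 1")
    return float(np.sqrt(np.sum((u - v) ** 2)))


def _wcss(X: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    return float(np.sum((X - centroids[assign]) ** 2))


def _lloyd(X: np.ndarray, seed: int, max_iter: int) -> tuple[np.ndarray, np.ndarray, list[float]]:
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    # init: two distinct random samples
    for _ in range(100):
        idx = rng.choice(n, size=2, replace=False)
        centroids = X[idx].copy()
        if not np.allclose(centroids[0], centroids[1]):
            break
    trace: list[float] = []
    assign = np.zeros(n, dtype=int)
    for it in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        trace.append(_wcss(X, centroids, new_assign))
        for c in range(2):
            if not np.any(new_assign == c):
                # reseed the empty centroid at the farthest point
                far = d2.min(axis=1).argmax()
                centroids[c] = X[far]
                new_assign[far] = c
        if it > 0 and np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign
        for c in range(2):
            centroids[c] = X[assign == c].mean(axis=0)
    trace.append(_wcss(X, centroids, assign))
    return assign, centroids, trace


def kmeans_two(
    X_panel: pd.DataFrame,
    n_restarts: int = 25,
    max_iter: int = 100,
    seed: int = 0,
) -> StratificationResult:
    """Best-of-restarts two-means clustering of samples (rows) by WCSS.

    ``X_panel`` is samples x genes.  Deterministic under ``seed``; all-identical
    samples raise.
    """
    if isinstance(X_panel, pd.DataFrame):
        sample_ids = [str(s) for s in X_panel.index]
        X = X_panel.to_numpy(dtype=float)
    else:
        X = np.asarray(X_panel, dtype=float)
        sample_ids = [f"S{j + 1:03d}" for j in range(X.shape[0])]
    if X.shape[0] < 2:
        raise ValueError("two-means needs at least two samples")
    if np.allclose(X, X[0]):
        raise ValueError("all samples identical: two-means is undefined")
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % np.uint32(2**31)
    best = None
    for s in sub_seeds:
        assign, centroids, trace = _lloyd(X, int(s), max_iter)
        inertia = trace[-1]
        if best is None or inertia < best[2][-1]:
            best = (assign, centroids, trace)
    assign, centroids, trace = best
    return StratificationResult(
        assignments=assign,
        centroids=centroids,
        inertia=float(trace[-1]),
        n_iter=len(trace) - 1,
        seed=seed,
        sample_ids=sample_ids,
        objective_trace=np.asarray(trace),
    )


def label_low_high(result: StratificationResult) -> StratificationResult:
    """Label the cluster with the smaller mean centroid level "Low".

    A tie in centroid means is broken toward the smaller cluster (logged).
    The labelling is invariant to the arbitrary 0/1 cluster indexing.
    """
    means = result.centroids.mean(axis=1)
    if means[0] == means[1]:
        sizes = np.bincount(result.assignments, minlength=2)
        low_cluster = int(sizes.argmin())
        logger.warning("centroid means tie; labelling the smaller cluster Low")
    else:
        low_cluster = int(means.argmin())
    labels = np.where(result.assignments == low_cluster, "Low", "High")
    result.labels = pd.Series(labels, index=pd.Index(result.sample_ids, name="sample_id"))
    return result


def stratify_and_test(
    X_panel: pd.DataFrame,
    cohort: pd.DataFrame,
    relapse: pd.Series | None = None,
    covariate_cols: list[str] | None = None,
    n_restarts: int = 25,
    seed: int = 0,
    relapse_unknown: tuple[str, ...] = ("NA", "unknown", "Not sure"),
) -> dict:
    """Cluster the panel, label Low/High, and run the survival/enrichment tests.

    ``X_panel`` is genes x samples (expression-matrix orientation); samples
    must align with ``cohort``'s index.  Runs the two-group log-rank test, a
    Cox model of the Low indicator plus ``covariate_cols`` (already
    dummy-coded numeric columns, e.g. stage and age group), and — when
    ``relapse`` is given — a chi-square test of label x relapse with
    unknown-relapse samples excluded.
    """
    samples = [str(s) for s in X_panel.columns]
    missing = [s for s in samples if s not in cohort.index]
    if missing:
        raise ValueError(f"samples missing from the clinical table: {missing}")
    result = label_low_high(kmeans_two(X_panel.T, n_restarts=n_restarts, seed=seed))
    labels = result.labels
    cohort = cohort.loc[samples]

    logrank = ss.logrank_test(cohort["os_months"], cohort["event"], labels.to_numpy())

    model = cohort[["os_months", "event"]].copy()
    model["mhc_low"] = (labels == "Low").astype(float)
    cox_cols = ["mhc_low"]
    if covariate_cols:
        for c in covariate_cols:
            model[c] = pd.to_numeric(cohort[c], errors="coerce")
        cox_cols += list(covariate_cols)
    cox = ss.cox_fit(model.dropna(), cox_cols)

    report: dict = {
        "labels": labels,
        "stratification": result,
        "logrank": logrank,
        "cox": cox,
    }
    if relapse is not None:
        relapse = relapse.loc[samples].astype(str)
        known = ~relapse.isin(relapse_unknown)
        n_excluded = int((~known).sum())
        if n_excluded:
            logger.info("excluding %d sample(s) with unknown relapse status", n_excluded)
        tab = pd.crosstab(labels[known], relapse[known])
        report["relapse_excluded"] = n_excluded
        report["relapse_table"] = tab
        report["relapse_chi2"] = ss.chi_square_2xk(tab.to_numpy())
    return report
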