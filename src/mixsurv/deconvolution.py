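"""Marker-constrained semi-supervised NMF (KL divergence) for cell proportions.

Model
-----
Bulk expression is modelled as a linear mixture ``X ≈ W @ H`` where ``W``
(genes x r) holds per-cell-type expression profiles and ``H`` (r x samples)
the cell-type proportions.  Semi-supervision enters through marker genes:
a gene known to be expressed exclusively in one cell type is only allowed a
nonzero basis entry in that type's column.  The factorisation minimises the
generalised Kullback-Leibler divergence

    D(X || WH) = sum_ij [ x_ij * log(x_ij / (WH)_ij) - x_ij + (WH)_ij ]

with the classic multiplicative updates (which never increase D), re-applying
the marker mask after every basis update.

Identifiability
---------------
A masked KL-NMF determines each cell type's mixing row only up to a positive
scale factor.  The biological closure constraint — the modelled cell types
together make up 100% of the sample — resolves it: after convergence we find
non-negative per-type scalings ``d`` minimising ``|| H^T d - 1 ||`` (NNLS),
absorb ``1/d`` into ``W``, and project the rescaled columns of ``H`` onto the
simplex.  On noiseless mixtures this recovers the true proportions exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

logger = logging.getLogger(__name__)

#: numerical floor applied to allowed factor entries to avoid underflow
ENTRY_FLOOR = 1e-12
_TINY = 1e-300


@dataclass
class MarkerMask:
    """Binary genes x types support pattern for the basis matrix.

    ``matrix[i, t]`` is True iff gene *i* may load on cell type *t*.  Marker
    rows have exactly one allowed column; optional non-marker rows are
    unconstrained (all True).
    """

    genes: list[str]
    cell_types: list[str]
    matrix: np.ndarray
    dropped_ambiguous: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_types(self) -> int:
        return len(self.cell_types)


@dataclass
class DeconvolutionResult:
    """Fitted factorisation and simplex-normalised proportions."""

    basis: pd.DataFrame            # genes x types, masked entries exactly 0
    raw_mixing: pd.DataFrame       # types x samples, pre-normalisation H
    proportions: pd.DataFrame      # types x samples, columns sum to 1
    divergence_trace: np.ndarray   # KL divergence per iteration (best restart)
    n_iter: int
    seed: int
    restarts_tried: int

    @property
    def divergence(self) -> float:
        return float(self.divergence_trace[-1])


def build_marker_mask(
    markers: Mapping[str, Sequence[str]],
    gene_ids: Sequence[str],
    include_non_markers: bool = False,
) -> MarkerMask:
    """Match marker sets against the measured genes and build the mask.

    Matching is case-sensitive by ID.  Genes claimed by two or more sets are
    ambiguous and dropped (with a warning); a cell type with no matched marker
    raises.  With ``include_non_markers`` the remaining measured genes are
    appended as unconstrained rows (``all_genes`` mode).
    """
    if len(markers) < 2:
        raise ValueError("need at least two cell types for deconvolution")
    gene_ids = list(gene_ids)
    present = set(gene_ids)
    claimed: dict[str, list[str]] = {}
    for cell_type, genes in markers.items():
        for g in genes:
            if g in present:
                claimed.setdefault(g, []).append(cell_type)
    ambiguous = sorted(g for g, owners in claimed.items() if len(owners) > 1)
    if ambiguous:
        logger.warning("%d marker gene(s) claimed by multiple cell types dropped: %s",
                       len(ambiguous), ambiguous[:10])
    cell_types = list(markers)
    rows: list[str] = []
    for cell_type in cell_types:
        matched = [g for g in markers[cell_type] if g in present and g not in ambiguous]
        if not matched:
            raise ValueError(f"cell type {cell_type!r} has no matched marker genes")
        n_missing = sum(1 for g in markers[cell_type] if g not in present)
        if n_missing:
            logger.info("cell type %r: %d marker(s) absent from the data", cell_type, n_missing)
        rows.extend(matched)
    owner = {g: claimed[g][0] for g in rows}
    if include_non_markers:
        marker_set = set(rows)
        rows = rows + [g for g in gene_ids if g not in marker_set and g not in ambiguous]
    matrix = np.zeros((len(rows), len(cell_types)), dtype=bool)
    col = {t: k for k, t in enumerate(cell_types)}
    for i, g in enumerate(rows):
        if g in owner:
            matrix[i, col[owner[g]]] = True
        else:
            matrix[i, :] = True
    return MarkerMask(rows, cell_types, matrix, dropped_ambiguous=ambiguous)


def initialize(X: np.ndarray, mask: MarkerMask, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform(ε, 1) factors scaled so that mean(W0 @ H0) ≈ mean(X).

    Masked basis entries are set exactly to zero.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != mask.n_genes:
        raise ValueError("X row count does not match mask")
    mean_x = X.mean()
    if mean_x <= 0:
        raise ValueError("expression matrix is all zero")
    rng = np.random.default_rng(seed)
    n, r = mask.matrix.shape
    p = X.shape[1]
    W0 = rng.uniform(ENTRY_FLOOR, 1.0, (n, r))
    H0 = rng.uniform(ENTRY_FLOOR, 1.0, (r, p))
    W0[~mask.matrix] = 0.0
    scale = mean_x / max((W0 @ H0).mean(), _TINY)
    W0 *= np.sqrt(scale)
    H0 *= np.sqrt(scale)
    return W0, H0


def kl_divergence(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalised KL divergence D(X || WH), with 0·log 0 := 0.

    Returns ``inf`` if the model assigns zero where the data are positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(W, dtype=float) @ np.asarray(H, dtype=float)
    pos = X > 0
    if np.any(Y[pos] == 0):
        return float("inf")
    terms = Y - X
    terms[pos] += X[pos] * np.log(X[pos] / Y[pos])
    return float(terms.sum())


def update_step(
    W: np.ndarray, H: np.ndarray, X: np.ndarray, mask: MarkerMask
) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative KL update of H then W, re-applying the marker mask.

    These are the standard divergence-reducing rules
    ``H_tj <- H_tj * [sum_i W_it x_ij/(WH)_ij] / sum_i W_it`` followed by the
    symmetric W rule against the updated H; masked basis entries are forced
    back to zero and allowed entries floored at 1e-12 against underflow.
    """
    X = np.asarray(X, dtype=float)
    ratio = X / np.maximum(W @ H, _TINY)
    H_new = H * (W.T @ ratio) / np.maximum(W.sum(axis=0)[:, None], _TINY)
    H_new = np.maximum(H_new, ENTRY_FLOOR)
    ratio = X / np.maximum(W @ H_new, _TINY)
    W_new = W * (ratio @ H_new.T) / np.maximum(H_new.sum(axis=1)[None, :], _TINY)
    W_new = np.maximum(W_new, ENTRY_FLOOR)
    W_new[~mask.matrix] = 0.0
    return W_new, H_new


def _run_single(X, mask, seed, max_iter, tol):
    W, H = initialize(X, mask, seed)
    trace = [kl_divergence(X, W, H)]
    for _ in range(max_iter):
        W, H = update_step(W, H, X, mask)
        d = kl_divergence(X, W, H)
        trace.append(d)
        prev = trace[-2]
        if not np.isfinite(d):
            break
        if prev == 0 or abs(prev - d) / max(prev, _TINY) < tol:
            break
    return W, H, np.asarray(trace)


def fit(
    X: pd.DataFrame,
    markers: Mapping[str, Sequence[str]],
    *,
    mode: str = "markers_only",
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 10,
    seed: int = 42,
) -> DeconvolutionResult:
    """Estimate cell-type proportions from a genes x samples matrix.

    Runs ``n_restarts`` seeded initialisations of the masked multiplicative
    KL-NMF, iterating until the relative divergence change drops below
    ``tol`` (or ``max_iter``), and keeps the lowest-divergence run.  ``mode``
    is ``"markers_only"`` (fit on the matched marker-gene union; default) or
    ``"all_genes"`` (retain non-marker genes as unconstrained rows).

    Negative input values are floored at zero.  The returned proportions have
    simplex columns; the per-type scale is fixed by the 100%-closure NNLS
    step described in the module docstring.
    """
    if mode not in ("markers_only", "all_genes"):
        raise ValueError(f"unknown mode {mode!r}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    mask = build_marker_mask(markers, X.index, include_non_markers=(mode == "all_genes"))
    X_fit = np.maximum(X.loc[mask.genes].to_numpy(dtype=float), 0.0)
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % np.uint32(2**31)

    best = None
    for s in sub_seeds:
        W, H, trace = _run_single(X_fit, mask, int(s), max_iter, tol)
        if not np.isfinite(trace[-1]):
            continue
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    if best is None:
        raise RuntimeError(
            f"deconvolution failed: non-finite divergence in all {n_restarts} restart(s)")
    W, H, trace = best

    # closure constraint: scale H rows so sample columns sum to ~1
    d, _res = scipy.optimize.nnls(H.T, np.ones(H.shape[1]))
    zero_rows = [mask.cell_types[t] for t in range(len(d)) if d[t] <= 0]
    if zero_rows:
        logger.warning("cell type(s) %s have an all-zero mixing row; proportion set to 0",
                       zero_rows)
    H_scaled = d[:, None] * H
    W_scaled = np.where(d[None, :] > 0, W / np.where(d[None, :] > 0, d[None, :], 1.0), W)
    col_sums = H_scaled.sum(axis=0)
    proportions = H_scaled / np.maximum(col_sums, _TINY)

    genes = pd.Index(mask.genes, name="gene_id")
    types = pd.Index(mask.cell_types, name="cell_type")
    return DeconvolutionResult(
        basis=pd.DataFrame(W_scaled, index=genes, columns=types),
        raw_mixing=pd.DataFrame(H, index=types, columns=X.columns),
        proportions=pd.DataFrame(proportions, index=types, columns=X.columns),
        divergence_trace=trace,
        n_iter=len(trace) - 1,
        seed=seed,
        restarts_tried=n_restarts,
    )


def evaluate_recovery(true_H: pd.DataFrame, est_H: pd.DataFrame) -> dict[str, float]:
    """Mean absolute difference and Pearson r between proportion matrices.

    Cell-type identity is fixed by the marker mask, so entries are compared
    directly (aligned by label when both are DataFrames, flattened).  With
    zero variance in either input the correlation is undefined and returned
    as ``nan``.
    """
    if isinstance(true_H, pd.DataFrame) and isinstance(est_H, pd.DataFrame):
        est_H = est_H.loc[true_H.index, true_H.columns]
    t = np.asarray(true_H, dtype=float).ravel()
    e = np.asarray(est_H, dtype=float).ravel()
    if t.shape != e.shape:
        raise ValueError("proportion matrices have mismatched shapes")
    mad = float(np.mean(np.abs(t - e)))
    if np.ptp(t) == 0 or np.ptp(e) == 0:
        warnings.warn("zero-variance proportions: Pearson r undefined")
        return {"mad": mad, "pearson_r": float("nan")}
    r, _p = scipy.stats.pearsonr(t, e)
    return {"mad": mad, "pearson_r": float(r)}
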