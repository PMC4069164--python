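"""Synthetic-data generators for every stage of the pipeline.

The generators emulate the three kinds of inputs the analysis consumes:

* cell-type signature matrices with type-exclusive marker genes, and bulk
  mixtures ``X = W @ H + noise`` with Dirichlet-distributed ground-truth
  proportions (for testing deconvolution recovery);
* right-censored overall-survival cohorts following a two-group proportional
  hazards model (for testing Kaplan-Meier / log-rank / Cox machinery);
* small expression panels with two planted mean-level clusters, mimicking an
  MHC-gene panel split into antigen-presentation Low/High groups.

All randomness flows from a single integer seed per call; sub-streams are
derived deterministically with :class:`numpy.random.SeedSequence`, so equal
seeds give bit-identical outputs.

Intensity parameters are on a natural-log scale and drawn lognormal: bulk
microarray intensities are positive and right-skewed.  Defaults put marker
genes around 1000 intensity units and background genes around 100, with
within-type log-sd 0.5 — the shape of a quantile-normalised bead array after
background subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio

DEFAULT_MARKER_MEAN = math.log(1000.0)
DEFAULT_BACKGROUND_MEAN = math.log(100.0)
#: additive noise sd on the intensity scale; ~10% of a typical mixed marker signal
DEFAULT_NOISE_SD = 30.0


@dataclass(frozen=True)
class SignatureSpec:
    """Parameters of a synthetic cell-type signature matrix."""

    cell_types: tuple[str, ...]
    markers_per_type: int = 20
    background_genes: int = 100
    marker_mean: float = DEFAULT_MARKER_MEAN
    background_mean: float = DEFAULT_BACKGROUND_MEAN
    within_type_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) < 1:
            raise ValueError("at least one cell type required")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell type names must be unique")
        if self.markers_per_type < 1:
            raise ValueError("markers_per_type must be >= 1")
        if self.background_genes < 0:
            raise ValueError("background_genes must be >= 0")
        for name in ("marker_mean", "background_mean", "within_type_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.within_type_sd < 0:
            raise ValueError("within_type_sd must be >= 0")


@dataclass
class MixtureDataset:
    """A synthetic bulk dataset with known composition.

    ``expression`` is genes x samples, ``true_proportions`` is cell types x
    samples with simplex columns, and ``marker_sets`` names the exclusive
    marker genes of each type.
    """

    expression: pd.DataFrame
    true_proportions: pd.DataFrame
    marker_sets: dict[str, list[str]]
    noise_sd: float
    seed: int

    def write(self, directory: str | Path) -> None:
        """Write the standard fixture files (expression TSV, GMT, truth TSV)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mio.write_expression_tsv(self.expression, directory / "expression.tsv")
        mio.write_gmt(self.marker_sets, directory / "markers.gmt")
        mio.write_expression_tsv(
            self.true_proportions.rename_axis("cell_type"),
            directory / "true_proportions.tsv",
        )


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Two-group exponential proportional-hazards simulation parameters.

    ``beta`` is the log hazard ratio of the flagged (e.g. marker-Low) group;
    rates are per month.  Censoring is independent exponential truncated at an
    administrative ``max_followup``.
    """

    n_samples: int
    beta: float = math.log(2.23)
    baseline_rate: float = 0.02
    censor_rate: float = 0.008
    max_followup: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.baseline_rate <= 0 or self.censor_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be > 0")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


def generate_signatures(spec: SignatureSpec) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Draw a genes x types basis matrix with type-exclusive marker blocks.

    Marker genes of type *t* are lognormal in column *t* and exactly zero in
    every other column; background genes are lognormal (at a lower mean) in
    all columns.  Returns the basis and the marker-set collection.
    """
    rng = np.random.default_rng(spec.seed)
    r = len(spec.cell_types)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    marker_sets: dict[str, list[str]] = {}
    for t, cell_type in enumerate(spec.cell_types):
        names = [f"{cell_type}_M{k + 1}" for k in range(spec.markers_per_type)]
        marker_sets[cell_type] = names
        gene_ids.extend(names)
        vals = rng.lognormal(spec.marker_mean, spec.within_type_sd, spec.markers_per_type)
        block = np.zeros((spec.markers_per_type, r))
        block[:, t] = vals
        rows.append(block)
    if spec.background_genes:
        gene_ids.extend(f"BG{k + 1}" for k in range(spec.background_genes))
        rows.append(rng.lognormal(spec.background_mean, spec.within_type_sd,
                                  (spec.background_genes, r)))
    basis = pd.DataFrame(np.vstack(rows), index=pd.Index(gene_ids, name="gene_id"),
                         columns=list(spec.cell_types))
    return basis, marker_sets


def generate_mixtures(
    true_basis: pd.DataFrame,
    n_samples: int,
    dirichlet_alpha,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    marker_sets: dict[str, list[str]] | None = None,
) -> MixtureDataset:
    """Mix the basis with Dirichlet proportions plus additive Gaussian noise.

    ``expression = true_basis @ H + N(0, noise_sd)`` clamped at zero; the
    columns of the true proportion matrix ``H`` are i.i.d.
    Dirichlet(``dirichlet_alpha``) and sum to one.
    """
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    r = true_basis.shape[1]
    if alpha.shape != (r,):
        raise ValueError(f"dirichlet_alpha must have length {r}, got {alpha.shape}")
    if np.any(alpha <= 0):
        raise ValueError("dirichlet_alpha entries must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    h_true = rng.dirichlet(alpha, size=n_samples).T  # r x n_samples
    clean = true_basis.to_numpy() @ h_true
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, clean.shape)
    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]
    expression = pd.DataFrame(np.maximum(clean, 0.0), index=true_basis.index,
                              columns=sample_ids)
    proportions = pd.DataFrame(h_true, index=true_basis.columns, columns=sample_ids)
    if marker_sets is None:
        marker_sets = {
            t: [g for g in true_basis.index
                if (true_basis.loc[g] > 0).sum() == 1 and true_basis.at[g, t] > 0]
            for t in true_basis.columns
        }
    return MixtureDataset(expression, proportions, dict(marker_sets), noise_sd, seed)


def generate_survival(low_group_flags, spec: SurvivalSimSpec) -> pd.DataFrame:
    """Simulate right-censored overall survival for flagged/unflagged samples.

    Event times are exponential with hazard ``baseline_rate * exp(beta*flag)``;
    censoring times are exponential(``censor_rate``) truncated at
    ``max_followup``.  Returns a cohort DataFrame indexed by sample_id with
    ``os_months``, ``event`` and a ``group`` column ("Low" for flag 1).
    """
    flags = np.asarray(low_group_flags)
    if flags.ndim != 1 or flags.shape[0] != spec.n_samples:
        raise ValueError("low_group_flags must be a 1-D array of length n_samples")
    if not np.isin(flags, [0, 1]).all():
        raise ValueError("low_group_flags must be binary")
    flags = flags.astype(int)
    rng = np.random.default_rng(spec.seed)
    hazard = spec.baseline_rate * np.exp(spec.beta * flags)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.minimum(rng.exponential(1.0 / spec.censor_rate, spec.n_samples),
                             spec.max_followup)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    sample_ids = [f"S{j + 1:03d}" for j in range(spec.n_samples)]
    return pd.DataFrame(
        {
            "os_months": observed,
            "event": event,
            "group": np.where(flags == 1, "Low", "High"),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def generate_mhc_panel(
    n_samples: int = 139,
    n_genes: int = 18,
    cluster_fraction: float = 0.5,
    separation: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a genes x samples panel with two planted mean-level clusters.

    A ``cluster_fraction`` share of samples sit at a low base level and the
    rest ``separation`` units higher, with per-gene baselines and Gaussian
    noise; values are clamped at zero.  Returns the panel and the true labels
    (0 = low cluster, 1 = high cluster) for recovery tests.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not 0.0 < cluster_fraction < 1.0:
        raise ValueError("cluster_fraction must be in (0, 1)")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_low = int(round(cluster_fraction * n_samples))
    n_low = min(max(n_low, 1), n_samples - 1)  # both clusters non-empty
    labels = np.zeros(n_samples, dtype=int)
    labels[rng.permutation(n_samples)[: n_samples - n_low]] = 1
    base = 6.0 + rng.normal(0.0, 0.5, n_genes)  # per-gene baseline level
    values = base[:, None] + separation * labels[None, :]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.shape)
    gene_ids = [f"MHC{g + 1}" for g in range(n_genes)]
    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]
    panel = pd.DataFrame(np.maximum(values, 0.0),
                         index=pd.Index(gene_ids, name="gene_id"),
                         columns=sample_ids)
    return panel, labels
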