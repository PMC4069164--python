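"""End-to-end drivers: the blood (PBMC) arm and the tissue (MHC) arm.

The blood arm deconvolves immune-cell proportions from bulk PBMC expression,
median-splits each cell type into Low/High, screens cell types and clinical
factors by log-rank, and fits a multivariate Cox model on everything the
screen selects.  The tissue arm two-means-clusters samples on an MHC gene
panel, labels the low-expression cluster, and tests it by log-rank, adjusted
Cox and relapse chi-square.

Every run is driven by a :class:`RunConfig` (loadable from YAML) and a single
seed; reports are JSON/TSV with the config hash and seed in a header, and two
runs with the same config and seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconvolution, io as mio, stratification, survival as ss

logger = logging.getLogger(__name__)


@dataclass
class DeconvolutionParams:
    mode: str = "markers_only"
    restarts: int = 10
    max_iter: int = 2000
    tol: float = 1e-6


@dataclass
class PbmcArmConfig:
    expression: str
    markers: str
    clinical: str
    deconvolution: DeconvolutionParams = field(default_factory=DeconvolutionParams)
    screen_factors: list[str] = field(default_factory=list)
    #: {factor: reference level} for dummy coding; default = most frequent level
    references: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05


@dataclass
class TissueArmConfig:
    expression: str
    panel: str
    clinical: str
    relapse_col: str | None = None
    #: categorical clinical factors adjusted for in the Cox model
    covariates: list[str] = field(default_factory=list)
    references: dict[str, str] = field(default_factory=dict)
    kmeans_restarts: int = 25
    alpha: float = 0.05


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 42
    pbmc: PbmcArmConfig | None = None
    tissue: TissueArmConfig | None = None

    def __post_init__(self) -> None:
        for arm in (self.pbmc, self.tissue):
            if arm is not None and not 0 < arm.alpha < 1:
                raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        pbmc = raw.get("pbmc")
        tissue = raw.get("tissue")
        if pbmc is not None:
            dec = pbmc.pop("deconvolution", {})
            pbmc = PbmcArmConfig(deconvolution=DeconvolutionParams(**dec), **pbmc)
        if tissue is not None:
            tissue = TissueArmConfig(**tissue)
        return cls(out_dir=raw["out_dir"], seed=int(raw.get("seed", 42)),
                   pbmc=pbmc, tissue=tissue)

    def hash(self) -> str:
        """SHA-256 over the canonical config, excluding the output directory.

        Keeping out_dir out of the hash means the same analysis written to two
        different directories yields byte-identical reports.
        """
        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_report(report: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _majority_reference(cohort: pd.DataFrame, factor: str,
                        exclude=("NA", "Not sure")) -> str:
    usable = cohort.loc[~cohort[factor].isin(exclude), factor]
    return usable.value_counts().idxmax()


def _dummy_block(cohort: pd.DataFrame, factors: list[str],
                 references: dict[str, str]) -> pd.DataFrame:
    blocks = []
    for factor in factors:
        ref = references.get(factor) or _majority_reference(cohort, factor)
        blocks.append(ss.dummy_code(cohort, factor, ref))
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=cohort.index)


def run_pbmc_arm(config: RunConfig) -> dict:
    """Deconvolve, screen per-cell-type survival, and fit the joint Cox model."""
    assert config.pbmc is not None, "config has no pbmc arm"
    cfg = config.pbmc
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"config_hash={config.hash()}", f"seed={config.seed}"]

    expr = mio.read_expression_tsv(cfg.expression)
    markers = mio.read_gmt(cfg.markers)
    clinical = mio.read_clinical_tsv(cfg.clinical)

    shared = [s for s in expr.columns if s in clinical.index]
    if not shared:
        raise ValueError("no samples shared between expression and clinical tables")
    dropped = expr.shape[1] - len(shared)
    if dropped:
        logger.warning("pbmc arm: %d expression sample(s) lack clinical data", dropped)
    expr = expr[shared]
    clinical = clinical.loc[shared]

    dec = deconvolution.fit(
        expr, markers, mode=cfg.deconvolution.mode,
        max_iter=cfg.deconvolution.max_iter, tol=cfg.deconvolution.tol,
        n_restarts=cfg.deconvolution.restarts, seed=config.seed,
    )
    mio.write_expression_tsv(dec.proportions.T.rename_axis("sample_id"),
                             out / "proportions.tsv", header_comments=header)
    logger.info("deconvolution done in %.2fs (divergence %.4g, %d iterations)",
                time.perf_counter() - t0, dec.divergence, dec.n_iter)

    # per-cell-type median split + log-rank screen
    cell_rows = []
    splits: dict[str, pd.Series] = {}
    for cell_type in dec.proportions.index:
        split = ss.median_split(dec.proportions.loc[cell_type])
        splits[cell_type] = split.labels
        n_low = int((split.labels == "Low").sum())
        if n_low in (0, len(split.labels)) or clinical["event"].sum() == 0:
            cell_rows.append({"cell_type": cell_type, "median": split.split_value,
                              "n_low": n_low, "chi2": np.nan, "p": np.nan,
                              "selected": False})
            continue
        res = ss.logrank_test(clinical["os_months"], clinical["event"],
                              split.labels.to_numpy())
        cell_rows.append({"cell_type": cell_type, "median": split.split_value,
                          "n_low": n_low, "chi2": res.chi2, "p": res.p,
                          "selected": bool(res.p < cfg.alpha)})
    cell_table = pd.DataFrame(cell_rows).set_index("cell_type")

    # KM curves per group for each cell type
    km_rows = []
    for cell_type, labels in splits.items():
        for grp in ("Low", "High"):
            in_grp = labels == grp
            if in_grp.sum() == 0:
                continue
            curve = ss.km_curve(clinical.loc[in_grp.to_numpy(), "os_months"],
                                clinical.loc[in_grp.to_numpy(), "event"])
            for t, n, d, s in zip(curve.event_times, curve.at_risk,
                                  curve.events, curve.survival):
                km_rows.append({"cell_type": cell_type, "group": grp, "time": t,
                                "at_risk": int(n), "events": int(d), "survival": s})
    km_table = pd.DataFrame(km_rows)

    screen = (ss.univariate_screen(clinical, cfg.screen_factors, alpha=cfg.alpha)
              if cfg.screen_factors else None)

    # multivariate Cox: selected cell types (Low indicator) + selected factors
    selected_cells = [c for c in cell_table.index if cell_table.at[c, "selected"]]
    selected_factors = ([f for f in screen.index if screen.at[f, "selected"]]
                        if screen is not None else [])
    cox_payload = None
    if selected_cells or selected_factors:
        model = clinical[["os_months", "event"]].copy()
        cols = []
        for cell_type in selected_cells:
            col = f"{cell_type}[Low vs High]"
            model[col] = (splits[cell_type] == "Low").astype(float)
            cols.append(col)
        dummies = _dummy_block(clinical, selected_factors, cfg.references)
        model = pd.concat([model, dummies], axis=1)
        cols += list(dummies.columns)
        cox = ss.cox_fit(model.dropna(), cols)
        cox_payload = {
            "converged": cox.converged,
            "log_likelihood": cox.log_likelihood,
            "coefficients": (cox.summary.round(10).reset_index()
                             .to_dict(orient="records") if cox.converged else None),
            "message": cox.message,
        }
    else:
        logger.info("pbmc arm: nothing significant in the screen; "
                    "multivariate model skipped")

    km_path = out / "km_curves.tsv"
    with open(km_path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        km_table.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    report = {
        "arm": "pbmc",
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_samples": len(shared),
        "deconvolution": {
            "divergence": dec.divergence,
            "n_iter": dec.n_iter,
            "restarts": dec.restarts_tried,
        },
        "cell_type_logrank": cell_table.round(10).reset_index().to_dict(orient="records"),
        "clinical_screen": (screen.round(10).reset_index().to_dict(orient="records")
                            if screen is not None else None),
        "multivariate_cox": cox_payload,
    }
    _write_report(report, out / "pbmc_report.json")
    logger.info("pbmc arm finished in %.2fs", time.perf_counter() - t0)
    return report


def run_tissue_arm(config: RunConfig) -> dict:
    """Stratify tissue samples on the MHC panel and test prognosis/relapse."""
    assert config.tissue is not None, "config has no tissue arm"
    cfg = config.tissue
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"config_hash={config.hash()}", f"seed={config.seed}"]

    panel_path = Path(cfg.panel)
    if not panel_path.exists():
        raise FileNotFoundError(f"panel gene list not found: {panel_path}")
    panel_genes = [l.strip() for l in panel_path.read_text(encoding="utf-8").splitlines()
                   if l.strip() and not l.startswith("#")]
    expr = mio.read_expression_tsv(cfg.expression)
    matched = [g for g in panel_genes if g in expr.index]
    if not matched:
        raise ValueError("no panel genes found in the expression matrix")
    if len(matched) < len(panel_genes):
        logger.warning("tissue arm: %d panel gene(s) absent from the data",
                       len(panel_genes) - len(matched))
    clinical = mio.read_clinical_tsv(cfg.clinical)

    dummies = _dummy_block(clinical, cfg.covariates, cfg.references)
    cohort = pd.concat([clinical[["os_months", "event"]], dummies], axis=1)
    relapse = (clinical[cfg.relapse_col] if cfg.relapse_col else None)

    res = stratification.stratify_and_test(
        expr.loc[matched], cohort, relapse=relapse,
        covariate_cols=list(dummies.columns),
        n_restarts=cfg.kmeans_restarts, seed=config.seed,
    )

    labels_path = out / "mhc_labels.tsv"
    with open(labels_path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        res["labels"].rename("mhc_group").to_csv(fh, sep="\t", lineterminator="\n")
    strat = res["stratification"]
    centroids = pd.DataFrame(strat.centroids, index=["cluster0", "cluster1"],
                             columns=matched)
    with open(out / "mhc_centroids.tsv", "w", encoding="utf-8", newline="\n") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        centroids.to_csv(fh, sep="\t", index_label="cluster", lineterminator="\n")

    cox = res["cox"]
    report = {
        "arm": "tissue",
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_samples": int(len(res["labels"])),
        "n_low": int((res["labels"] == "Low").sum()),
        "panel_genes_used": matched,
        "kmeans": {"inertia": strat.inertia, "n_iter": strat.n_iter},
        "logrank": {"chi2": res["logrank"].chi2, "df": res["logrank"].df,
                    "p": res["logrank"].p},
        "multivariate_cox": {
            "converged": cox.converged,
            "log_likelihood": cox.log_likelihood,
            "coefficients": (cox.summary.round(10).reset_index()
                             .to_dict(orient="records") if cox.converged else None),
            "message": cox.message,
        },
        "relapse_chi2": res.get("relapse_chi2"),
        "relapse_excluded": res.get("relapse_excluded"),
        "relapse_table": (res["relapse_table"].to_dict() if "relapse_table" in res
                          else None),
    }
    _write_report(report, out / "tissue_report.json")
    logger.info("tissue arm finished in %.2fs", time.perf_counter() - t0)
    return report


def run(config: RunConfig) -> dict:
    """Run whichever arms the config defines; returns {arm: report}."""
    if config.pbmc is None and config.tissue is None:
        raise ValueError("config defines neither a pbmc nor a tissue arm")
    reports = {}
    if config.pbmc is not None:
        reports["pbmc"] = run_pbmc_arm(config)
    if config.tissue is not None:
        reports["tissue"] = run_tissue_arm(config)
    return reports
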