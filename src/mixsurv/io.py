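"""Tabular input/output: expression matrices, GMT marker sets, clinical tables.

Conventions
-----------
Expression matrices are :class:`pandas.DataFrame` with genes (or probes) in
rows and samples in columns; the first TSV column holds the row identifier.
Marker collections are ordered ``dict[str, list[str]]`` mapping cell-type name
to gene IDs.  Clinical cohorts are DataFrames indexed by ``sample_id`` with an
``os_months`` float column, a binary ``event`` column and any number of
categorical covariate columns stored as strings.

Lines starting with ``#`` in any of these files are metadata comments
(run provenance headers) and are skipped on read.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_CLINICAL_COLUMNS = ("sample_id", "os_months", "event")


class ParseError(ValueError):
    """A malformed input table (ragged row, duplicate ID, non-numeric cell)."""


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column = row ID, header = sample IDs).

    Raises :class:`ParseError` on ragged rows, duplicated row or sample IDs,
    or non-numeric cells, naming the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows: pandas names the line
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row IDs {dupes}")
    # pandas mangles duplicate header names; check the raw header line instead
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                sample_ids = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise ParseError(f"{path}: empty file")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample IDs {dupes}")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna()
    if bad.to_numpy().any():
        row = bad.any(axis=1).idxmax()
        raise ParseError(f"{path}: non-numeric cell in row {row!r}")
    if values.isna().to_numpy().any():
        row = values.isna().any(axis=1).idxmax()
        raise ParseError(f"{path}: missing cell in row {row!r}")
    values.index = values.index.astype(str)
    values.index.name = df.index.name or "gene_id"
    return values


def write_expression_tsv(
    matrix: pd.DataFrame, path: str | Path, header_comments: Sequence[str] = ()
) -> None:
    """Write a genes x samples matrix as TSV, with optional ``#`` header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", index_label=matrix.index.name or "gene_id",
                      lineterminator="\n")


def collapse_probes(
    probe_matrix: pd.DataFrame, annotation: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    Probes mapping to zero gene IDs (including probes absent from
    ``annotation``) and probes mapping to more than one gene ID are dropped;
    each gene's value is the arithmetic mean of its uniquely-mapped probes,
    per sample.
    """
    gene_of: dict[str, str] = {}
    for probe in probe_matrix.index:
        genes = list(annotation.get(probe, ()))
        if len(genes) == 1:
            gene_of[probe] = str(genes[0])
    if not gene_of:
        raise ValueError("no probe maps uniquely to a gene ID")
    kept = probe_matrix.loc[list(gene_of)]
    collapsed = kept.groupby(
        pd.Index([gene_of[p] for p in kept.index], name="gene_id"), sort=False
    ).mean()
    n_dropped = probe_matrix.shape[0] - kept.shape[0]
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped/multi-mapped probes", n_dropped)
    return collapsed


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT v1 gene-set file into an ordered {set name: gene list} map.

    Each line is ``name<TAB>description<TAB>gene...``.  Duplicate genes within
    a set are stored once (with a logged warning); a line with fewer than two
    columns, an empty gene list, or a repeated set name is a parse error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected name<TAB>description, got {len(fields)} column(s)")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning("gene set %r lists %d duplicate gene(s); de-duplicated",
                               name, len(genes) - len(unique))
            sets[name] = unique
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return sets


def write_gmt(marker_sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in marker_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Read a clinical table with columns sample_id, os_months, event, covariates.

    Covariates are kept as categorical strings ("Not sure" stays its own
    category); missing covariate cells become the category ``"NA"``.  Negative
    survival times and non-binary event flags raise with the sample ID named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample_id {dupes}")
    df = df.set_index("sample_id")
    times = pd.to_numeric(df["os_months"], errors="coerce")
    if times.isna().any() or (times < 0).any():
        bad = times.index[times.isna() | (times < 0)][0]
        raise ParseError(f"{path}: invalid os_months for sample {bad!r}")
    events = pd.to_numeric(df["event"], errors="coerce")
    if events.isna().any() or ~events.isin([0, 1]).all():
        bad = events.index[events.isna() | ~events.isin([0, 1])][0]
        raise ParseError(f"{path}: event must be 0/1; offending sample {bad!r}")
    out = df.copy()
    out["os_months"] = times.astype(float)
    out["event"] = events.astype(int)
    covars = [c for c in out.columns if c not in ("os_months", "event")]
    for c in covars:
        out[c] = out[c].fillna("NA").astype(str)
    return out


def write_clinical_tsv(cohort: pd.DataFrame, path: str | Path,
                       header_comments: Sequence[str] = ()) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        cohort.to_csv(fh, sep="\t", index_label="sample_id", lineterminator="\n")
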