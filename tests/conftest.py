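"""Shared fixtures: synthetic datasets and on-disk pipeline inputs."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mixsurv import io as mio, simulate


@pytest.fixture(scope="session")
def four_type_signatures():
    spec = simulate.SignatureSpec(cell_types=("Jurkat", "IM9", "Raji", "THP1"), seed=11)
    return simulate.generate_signatures(spec)


@pytest.fixture(scope="session")
def noisy_mixture(four_type_signatures):
    basis, markers = four_type_signatures
    return simulate.generate_mixtures(basis, 24, [1.0] * 4, seed=12, marker_sets=markers)


@pytest.fixture(scope="session")
def noiseless_mixture(four_type_signatures):
    basis, markers = four_type_signatures
    return simulate.generate_mixtures(basis, 12, [1.0] * 4, noise_sd=0.0, seed=13,
                                      marker_sets=markers)


def make_pbmc_fixture(directory: Path, n_samples: int = 108, beta: float = math.log(2.23),
                      seed: int = 0) -> Path:
    """Write a full blood-arm fixture (expression, GMT, clinical) to disk.

    Survival is driven by the true T-cell proportion (Low half at excess
    hazard exp(beta)); stage/age/gender covariates are independent noise.
    """
    rng = np.random.default_rng(seed)
    spec = simulate.SignatureSpec(cell_types=("B", "T", "NK", "DC", "Mono"),
                                  seed=seed + 1)
    basis, markers = simulate.generate_signatures(spec)
    mix = simulate.generate_mixtures(basis, n_samples, [1.0] * 5, seed=seed + 2,
                                     marker_sets=markers)
    directory.mkdir(parents=True, exist_ok=True)
    mix.write(directory)
    tprop = mix.true_proportions.loc["T"]
    flags = (tprop < tprop.median()).astype(int).to_numpy()
    surv = simulate.generate_survival(
        flags, simulate.SurvivalSimSpec(n_samples=n_samples, beta=beta, seed=seed + 3)
    ).drop(columns="group")
    surv.index = pd.Index(mix.expression.columns, name="sample_id")
    surv["stage"] = rng.choice(["I", "II-III"], n_samples)
    surv["age_group"] = rng.choice(["<68", ">=68"], n_samples)
    surv["gender"] = rng.choice(["male", "female"], n_samples)
    mio.write_clinical_tsv(surv, directory / "clinical.tsv")
    return directory


def make_tissue_fixture(directory: Path, n_samples: int = 139, separation: float = 3.0,
                        beta: float = math.log(2.45), seed: int = 0) -> Path:
    """Write a tissue-arm fixture (panel expression, gene list, clinical)."""
    rng = np.random.default_rng(seed)
    panel, labels = simulate.generate_mhc_panel(n_samples, 18, separation=separation,
                                                noise_sd=1.0, seed=seed + 1)
    directory.mkdir(parents=True, exist_ok=True)
    mio.write_expression_tsv(panel, directory / "tissue_expression.tsv")
    (directory / "panel.txt").write_text("\n".join(panel.index) + "\n", encoding="utf-8")
    flags = (labels == 0).astype(int)  # low-MHC cluster carries the excess hazard
    surv = simulate.generate_survival(
        flags, simulate.SurvivalSimSpec(n_samples=n_samples, beta=beta, seed=seed + 2)
    ).drop(columns="group")
    surv.index = pd.Index(panel.columns, name="sample_id")
    surv["stage"] = rng.choice(["I", "II-III"], n_samples)
    surv["age_group"] = rng.choice(["<62", ">=62"], n_samples)
    relapse = np.where(rng.random(n_samples) < np.where(flags == 1, 0.55, 0.25),
                       "yes", "no").astype(object)
    relapse[rng.choice(n_samples, 2, replace=False)] = "unknown"
    surv["relapse"] = relapse
    mio.write_clinical_tsv(surv, directory / "clinical.tsv")
    return directory


@pytest.fixture()
def pbmc_fixture_dir(tmp_path):
    return make_pbmc_fixture(tmp_path / "pbmc", seed=100)


@pytest.fixture()
def tissue_fixture_dir(tmp_path):
    return make_tissue_fixture(tmp_path / "tissue", seed=200)
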