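# mixsurv

Immune-cell deconvolution of bulk gene expression and survival analysis of
the estimated proportions.

Bulk expression profiles of blood (PBMC) or tissue are mixtures: each
measured intensity is a weighted sum of the expression of the constituent
cell types, with weights equal to the cell-type proportions.  `mixsurv`
estimates those proportions, asks whether they carry prognostic information
for patient overall survival, and — for tissue cohorts — stratifies samples
by the expression of an MHC (antigen-presentation) gene panel.  It is aimed
at retrospective analyses of banked specimens, where flow cytometry is
impossible but expression arrays exist, and ships a synthetic-data module so
every stage is testable with known ground truth.

## The model

Expression of gene *i* in sample *j* is modelled as a linear combination
over *r* cell types,

    x_ij = Σ_t  w_it · h_tj + ε_ij        (X ≈ W·H,  all entries ≥ 0)

where `W` (genes × r) holds per-type expression profiles and `H`
(r × samples) the proportions.  The factorisation minimises the generalised
Kullback–Leibler divergence

    D(X‖WH) = Σ_ij [ x_ij·log(x_ij/(WH)_ij) − x_ij + (WH)_ij ]

by multiplicative updates, with a *marker constraint*: a gene known to be
expressed exclusively in one cell type may only load on that type's column
of `W` (all other entries are held at exactly zero).  Because the modelled
cell types together make up 100% of the sample, the per-type scale left free
by the factorisation is resolved by a non-negative least-squares fit of
`Hᵀd ≈ 1`, after which columns of `H` are simplex-normalised to give
proportions.

Downstream, each cell type's proportion is median-split into Low
(< median) / High (≥ median) groups, group survival is compared by
Kaplan–Meier curves and the log-rank test, and independent prognostic value
is assessed by multivariate Cox proportional-hazards regression (Efron tie
handling, Wald CIs).  Tissue samples are stratified by two-means (k = 2
Lloyd) clustering of an MHC gene panel under plain Euclidean distance, the
lower-expression cluster labelled "Low"; relapse enrichment in the Low group
is tested by Pearson chi-square.

## Worked example

```python
import math
from mixsurv import simulate, deconvolution as dec, survival as ss

# 5-type signatures with exclusive markers; 108 mixed samples
spec = simulate.SignatureSpec(cell_types=("B", "T", "NK", "DC", "Mono"), seed=1)
basis, markers = simulate.generate_signatures(spec)
mix = simulate.generate_mixtures(basis, 108, [1.0] * 5, seed=2, marker_sets=markers)

res = dec.fit(mix.expression, markers, n_restarts=10, seed=42)
print(dec.evaluate_recovery(mix.true_proportions, res.proportions))
# {'mad': 0.0054, 'pearson_r': 0.9991}

# survival driven by the true T-cell proportion (Low half at hazard ratio 2.23)
tprop = mix.true_proportions.loc["T"]
flags = (tprop < tprop.median()).astype(int).to_numpy()
cohort = simulate.generate_survival(
    flags, simulate.SurvivalSimSpec(n_samples=108, beta=math.log(2.23), seed=3))

split = ss.median_split(res.proportions.loc["T"])
lr = ss.logrank_test(cohort["os_months"].to_numpy(), cohort["event"].to_numpy(),
                     split.labels.to_numpy())
cohort["t_low"] = (split.labels == "Low").to_numpy().astype(float)
cox = ss.cox_fit(cohort, ["t_low"])
```

This run prints a recovery of MAD 0.0054 / Pearson r 0.9991 against the
known mixing proportions, a log-rank chi² of 7.27 (p = 0.0070) for the
estimated-T-cell Low vs High split, and a Cox hazard ratio of 1.82
(95% CI 1.17–2.83, p = 0.0078) for the Low group — i.e. the planted
excess risk in T-cell-poor samples is recovered from the deconvolved
proportions alone.

The same analyses are scriptable from the shell:

```
mixsurv deconvolve --expr expression.tsv --markers markers.gmt --out props.tsv
mixsurv survival --clinical clinical.tsv --props props.tsv --cell T \
    --screen stage,age_group --out results.json
mixsurv stratify --expr tissue.tsv --panel mhc_genes.txt \
    --clinical clinical.tsv --relapse-col relapse --out out/
mixsurv run --config run.yaml        # end-to-end blood and/or tissue arms
```

All outputs are TSV/JSON with the config hash and seed in a header; a fixed
config and seed reproduce every file byte for byte.

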