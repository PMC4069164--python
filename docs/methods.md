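# Methods

## Deconvolution model

Bulk expression is modelled as a non-negative linear mixture `X ≈ W·H`
(genes × samples ≈ (genes × r)·(r × samples)), fitted by minimising the
generalised Kullback–Leibler divergence with the classic multiplicative
update rules.  Those updates never increase the divergence, and the
per-iteration divergence trace is recorded and checked in the tests.

Semi-supervision is a hard support constraint on `W`: each marker gene may
load only on its own cell type's column; the off-type entries are zeroed at
initialisation and re-zeroed after every basis update (multiplicative
updates preserve zeros, so this costs nothing and guarantees exactness).
Two gene universes are supported: `markers_only` (default) restricts the fit
to the union of matched marker genes, making every basis row single-support
— this is the identifiable, fast setting used throughout; `all_genes` keeps
the remaining genes as unconstrained rows.  Markers claimed by two cell
types are ambiguous and dropped with a warning; a cell type with no matched
markers is an error.

**Scale identifiability.**  With a masked basis the objective is invariant
to scaling `W`'s column *t* by `c` and `H`'s row *t* by `1/c`, so the mixing
rows are determined only up to per-type factors and simple column
normalisation of `H` cannot recover proportions.  The closure assumption —
the modelled types make up 100% of every sample — fixes the scales: we solve
`min_{d ≥ 0} ‖Hᵀd − 1‖₂` (NNLS), multiply `H`'s rows by `d` (compensating in
`W`), and project each column onto the simplex.  On noiseless data of the
generative form this recovers the true proportions exactly, which the tests
assert at MAD < 0.01 with a simplex-constrained least-squares oracle.

Numerical choices: allowed factor entries are floored at 1e-12 against
underflow; convergence is declared when the relative divergence change drops
below `tol` (default 1e-6) or at `max_iter` (default 2000); `n_restarts`
(default 10) seeded initialisations are run and the lowest-divergence run
kept.  Initial factors are uniform(ε, 1), scaled so `mean(W₀H₀) ≈ mean(X)`.
In `markers_only` mode the problem separates into per-type rank-1 KL
factorisations, for which a single multiplicative sweep lands on the
optimum, so fits typically converge in a handful of iterations.  A mixing
row driven to (floored) zero yields a zero proportion with a logged warning.
Negative input intensities (possible after upstream background subtraction)
are floored at 0 before fitting.

Recovery is summarised by the mean absolute difference over all proportion
entries and the Pearson correlation of the flattened matrices — cell-type
identity is pinned by the marker mask, so no column matching is needed.

## Survival statistics

* **Median split**: Low = value < median, High = value ≥ median; the median
  is the standard sample median (mean of the central pair for even n).  When
  every value ties at the median the Low group is empty and a warning is
  logged.
* **Kaplan–Meier**: product-limit estimator, reported at distinct event
  times.
* **Log-rank**: two-group (df = 1) and k-group variants; the two-group
  statistic equals the Cox score test of the group indicator on tie-free
  data, which the tests verify.
* **Cox regression**: partial likelihood with the Efron tie correction,
  Newton–Raphson via lifelines with the convergence tolerance tightened to
  1e-11 so that coefficients agree with direct likelihood maximisation to
  better than 1e-6.  Hazard ratios carry Wald 95% CIs
  (`exp(coef ± 1.96·se)`) and Wald p-values.  Non-convergence (e.g.
  monotone likelihood under complete separation) returns a flagged result
  rather than numbers.
* **Chi-square**: Pearson's statistic without continuity correction,
  df = (rows−1)(cols−1).
* **Univariate screen**: per-factor log-rank at α = 0.05 selects the
  factors entering the multivariate model.  No multiple-testing correction
  is applied across cell types or factors — this mirrors the raw-threshold
  screening design the pipeline emulates and is a deliberate, documented
  caveat, not a recommendation.

Categorical covariates are dummy-coded against an explicit reference level
(configurable; by default the most frequent level).  "Not sure"/"NA"
categories are excluded from a factor's contrast but their samples stay in
the cohort for everything else.

## Stratification

Two-means clustering of samples on the raw panel intensities (no gene
standardisation — the distance is plain Euclidean over the panel genes;
configurable upstream by transforming the input).  Lloyd's algorithm is
implemented directly because the contract requires its internals: a
monotone within-cluster-sum-of-squares trace and a farthest-point reseed
for an emptied cluster.  25 seeded restarts are run and the best objective
kept; the result is cross-checked against scikit-learn's KMeans objective
in the tests.  The cluster with the smaller mean centroid level is labelled
"Low" (antigen-presentation-low); ties break toward the smaller cluster with
a log message.  Samples with unknown relapse status are excluded from the
relapse chi-square only.

## Synthetic data: what it does and does not emulate

The generators define the study conditions for every test:

* **Signatures**: marker intensities lognormal(ln 1000, 0.5), background
  lognormal(ln 100, 0.5) — positive, right-skewed, array-scale values; 20
  markers/type and 100 background genes by default.  Marker exclusivity is
  exact (off-type entries are 0), which is an idealisation of real marker
  panels.
* **Mixtures**: proportions Dirichlet(α) per sample (uniform α = 1 in the
  validation design); additive Gaussian noise, sd 30 (~10% of a typical
  mixed marker intensity), clamped at zero.  Real arrays have
  intensity-dependent, partly multiplicative noise, probe effects and batch
  structure; none of that is simulated, so passing recovery tests bound
  algorithmic error, not biological error.
* **Survival**: exponential event times with hazard
  `0.02·exp(β·flag)` per month (median ~35 months at baseline, a realistic
  resected-NSCLC scale), independent exponential censoring at 0.008/month
  truncated at 120 months.  The default β = log 2.23 matches the effect
  size the pipeline is designed to detect.  Real censoring mechanisms are
  unknown and need not be independent.
* **MHC panel**: 18 genes × 139 samples by default; per-gene baselines
  around 6 (log-intensity scale, sd 0.5) with one cluster shifted by
  `separation` (default 2) plus N(0, 1) noise.  Planted clusters differ
  only in mean level, the feature two-means actually uses.

One integer seed per generator call; sub-streams are spawned
deterministically, so equal seeds give bit-identical data.

## Problem sizes used in the checks

Recovery checks use 24-sample, four-type mixtures averaged over 10
replicates; monotonicity is checked on 100 small random instances; log-rank
calibration uses 1000 null cohorts of 108 patients (the blood-cohort
scale, where the chi-square reference of the log-rank statistic is
accurate; at much smaller cohorts it is mildly anti-conservative); Cox
consistency uses 20 cohorts of 2000.  These sizes give stable Monte-Carlo
estimates while keeping the whole suite around half a minute.

## Known limitations

* Proportions are relative to the modelled cell types only; absolute counts
  and unmodelled cell types are out of scope, and closure renormalisation
  redistributes any unmodelled mass across the modelled types.
* The marker-constrained KL objective assumes markers are strictly
  type-exclusive; leaky markers bias the corresponding proportions.
* Exactly two strata are fitted in the tissue arm; no attempt is made to
  select k.
* Proportional hazards are assumed, untested; no time-dependent covariates,
  stratified baselines or competing risks.
* GEO series ingestion is not part of the tested surface; inputs are plain
  TSV/GMT tables.
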