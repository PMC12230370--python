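# macrosem

Spatial piecewise structural equation modelling of gridded species richness
with phylogenetic tip metrics.

## What this is for

Species richness varies enormously across the range of a clade, and three
non-exclusive mechanisms compete to explain it: regional climate may set
richness **directly** (carrying capacity), or **indirectly** through its
effect on **diversification rates** (regions that speciate faster hold more
species) or on **evolutionary time** (regions occupied longer accumulate
more species).  `macrosem` is a toolkit for confronting these hypotheses
with gridded range and phylogenetic data, for researchers in macroecology
and macroevolution:

- assemble a presence–absence matrix and per-cell richness on an equal-area
  grid (cells below a land-coverage threshold removed);
- compute per-species tip metrics on time-calibrated trees — the **DR**
  speciation-rate statistic (reciprocal of the equal-splits measure
  `ES = Σ_j l_j (1/2)^(j−1)`, which up-weights recent branching) and
  **tip age** (pendant-edge length, a proxy for evolutionary time) —
  averaged over stochastically completed tree replicates, then over the
  species in each cell;
- derive climate-change **velocity** (temporal rate / spatial gradient,
  km/yr) from paleoclimate snapshots;
- screen predictors with **Dutilleul's** spatially corrected correlation
  test (effective sample size from distance-class covariograms) and a
  within-pathway collinearity rule (|r| > 0.8);
- fit candidate causal structures as **piecewise SEMs** in which every
  equation is a **SAR error model** `y = Xβ + u, u = λWu + ε` estimated by
  profile maximum likelihood with an eigenvalue log-Jacobian, ranked by
  summed AICc, with d-separation tests and Fisher's C for non-saturated
  structures and direct/indirect/total standardized path effects.

A first-class synthetic-data module generates birth–death trees,
autocorrelated environmental fields, spreading-dye ranges with Brownian
niche evolution, and cell tables under a known structural model with
SAR-correlated errors — so every estimator above has a parameter-recovery
test against ground truth.

## Worked example

The bundled demo simulates a 20×20-cell study (120 species, 100 imputation
replicates, known generating structure) and runs the full pipeline:

```
macrosem all --config examples/demo.yaml
macrosem report demo_run
```

which prints (abridged):

```
best model: m2  (total AICc 1009.000)
Fisher's C: 0.22668327633936847  df=4  p=0.994042

per-equation R^2 and lambda:
  mean_dr: R^2 = 0.003, lambda = 0.861
  richness_z: R^2 = 0.027, lambda = 0.984

residual Moran's I (raw -> spatially filtered):
  mean_dr: +0.5510 -> +0.0210
  richness_z: +0.9033 -> +0.0070

standardized effects on the response:
  aet: direct +0.6327, indirect +0.0000, total +0.6327
  mean_dr: direct -0.0433, indirect +0.0000, total -0.0433
  temp_seasonality: direct +0.0000, indirect +0.0092, total +0.0092

AICc ladder:
  #1 m2: AICc 1009.000 (delta 0.000, k=9)
  #2 m8: AICc 1011.040 (delta 2.042, k=10)
  ...
```

Reading this: richness in the simulated assemblage is overwhelmingly
explained by the productivity-like layer (`aet`, the layer that seeded
range placement), while the evolutionary path through the speciation-rate
metric contributes almost nothing — the classic signature of a clade whose
richness gradient is climate-driven.  The high λ values say the residuals
are strongly spatially structured, and the Moran's I column shows the SAR
error term doing its job: residual autocorrelation drops from +0.90 to
~0.01 after spatial filtering.  Fisher's C (p = 0.99) finds no missing
paths in the selected structure.  A rerun with the same config and seed is
bit-identical (see `demo_run/manifest.json`).

The library surface mirrors the pipeline: `simulate_bd_tree`,
`simulate_env_field`, `simulate_ranges`, `simulate_structural_cell_table`;
`filter_land_cells`, `build_pam`, `richness`, `climate_velocity`,
`normalize`; `dr_metric`, `tip_ages`, `impute_missing_taxa`,
`species_metrics_over_trees`, `cell_means`; `build_weights`, `morans_i`,
`dutilleul_test`, `collinearity_screen`; `fit_sar_error`, `aicc`,
`nagelkerke_r2`; `PsemSpec`, `enumerate_candidates`, `fit_psem`,
`dsep_tests`, `rank_and_select`, `path_effects`.

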