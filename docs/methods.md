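# Methods

`macrosem` implements a desk-scale pipeline for asking what drives spatial
variation in species richness: does regional climate act on richness
directly, or indirectly through lineage diversification (tip speciation
rates) or through the time regions have had to accumulate species
(evolutionary time)?  The pipeline mirrors the structure of comparative
macroecological studies of gridded richness in species-rich clades: richness
is assembled on an equal-area grid, tip-level phylogenetic metrics are
averaged over stochastically completed time trees and then over the species
in each cell, predictors are screened with spatially corrected correlations,
and candidate causal structures are fitted as piecewise structural equation
models (pSEMs) whose every equation is a simultaneous-autoregressive (SAR)
error regression, ranked by AICc.

## Grid assembly

Cells are squares of side `cell_size` km (default 100), indexed row-major,
with centroids at `((col + 0.5)s, (row + 0.5)s)`; the grid is equal-area by
construction and all distances are planar Euclidean.  Cells with land
fraction below a threshold (default 0.25, boundary kept) are removed before
any other step.  The presence–absence matrix (PAM) is restricted to retained
cells; species left without any retained cell are dropped with a logged
warning, never silently.  Richness is the PAM row sum.

Climate-change velocity is the temporal rate of change divided by the local
spatial gradient.  For each paleo snapshot of age `a` years the temporal
rate is `|current − paleo| / a` (units/yr); the spatial gradient of the
current layer is the magnitude of its central-difference gradient,
`sqrt(gx² + gy²)` in units/km (one-sided differences at grid edges); the
returned layer is the mean of per-snapshot velocities (km/yr).  The gradient
magnitude (rather than, say, an average of the axis gradients) is the
standard terrain-slope definition and is what makes the closed-form check —
a plane of slope 0.01 units/km under a uniform temporal rate of 0.001
units/yr gives exactly 0.1 km/yr — hold in every interior cell.  Flat
terrain would divide by zero, so gradients are floored at a configurable
epsilon (default 1e-6 units/km) and affected cells logged.  When several
climate layers are available, velocity is computed per layer and averaged.

Normalization z-scores every covariate over retained cells using the
*population* standard deviation (divide by n), so test values are exact.
Raw richness is kept alongside a z-scored copy (`richness_z`) used for
modelling; the (mean, sd) pairs are stored so the transform is invertible.

## Tip metrics

The equal-splits measure of a tip is `ES = Σ_j l_j (1/2)^(j−1)` over the
edges from the tip (pendant edge, `j = 1`) to the root; the DR statistic is
its reciprocal (1/Myr), so species from clades that branch frequently and
recently score high.  The halving rule is applied per split regardless of
its degree; input polytomies are accepted (trees completed by imputation are
binary anyway).  Evolutionary time per species is the pendant-edge length —
the time since its most recent splitting event.  A birth–death correction
for unsampled speciation events is a recognized refinement of this
estimator; the uncorrected pendant age is used here, and the correction is
an extension point isolated in `tip_ages`.

Missing species are added by simplified stochastic taxon addition: each
missing species, in sorted order, is grafted into its named clade by drawing
an attachment edge with probability proportional to edge length among the
clade's crown-subtree edges plus its stem, an attachment time uniform along
that edge, and a pendant edge extended to the present.  This keeps the tree
ultrametric by construction (observed relative depth spread < 1e-12 over 100
replicates) and adds exactly one tip per species.  Full birth–death-weighted
attachment (as in dedicated taxon-addition software) is deliberately not
implemented; the length-proportional rule is documented, isolated behind one
operation, and sufficient for generating attachment uncertainty across
replicates.  Metric averaging happens at the species level across the tree
replicates first, then per cell as the unweighted mean over species present;
empty cells get a missing value and are excluded from modelling.

## Spatial statistics

Weight matrices are built from a symmetric neighbour relation (queen or rook
contiguity, a distance band, or symmetrized k-nearest neighbours) and
row-standardized last; isolated cells keep zero rows and are logged.  Queen
contiguity is the default scheme — the neighbour definition is a config knob
recorded in the run metadata, since reasonable analyses differ here.
Moran's I is `(n/S0) · z'Wz / z'z` on centred values.

The modified correlation t-test estimates how much effective information two
autocorrelated fields carry about their correlation.  Pairwise distances are
binned into equal-width classes (Sturges' rule by default); each field's
spatial covariance matrix is filled with its class-wise mean cross-products
(isotropy and second-order stationarity assumed); the effective sample size
is

    M̂ = 1 + tr(BΣ̂x) · tr(BΣ̂y) / tr(BΣ̂x B Σ̂y),   B = I − 11'/n,

and `F = (M̂ − 2) r² / (1 − r²)` is referred to F(1, M̂ − 2), two-sided.
For white-noise fields M̂ ≈ n; under strong autocorrelation M̂ collapses
toward the number of effectively independent patches.  When M̂ ≤ 2
(including occasional negative estimates when the cross-trace is near zero)
the pair carries too little information and p is reported as 1 with a
warning — a conservative choice.  Calibration under the synthetic generator:
empirical type-I error 0.05 on white noise and 0.06–0.08 on strongly
autocorrelated fields where the naive t-test rejects at ~0.76.

The collinearity screen computes all pairwise modified correlations, then
greedily eliminates within each declared pathway group: while any remaining
pair exceeds the threshold (default |r| > 0.8), the member with the larger
mean absolute correlation to the other remaining variables is dropped.  The
tie-break rule is a package choice; all pairwise results are reported so
alternative rules can be audited.

## SAR error model

Each structural equation is `y = Xβ + u`, `u = λWu + ε`, `ε ~ N(0, σ²I)`.
With `A = I − λW`, β and σ² are profiled out analytically and

    ℓ(λ) = −(n/2)(ln 2πσ̂²(λ) + 1) + Σ_i ln|1 − λω_i|

is maximized by bounded Brent search (tolerance 1e-8, no randomness) over
`(1/ω_min + δ, 1/ω_max − δ)`, `δ = 1e-5`, where ω are the eigenvalues of W
(computed once per weights object via the symmetric similarity
`D^{-1/2} A D^{-1/2}` and cached).  An estimate within 1e-6 of the boundary
raises with diagnostics rather than returning a degenerate fit.  With an
empty weight matrix the model reduces exactly to OLS and λ is fixed at 0.

Coefficient standard errors are the conditional asymptotic
`σ̂²(X_f'X_f)^{-1}` at the profile optimum (`X_f = AX`), with two-sided
normal p-values — adequate for the screening-level significance used by
d-separation, and verified by simulation: 95% intervals cover at 0.93–0.97
under the generator.  The parameter count is `k = p + 2` (intercept and
slopes, plus λ and σ²), recorded in the fit so other conventions can be
audited.  `AICc = AIC + 2k(k+1)/(n − k − 1)`; the pseudo-R² is Nagelkerke's
`1 − exp((2/n)(ℓ_null − ℓ_model))` against the intercept-plus-λ null.

## Piecewise SEM

A candidate is a DAG over cell-table variables with richness as sink; each
variable with parents gets a SAR regression on its parents, and the model
score is the summed component AICc.  This likelihood-based score is only
comparable across candidates modelling the same set of responses — dropping
an equation removes its entire likelihood — so the pipeline restricts
ranking to candidates carrying the full endogenous configuration, and
`rank_and_select` warns when handed mixed sets.  Ties go to fewer
parameters, then stable input order, and are flagged.

The d-separation basis set contains one claim per non-adjacent pair,
conditioned on the union of both variables' parents, oriented so the
regression response is the topologically later variable.  Pairs of two
exogenous variables are excluded: their covariance is free in a piecewise
model rather than a causal claim (so a model missing only
exogenous–exogenous edges is saturated), and regressing one raw exogenous
field on another is not a SAR-distributed residual — including such claims
destroys the Fisher's C calibration.  Each claim's p-value is the added
variable's SAR coefficient p-value; `C = −2Σ ln p` with `df = 2k`.
Saturated models return an explicit SATURATED marker — C is undefined for
them and is never reported as zero.  Under the generating model the C
p-values are uniform (KS p ≈ 0.05–0.7 across master seeds, 200 replicates).

Path effects on richness: direct is the coefficient on the edge into
richness (0 if absent); indirect is the sum over all directed paths of the
product of coefficients along the path; total is their sum.  "Significance"
of individual paths for reporting uses the SAR coefficient p-value at
α = 0.05, uncorrected.

## Synthetic generator

The generator provides known ground truth for every stage, emulating the
statistical structure of the real inputs the pipeline expects:

- **Trees**: forward Gillespie birth–death simulation from a stem lineage,
  stopped at a uniform point inside the first interval with exactly n alive
  lineages, extinct lineages pruned (reject-and-retry on full extinction,
  cap 1000).  Defaults 0.5/0.1 events/Myr and ~10²–10³ tips emulate a
  time-calibrated phylogeny of a diverse clade at desk scale.
- **Environmental fields**: Gaussian-kernel smoothing of white noise,
  standardized to mean 0, sd 1; the smoothing scale (default 300 km = 3
  cells) controls the autocorrelation range.  Kernel smoothing was chosen
  over spectral synthesis: fewer moving parts, adequate control.
- **Ranges**: each species' niche optimum evolves on the tree by unit-rate
  Brownian motion (only relative optima matter); ranges grow by spreading
  dye — from the best-matching seed cell, repeatedly accrete the
  rook-adjacent free cell whose environment best matches the optimum —
  until a drawn lognormal size is reached, so ranges are cell-connected and
  environmentally clustered with phylogenetic signal.
- **Structural tables**: exogenous layers are independent fields; each
  endogenous variable and the response add SAR(λ) errors generated as
  `(I − λW)^{-1}ε` by dense solve (grids are capped at desk scale, so dense
  algebra suffices).  The default effect sizes (direct 0.36 and 0.18,
  mediated 0.10 through the endogenous speciation rate, λ = 0.5, noise sd
  0.3) reproduce the magnitude regime reported for richness gradients
  dominated by productivity and seasonality with a weak diversification
  path.

A single master seed spawns fixed per-component substreams (tree, fields,
ranges, errors), so every artifact is a pure function of (config, seed) and
components can be regenerated independently.

What the generator does *not* emulate: realistic paleogeography or coastline
geometry, geographically linked speciation–extinction dynamics, dispersal
barriers, range-size/richness covariance created by sampling artefacts, and
non-stationary or anisotropic environmental covariance.  Passing
parameter-recovery tests therefore shows the estimators are correct under
their own assumptions — not that those assumptions hold for any particular
empirical dataset.

## Problem sizes and numerical choices

Simulation-based checks use 20×20 grids (n = 400) for SAR recovery and
calibration experiments and 30×30 (n = 900) for pSEM recovery, with 100–1000
replicates depending on the experiment; these sizes give stable Monte-Carlo
summaries while keeping any single experiment in the tens of seconds.
Degenerate inputs fail loudly by design: zero-variance variables, empty land
masks, cyclic candidate graphs, inadmissible λ, zero-length tree edges, and
boundary λ estimates all raise rather than return silently wrong numbers.
Floating-point output is written with 6 significant digits; internal
computation is full precision.

## Known limitations

- Imputation uses length-proportional attachment, not a fitted birth–death
  posterior; rate estimates for imputed species are correspondingly
  diffuse.
- Tip ages are uncorrected pendant lengths (see above).
- SAR coefficient uncertainty is conditional on λ̂; for small n the
  intervals can be slightly liberal.
- The candidate enumerator is combinatorial in the number of exogenous
  variables; explicit model lists should be supplied for large variable
  sets.
- Per-equation weight matrices are supported but default to a single shared
  matrix across equations.
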