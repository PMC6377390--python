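# Methods

`gwclhs` implements a hybrid soil-sampling design workflow: a
geographically weighted principal component analysis (GWPCA) condenses a
stack of environmental covariate rasters into locally-adapted score
layers, and a cost-constrained conditioned Latin hypercube sampler (cLHS)
selects `n` sampling cells that represent both the covariate distribution
and the map, while a wetness-derived cost surface steers samples away from
low-relevance terrain (crests and ridges). This note records the models,
the defaults and why, and what the synthetic test beds do and do not show.

## Grid model

Rasters are row-major, north-up grids; row `r`, column `c` has its cell
center at `(x0 + (c+0.5)·s, y0 − (r+0.5)·s)` for cell size `s` and the
top-left corner `(x0, y0)`. All distances are Euclidean between cell
centers in map units. Cell validity is the intersection of per-layer
validity; every analysis operates on the flat table of valid cells.
Only nearest-neighbor coarsening is provided: resampling fidelity is a
preprocessing concern, orthogonal to the sampling-design mathematics.

## Geographically weighted PCA

At cell `i`, observations are weighted by the compactly supported
bi-square kernel

    w_ij = (1 − (d_ij/b)²)²  for d_ij < b,  else 0,

with bandwidth `b` either a fixed distance (default mode; a reported
bandwidth in km implies this reading) or an adaptive neighbor count
converted per location to the distance of its k-th nearest other point.
The local second-moment structure is the weighted covariance about the
weighted mean, `Σ_i = X_cᵀ diag(w/Σw) X_c`.

**Correlation scale.** Covariates in this problem class carry
incommensurate units (meters, percent, dB, mm), so the analysis
standardizes each variable globally (mean 0, sd 1, `n−1` denominator) and
then re-normalizes every local matrix to correlation form. Consequences:
each location's eigenvalues sum to `p` exactly, and the Kaiser retention
rule ("eigenvalue ≥ 1") is meaningful. The Kaiser rule is applied to
location-averaged eigenvalues, since a per-location `k` would give a
ragged score stack; `k ≥ 1` is enforced with a warning.

Eigenvectors are sign-fixed (largest-magnitude element positive, ties to
the lowest index) so loadings are comparable between neighboring cells and
runs are bit-reproducible. Neighborhoods with fewer than `p+1` nonzero
weights are a hard error naming the cell — silent ridge regularization
would hide an undersized bandwidth. A locally dominant variability map
("winning variable": argmax |loading| on the local leading component)
summarizes where each covariate drives the local structure.

Categorical layers are excluded from the PCA by default; a one-hot
expansion is available (`one_hot_categorical=True`) for users who want
class indicators in feature space. PCA of arbitrary integer codes is not
meaningful.

**Bandwidth selection.** Candidate bandwidths are scored by leave-one-out
reconstruction: for each cell `i` of a seeded random subsample, the local
PCA is fitted with `w_ii = 0` and `i`'s standardized covariate vector is
reconstructed from the first `k` components,
`ẑ_i = μ_w + V_k V_kᵀ (z_i − μ_w)`; the score is the summed squared
residual and the minimizing candidate wins (ties to the smallest). The
reconstruction deliberately uses covariance-scale eigenvectors about the
local weighted mean — reconstruction lives on the data scale, whereas the
reported eigenstructure is correlation-scale. Candidates that starve any
neighborhood score `+inf` with a warning rather than crashing the search.
The default subsample fraction is 0.10, a pure compute shortcut that
matters on 10⁵-pixel stacks; on desk-scale grids the full population is
affordable and removes subsampling noise.

Two caveats a user should know. First, with spatially smooth fields the
leave-one-out residual partly measures *local-mean prediction*, which
always favors small bandwidths; the criterion separates spatial regimes
cleanly when the covariance structure, not the mean surface, differs in
space. Second, bandwidths much larger than the domain are near-identical
kernels, so a candidate grid should top out around the domain width —
beyond that the comparison measures ties.

The GW standard deviation `σ_i = [Σ_j (x_j − x̄)² w_ij]^0.5` is provided in
both the raw form (as commonly printed) and a `normalized` form dividing
by `Σw` before the root, which reduces to the population sd under uniform
weights; the raw form's scale depends on the neighborhood size.

## Terrain cost surface

Slope is the central-difference gradient magnitude `tanβ` (one-sided at
borders; exact on planes). Flow routing is single-direction D8: each cell
drains to the 8-neighbor with the steepest distance-weighted drop
(strictly positive; ties resolved in fixed N, NE, E, SE, S, SW, W, NW
order). Pits and flats are flagged, not filled — depression filling is DEM
preprocessing. The wetness index is

    TWI = ln(a / tanβ),  a = (upslope count + 1) · cell_size,

with `tanβ` floored at 1e-4 so flats stay finite. Single-direction routing
was chosen over multiple-flow-direction variants because it is exactly
specifiable and verifiable against a brute-force transitive-closure
oracle; the sampling method only needs *a* wetness index with the right
polarity (low on crests, high in depressions). Numeric values therefore
will not match any particular GIS implementation; the ordering semantics
are what the cost layer uses. The cost surface is the inverted min-max
rescaling `cost = (max TWI − TWI)/(max TWI − min TWI) ∈ [0,1]` — highest
penalty on the driest (crest) cells — and is invariant to affine
transforms of TWI.

## Conditioned Latin hypercube annealing

For a design of `n` cells from `N` valid cells the objective is
`O = w1·O1 + w2·O2 + w3·O3` with

- `O1 = Σ_vars Σ_strata |η − 1|`: occupancy of the `n` equal-probability
  quantile strata per continuous variable (interior edges low-inclusive,
  last stratum top-inclusive);
- `O2 = Σ_vars Σ_classes |η_c/n − κ_c|`: class-share mismatch for
  categorical variables;
- `O3 = Σ_ij |c_ij − ĉ_ij|`: elementwise distance between design and
  population correlation matrices.

Annealing uses a single random swap per iteration (one selected cell for
one unselected cell) and geometric cooling `T_j = T0·f^j`. The move set is
deliberately minimal; worst-stratum-targeted moves are an optimization
that desk-scale problems do not need. The returned design is the best
objective *visited*, so late uphill excursions cannot lose the optimum,
and the best-objective trajectory is non-increasing by construction.

A cost surface enters the acceptance rule multiplicatively:

    P(accept) = exp(−max(ΔO,0)/T) · exp(−λ·max(Δcost,0)/T),

where `Δcost` is the change in the summed per-sample cost and `λ` is
`cost_weight`. The objective itself is untouched — cost shapes which
states are *visited*, giving separate objective and cost traces — and
`λ = 0` reproduces the unconstrained sampler exactly, down to the random
stream. Designs with a constant selected variable get `ĉ = 0` entries with
a warning rather than a crash.

Defaults: `n = 38` (the original access-tube budget; fully user-settable),
`iterations = 5·10⁴` (optimization plateaus by then at raster scale),
`T0 = 1`, `cooling = 0.999`, `weights = (1,1,1)`, `cost_weight = 1`. The
schedule should be matched to the run: over `M` iterations the final
temperature is `T0·f^M`, and on very small enumerable populations
(tens of cells) the landscape is rugged with an isolated optimum, so a
schedule that keeps `T` comparable to the objective spread for most of the
run (e.g. `T0 = 2`, `f = 0.9995` for 2·10³ iterations) stays ergodic and
reliably recovers the exhaustive optimum, whereas aggressive cooling traps
the chain in local minima. At full raster scale the defaults behave like
the usual explore-then-exploit schedule.

## Evaluation

Predicted and confirmed locations are paired by id (the field workflow
confirms each model point; nearest-neighbor matching would hide gross
misses). Positional error is `RMSE = sqrt(mean ||P_i − A_i||²)` in map
units — the squared-difference form over paired coordinates read as
geographic distance, which is what a result in meters implies. The
agreement correlation is the squared Pearson correlation between the
stacked coordinate vectors (x's then y's) of the two point sets; this is
one defensible reading among several, so it is isolated in a single
function that can be swapped. The suitability form scores six binary field
criteria (soil type, geology, landform, access-tube fixability, drainage,
effective depth > 100 cm) per location, averaged and expressed as a
percentage — with six criteria the attainable levels are multiples of
16.67%. `compare_designs` reports mean per-sample cost and mean
nearest-neighbor spacing for two designs on a shared cost grid; inference
is left to the caller.

## Synthetic data: what it emulates, what it does not

- `gaussian_random_field`: stationary fields by white-noise convolution
  with a Gaussian kernel (padded then cropped, so edges are unbiased),
  rescaled to the target sill, plus an optional iid nugget. Adequacy is
  checked by autocorrelation and variance tests, not variogram fits.
- `make_categorical_layer`: quantile thresholds of a smooth field — blocky
  class maps with guaranteed class occupancy.
- `make_dem_plane`: analytic inclined planes, for closed-form terrain
  checks. Note the sign convention: `gy` is the elevation gradient per
  map unit *northward*, so a plane draining south needs `gy > 0`.
- `make_two_regime_stack`: the locality test bed. Each half of the domain
  has a latent factor; a "hub" layer (0 in the west, 1 in the east) is the
  amplified factor itself and two partner layers correlate 0.9 with it.
  On correlation scale the local leading eigenvector is known analytically
  per regime, and the hub carries its largest loading — so local-loading
  recovery and the winning-variable map have exact ground truth, while a
  global PCA mixes the two hubs. The fields are spatially white: local
  correlation estimates then carry maximal effective sample size, which is
  the cleanest setting for testing *covariance* locality. (A pure
  variance-dominance regime contrast would be invisible on correlation
  scale — local renormalization erases amplitude — which is why the truth
  is carried by correlation structure.)

Passing tests on these generators show that the estimators and the
sampler do what their definitions promise under known structure. They do
not show that any particular real covariate stack is well-summarized by
`k` components, that a real bandwidth is transferable, or that TWI is the
right cost criterion outside the hydrological assumptions (rain-fed
moisture, impeding subsurface horizon) that motivated it.

## Numerical choices and degenerate inputs

- Eigendecomposition via symmetric `eigh`; eigenvalues in (−1e-10, 0)
  clamped to zero; asymmetric input (beyond 1e-8) rejected.
- Grid alignment tolerance: 1e-6 of a cell size on origins and cell size.
- Constant covariates are errors at standardization (named); constant TWI
  yields an all-zero cost surface with a warning; a flat DEM flags every
  cell unresolved with zero accumulation.
- Quantile strata use linear-interpolation empirical quantiles; a constant
  variable collapses its strata and is an error naming the variable.
- All stochastic components (field synthesis, subsample draw, annealing)
  take explicit integer seeds; repeated runs are bit-identical.

## Problem sizes used in the test suite

Test and acceptance runs use desk-scale grids — 40×40 cells (p = 4–5) for
the weighted-PCA and bandwidth studies, 24×24 for the cost-suppression
study (30 paired annealing runs of 3·10³ iterations), 16-cell populations
for exhaustive-enumeration checks, and 6×6 DEMs for flow-routing oracles —
sizes at which every claim can be verified against enumeration or a
closed form. The cost-suppression comparison runs its constrained arm at
`cost_weight = 2`, where 30 paired runs give the sign test adequate power;
the effect exists at weight 1 with a smaller margin.
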