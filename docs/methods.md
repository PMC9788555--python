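# Methods

This note documents the models, conventions, and numerical choices the
package implements, in the order the pipeline runs them.

## Grids and geometry

All rasters live on a regular lon/lat grid (WGS84 assumed, no
projections) with cell-center registration and row 0 at the north edge.
Cell membership is half-open — `[west, east)` × `(south, north]` — so a
point on a shared edge belongs deterministically to the cell to its
east or south. A stack of predictors shares one *intersection* nodata
mask: a cell is usable only if every variable has data there, because
the model needs complete feature vectors. Whatever nodata pattern the
input rasters carry is treated as the study-area mask; no cropping
polygon is applied.

GeoTIFF files carry standard georeferencing tags (ModelPixelScale,
ModelTiepoint, GDAL nodata) and store float32; ESRI ASCII grids use the
`ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value` header and six
decimals. Round-trips are bit-exact for GeoTIFF at float32 precision
and good to ~5e-7 for ASCII.

Cell areas use the spherical-rectangle formula
`(R·Δφ)·(R·Δλ·cos φ_center)` with R = 6371.0088 km. An ellipsoidal
refinement would change areas by under 0.3% and was rejected to keep
the oracle hand-checkable; a nominal mode charges a flat 25 km² per
cell for fixtures.

## Occurrence preparation

Thinning keeps the first-encountered record in each valid cell — a
deterministic tie rule, chosen because the upstream tools leave it
undocumented — and drops out-of-grid or nodata records with a logged
count. Thinning is idempotent. Train/test replicates are independent
seeded random subsamples (not cross-validation folds); the test count
is `round-half-up(fraction × n)`, clamped to leave at least one record
on each side.

## Predictor screening

Four bioclimatic layers (Bio8, Bio9, Bio18, Bio19) are excluded up
front for their known spatial artifacts. The Pearson matrix and a PCA
on z-scored columns are computed as an advisory report — which member
of a highly correlated set (|r| ≥ 0.8) is biologically meaningful
cannot be automated — while the reproducible pruning step is stepwise
VIF: drop the largest-VIF variable (`VIF = 1/(1−R²)`, intercept
included; perfect collinearity counts as infinite) until all survivors
are below the threshold (default 10). Ties drop the later variable in
input order. By default the statistics are taken at occurrence
locations; a `mode="background"` flag uses every valid cell instead.
PCA loading signs are fixed so each component's largest-magnitude
loading is positive.

## Maximum-entropy model

Features are built on min-max-scaled predictors (scaling from the
training background, so training features lie in [0, 1]; projection
values may exceed that range before clamping):

* L: `x'`  Q: `x'²`  P: pairwise products
* H: forward `max(0, x'−k)/(1−k)` and reverse `max(0, k−x')/k` hinges,
  knots at 20 evenly spaced background quantiles per variable
* T: step indicators `x' > k`, same knot rule

The fit minimizes the L1-penalized negative log-likelihood (see the
README for the objective). Penalties are
`β_j = rm · β_class(m) · sd_j / √m` where `sd_j` is the feature's
standard deviation over the fitting background and `β_class` is the
published default schedule interpolated by presence count:
linear/quadratic (10, 30, 100) → (1.0, 0.2, 0.05); product
(0, 10, 17, 30, 100) → (2.6, 1.6, 1.1, 0.6, 0.05); threshold
(0, 100) → (2.0, 1.0); hinge constant 0.5. Presence rows are added to
the background for partition-function purposes (the usual convention;
a flag disables it for textbook toy problems). Zero-variance features
are frozen at zero.

**Solver.** A working-set proximal-Newton scheme: each iteration does a
full-gradient screening pass (one matrix-vector product) that evaluates
the exact KKT certificate for every feature, collects the working set
of nonzero-or-violating coordinates, minimizes the L1-penalized local
quadratic model on that set by cyclic coordinate descent with
soft-thresholding, and accepts the step after a halving line search
that keeps the true objective non-increasing. The objective is convex,
so this converges to the optimum; iteration stops when the certificate
violation falls below half the tolerance (default `kkt_tol = 1e-4`),
with a stall guard for numerical plateaus and a hard cap of
`max_iterations` (default 5000). The fit itself is deterministic; the
seed only affects background sampling.

**Outputs.** "raw" is the Gibbs density normalized over the *training*
background; on projection grids it transfers as a density and is not
renormalized. "logistic" is `τ·e^H·raw / (1 + τ·e^H·raw)` with
`τ = 0.5` and `H` the training entropy — the 0–1 display whose null
model prints 1/3 everywhere. A cloglog display
(`1 − exp(−e^H·raw)`) is available but not the default. Clamping clips
each predictor to its training-background range before featurization.

**Interpretation.** Percent contribution credits each accepted solver
update's decrease in penalized NLL to the updated features' parent
variables (product features split evenly; the per-feature share within
a Newton step follows the quadratic-model decrease, scaled to the
realized decrease), floors negatives at zero and normalizes to 100.
Jackknife gains are `NLL(null) − NLL(fitted)` of single-variable and
leave-one-out refits at matched settings. Response curves sweep one
variable over its background range with all others at background
means.

## Tuning and evaluation

AICc ranks candidates over an `rm × feature-class` grid fitted on the
full presence set: raw scores are renormalized over all valid landscape
cells, the log-likelihood is the presence sum of the standardized log
scores, `K` counts nonzero coefficients, and candidates with
`n − K − 1 ≤ 0` are invalid. Ties at the minimum break toward smaller
`K`, then smaller `rm` (parsimony).

Replicate evaluation refits the chosen candidate on each 75/25 split
and reports train/test AUC (rank-based, ties half), their difference,
the omission rate of test presences below the minimum training
prediction, and the continuous Boyce index. The Boyce implementation
slides windows of width range/10 across the background prediction range
at 100 evenly spaced starts, drops windows with zero expected fraction,
and reports the Spearman correlation of predicted-to-expected ratio
against window midpoint; means ± sample SD (n−1) aggregate replicates.
Window defaults are stated here because the upstream description gives
none.

The binarization threshold maximizes training sensitivity plus
specificity over observed prediction values (smallest value among
ties), computed on the full-data best-model fit; the suitable range
`(t, 1]` divides into three equal-width levels (low/moderate/high).
Binarization itself is a strict "greater than".

## Scenario analysis

Member suitability maps are averaged on the displayed (logistic) scale,
with nodata wherever any member is nodata. Change accounting classes
cells as expansion (absent→present), contraction (present→absent),
stable presence, stable absence; percentages are relative to the
*current suitable area*, making net change exactly expansion minus
contraction. (Published tables of this kind sometimes use a larger,
unstated denominator for their "no change" column; this implementation
documents its own definition rather than guessing one, and checks it on
synthetic data only.) The presence-triple map codes each cell by its
(current, mid-century, late-century) binary states; the eight codes
partition the valid area. Range centroids are area-weighted means of
present-cell centers (suitability weighting available via a flag), and
the pipeline accepts any number of GCM members per scenario.

## Synthetic data

The generator emulates the structure the pipeline needs to be testable,
not real-world marginal distributions or units:

* **Surfaces.** Gaussian-filtered white noise fields (length scale 5
  cells by default) plus one deterministic north–south gradient field
  are empirically orthonormalized over valid cells and mixed through
  the Cholesky factor of the requested correlation matrix, so the
  realized cross-correlations match the target essentially exactly and
  every variable inherits a latitudinal trend. A nodata margin
  emulates cropped rasters.
* **Truth.** Suitability is `expit` of a linear + quadratic form in a
  subset of variables — the same family the model's LQ features can
  represent, which is what makes parameter recovery a meaningful test.
* **Presences.** Cells are drawn with probability proportional to
  truth × optional bias surface, with replacement (duplicates give the
  thinning stage work), each point placed uniformly inside its cell.
* **Scenarios.** Members are base + per-variable additive shift +
  smooth zero-mean noise, seeds derived from the scenario seed and
  member index.

What passing tests do **not** show about real data: real bioclimatic
layers have non-Gaussian marginals, anisotropic spatial structure, and
much stronger collinearity; real occurrence data carry roads-and-rivers
sampling bias that the uniform-within-cell model only caricatures; and
real niches are not exactly logistic-quadratic, so the near-perfect
recovery correlations seen on synthetic data are an upper bound, not an
expectation.

## Problem sizes and default conditions

The recovery benchmark uses a 150×150 grid (≈21.3k valid cells), six
predictors with an AR(1)-like correlation (ρ = 0.5 between neighbors),
an LQ niche on two non-adjacent variables, 500 presence draws, a
20,000-cell background cap, and seeds 1–5; the tuning grid is
{L, LQ, LQH} × {0.5, 1, 2}. The scenario demonstration uses a 60×60
grid with a +0.5 SD shift on the driving variable across three
synthetic GCM members (noise SD 0.05). Sizes were chosen as the
smallest landscapes on which the spatial statistics are stable.

## Known limitations

* No categorical features, no fade-by-clamping output, no
  spatial-block cross-validation, no map rendering, no projections.
* Percent contribution is path-dependent (as in the reference
  implementation): it reflects the solver's credit assignment, not a
  variance decomposition.
* The AICc parameter count treats every nonzero coefficient equally;
  heavily regularized hinge models can be under-counted relative to
  their effective flexibility.
* Areas assume a spherical Earth; cells spanning the antimeridian are
  not handled.
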