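# nichecast

Presence-background ecological niche modeling for species whose ranges
shift with climate — built around the kind of question mosquito-vector
surveillance teams ask: *given point occurrence records and gridded
bioclimatic predictors, where is habitat suitable today, and where will
it be suitable under future emission scenarios?*

The package is a complete, reusable pipeline:

1. **Occurrence preparation** — one record per grid cell (the standard
   duplicate-trimming rule against sampling bias), replicated random
   75/25 train/test splits.
2. **Predictor screening** — a-priori exclusion of artifact-prone
   bioclimatic layers (Bio8/9/18/19), Pearson correlation report
   (|r| ≥ 0.8 flags), standardized PCA, and automated stepwise
   variance-inflation-factor pruning (VIF < 10).
3. **Maximum-entropy model** — a from-scratch L1-regularized
   presence-background fit with linear/quadratic/product/hinge/threshold
   features, percent contributions, jackknife gains, response curves,
   and clamped projection.
4. **Tuning and evaluation** — AICc over a regularization-multiplier ×
   feature-class grid, and a four-metric replicate evaluation suite
   (AUC, continuous Boyce index, AUC difference, minimum-training-presence
   omission rate).
5. **Thresholding and scenarios** — maximum training
   sensitivity-plus-specificity (MTSPS) binarization, equal tripartition
   of the suitable range into low/moderate/high levels, GCM averaging,
   expansion/stable/contraction accounting, eight-way presence-triple
   coding across periods, and range-centroid tracking.
6. **Synthetic data** — a generator for correlated, spatially smooth
   predictor surfaces with a known logistic "true niche", biased
   presence sampling, and perturbed future stacks, so the whole
   pipeline is testable without any external download.

## The model

MaxEnt estimates the distribution `q(x) = exp(λ·f(x)) / Z` over
background cells — the maximum-entropy distribution subject to
feature-mean constraints — by minimizing the convex objective

```
NLL(λ) = −mean_presence(λ·f) + log Σ_background exp(λ·f) + Σ_j β_j |λ_j|
```

Per-feature penalties follow the published default schedule
`β_j = rm · β_class(m) · sd_j / √m` (class tables interpolated by
presence count `m`; `rm` is the regularization multiplier). The solver
is a working-set proximal-Newton scheme with soft-thresholding, and
every fit carries a KKT certificate: `|mean_presence(f_j) − E_q[f_j]| ≤
β_j`, with the bound active wherever `λ_j ≠ 0`. The familiar 0–1
suitability display is the logistic output
`τ·e^H·q / (1 + τ·e^H·q)` with `τ = 0.5` and `H` the entropy of the
training distribution; projections onto new climate stacks transfer the
density without renormalizing and clamp predictors to their training
ranges.

Model selection uses AICc with raw scores renormalized over the full
landscape and `K` = number of nonzero coefficients.

## Worked example

```python
import numpy as np
from nichecast import *
from nichecast.maxent_core import predict_values, variable_contributions
from nichecast.varselect import extract_values
from nichecast.tuneval import evaluate_replicates, mtsps_threshold
from nichecast.occprep import SplitSpec
from nichecast.changecast import average_gcms, binarize, centroid, change_map

# a 100x100 synthetic landscape with a known niche on bio01
geom = default_geometry(100, 100)
stack = generate_env_stack(geom, 4, seed=0)
niche = NicheSpec({"bio01": 2.0}, {"bio01": -1.5}, intercept=0.5)
truth = true_suitability(stack, niche)
occ = thin_to_grid(sample_occurrences(truth, 400, seed=1), geom)

pres = extract_values(stack, occ)
bg = stack.values_at(*sample_background(stack, 20000, seed=2))
table = tune(pres, bg, stack, (0.5, 1.0, 2.0), ("L", "LQ", "LQH"))
best = table[table.best].iloc[0]
model = fit_maxent(pres, bg, FitSettings(rm=best.rm), FeatureSpec(best.fc))
```

Continuing through evaluation, thresholding, and a +0.4 warming shift
on the driving variable, the run prints:

```
400 raw records -> 387 after one-per-cell thinning
AICc-best candidate: fc=LQH, rm=2.0 (delta-AICc 0, K=4)
percent contribution: {'bio01': 96.1, 'bio02': 2.1, 'bio03': 1.3, 'bio04': 0.5}
Spearman rho vs true suitability: 0.979
test AUC 0.6913 +/- 0.0167, CBI 0.8703, OR_MTP 0.0041, AUC_diff 0.0035
MTSPS threshold: 0.2779
expansion 22.72%, contraction 17.23%, net 5.49%
centroid (102.041E, 37.295N) -> (101.954E, 37.636N)
```

Reading it: thinning removed 13 duplicate-cell records; AICc picked a
sparse model (4 nonzero coefficients) that concentrates 96% of the
percent contribution on the variable that actually generated the data
and ranks cells almost exactly like the true niche (ρ = 0.979); the low
AUC difference and omission rate say the model is not overfitted, and
the high Boyce index says predicted suitability is well calibrated
against test presences; after the warming shift the suitable range
grows by a net 5.5% of its current area and its centroid moves 0.34°
north, tracking the cells the shift newly qualifies.

The same stages are available as a CLI (`nichecast simulate`, `thin`,
`split`, `select-vars`, `tune`, `fit`, `evaluate`, `project`,
`response-curves`, `change`, `centroid`, `validate-stack`,
`validate-occ`).

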