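# Methods

This note documents the models and numerical choices behind `sdmax`, the
parameters that matter, what the synthetic benchmark does and does not
emulate, and the places where the design was genuinely open.

## Data model and conventions

Rasters are single-band ESRI ASCII grids in geographic WGS84, rows stored
north-to-south. Cells are half-open on their east and north edges, so every
point maps to exactly one cell and a point exactly on the west or south
edge belongs to the cell. The NODATA sentinel defaults to −9999; a stack's
valid mask is the intersection of its layers' masks (a cell is usable only
if every variable is defined there). These conventions are declared, not
inherited from any particular GIS, and the tests pin them down.

## Occurrence preparation

Cleaning is exact-duplicate removal (coordinates compared bitwise — records
differing in the sixth decimal are distinct observations), then *fishnet
thinning* at the environmental resolution: each occupied grid cell
contributes one presence — the single point, or the coordinate centroid of
all points in the cell. The centroid of points inside a convex cell cannot
leave the cell, so thinning is idempotent; a `keep-first` mode is available
for workflows that prefer an observed location over a synthetic centroid.
Thinning leaves at most one presence per modelling cell, which is the
property the model fitting relies on.

## Variable selection

Collinear bioclim variables are pruned with a deterministic greedy pass
over the Pearson matrix: a priority list (default `bio1, bio4, bio13,
bio17` — the ecologically motivated temperature/precipitation anchors) is
processed first, then remaining variables in ascending bio index; each
processed variable is retained and removes every not-yet-processed variable
with |r| ≥ 0.8 against it. The threshold is inclusive and applies to the
absolute value, so r = −0.814 removes. Two priority variables that are
themselves collinear raise an error rather than silently dropping one.

The package ships transcriptions of the two published 19×19 bioclim
correlation matrices (WorldClim 1.4 and 2.1 baselines) as in-package text;
the greedy pass retains the same 11 variables on both, which is the
regression surface for this module. Whether correlations should be taken
at presence locations or over all landscape cells is not standardized in
the field; the default here is the thinned presence sample (common SDM
practice), with a whole-region mode available.

## Maximum-entropy model

The fitting core is written here rather than wrapped: the model *is* the
package's subject. Given scaled features `f ∈ [0,1]` the raw model is the
Gibbs distribution over the background sample, and fitting minimizes

    L(λ) = −(1/m) Σ_presences λ·f + log Σ_background exp(λ·f) + Σⱼ βⱼ|λⱼ|.

Numerical choices:

- **Features.** Auto-selection by presence count (linear always;
  quadratic ≥ 10; hinge, both orientations with 20 evenly spaced background
  quantile knots per variable, ≥ 15; pairwise products ≥ 80). Threshold
  features are omitted — hinge features subsume them. Features constant
  over the background are dropped with a warning. Each feature is min–max
  scaled on the training background and clamped to [0,1] at projection
  time, which caps extrapolation beyond the training range.
- **Regularization.** βⱼ = β_mult · max(sd_j, 0.05)/√m with sd_j the
  presence standard deviation of feature j — default-like shrinkage with a
  class-level floor, one multiplier knob (default 1).
- **Optimizer.** Cyclic coordinate descent; per coordinate a Newton step on
  the smooth part, soft-thresholded by the penalty, then halved until the
  exact objective does not increase. The objective trace is therefore
  monotone non-increasing by construction, and the fit satisfies the L1
  KKT box condition |E_q[fⱼ] − presence mean| ≤ βⱼ at convergence.
  Stopping: objective change < 1e−5 per full cycle (configurable) or 500
  cycles. On ≤3-feature unpenalized instances the solution matches a
  dense-grid brute-force minimizer to 1e−4 (tested).
- **Outputs.** Raw scores are normalized over the training background (they
  sum to 1 there). Logistic output is c·q/(1+c·q) with c = exp(H); H and
  log Z enter through one exponential, `exp(H + λ·f − log Z)`, so the
  uninformative model scores 0.5 to double precision rather than
  accumulating two rounding errors.
- **Gain accounting.** The regularized training gain log N − L is recorded
  per cycle; each accepted coordinate step's gain increase is credited to
  the stepped feature's source variable (products split 50/50), which is
  what percent contribution normalizes. This step-attribution is
  order-dependent in principle; with cyclic sweeps it is deterministic for
  a given seed and feature order.

Replicated runs use seeded subsample splits (default 10 replicates, 75/25)
with a fresh background sample per replicate (default 10,000 cells, capped
at the number of valid cells) and aggregate suitability as the cellwise
mean of the replicate logistic maps.

## Evaluation and importance

Presence-only data has no true absences, so background points serve as
pseudo-absences in both the rank (Mann–Whitney, midrank ties) AUC and the
confusion-matrix metrics. Kappa and TSS require a binarization threshold
that presence-background practice does not fix; the default rule is the
threshold maximizing *training* TSS, with max-Kappa and fixed-value
alternatives. With a large background relative to the test presences,
Kappa is structurally small (it is prevalence-sensitive) while TSS is not —
users comparing to balanced-design studies should expect that asymmetry.

Permutation importance permutes one variable jointly across presences and
background (one seeded permutation by default; n-repeat averaging
optional), re-applies the fixed model, and normalizes the training-AUC
drops (floored at 0) to 100. Jackknife importance refits once per variable
alone and once per leave-one-out set, recording the final regularized
training gain. Response curves are single-variable refits evaluated along
the variable's background range — the "only this variable" construction,
not a marginal/partial-dependence curve.

## Synthetic benchmark

The generator builds Gaussian-smoothed white-noise fields (kernel s.d. 2
cells) rescaled to plausible bioclim ranges; collinear pairs mix a shared
field with independent noise at the analytic weight (ρ, √(1−ρ²)) and
redraw until the realized correlation is within 0.05 of target. The truth
surface is logit-additive: a Gaussian response in the driver (annual-mean-
temperature analog) plus a linear term in the secondary variable (diurnal-
range analog), mapped through the inverse logit. Presences are drawn with
probability proportional to truth suitability and jittered uniformly
inside their cell, so fishnet thinning has real work to do; an optional
smooth bias field emulates uneven sampling effort.

Default truth parameters define a strongly climate-limited virtual
species: optimum 18 °C, thermal breadth 0.8 °C, logit intercept 0,
secondary slope 0.1 per °C, 500 presences on an 80×80 grid. Under these
conditions prevalence is roughly 0.15–0.2 and the Bayes-optimal
presence-vs-background AUC is about 0.93 — an important number to keep in
mind: with presences sampled *proportionally* to a continuous suitability,
no model can reach AUC 1, and the fitted models here track that ceiling to
within ~0.01. The benchmark emulates spatial autocorrelation, collinearity
and sampling bias, but not real geography, non-climatic predictors,
observation error in coordinates, or niche truncation at range edges — so
passing tests demonstrate correct machinery and recoverability under the
stated generative model, not performance on any real landscape.

## Classification and change detection

Suitability classes are left-closed, right-open with the top class closed
at 1 (the interval notation "0–0.1, …, 0.4–1" is ambiguous at boundaries;
one convention is declared so tests are exact). Jenks natural breaks are
computed by exact dynamic programming over the sorted sample (seeded
subsample above 10,000 values) and *reported alongside* the fixed default
thresholds 0.1/0.2/0.4, which remain the classification default — the
fixed scheme is the comparable, publishable surface; Jenks is the
data-driven diagnostic.

Area accounting defaults to unweighted cell counting (the raster-calculator
convention); cos(latitude) weighting is available where geodesic area
matters. The overlay code 10·class₁ + class₂ is losslessly decodable and
its 16 codes map totally onto six change categories; change summaries are
per-category counts and percentages of valid cells.

## Pipeline

Stages (`simulate, thin, extract, select, fit, evaluate, project,
classify, change, report`) each write artifacts plus a manifest (master
seed, configuration hash, package version, outputs). One master seed
derives every stage's randomness by fixed offsets; two runs with the same
configuration are byte-identical in all CSV outputs. Missing prerequisites
raise a dependency error naming the stage to run first. Default problem
sizes (80×80 grid, 500 presences, 10 replicates, 10,000-cell background)
keep a full run around a minute on one core while leaving every statistic
well-resolved; all sizes are configuration fields.

## Known limitations

- The fitting core targets the published default behavior of
  maximum-entropy SDM tools but is not bit-compatible with any particular
  implementation; β schedules and feature bookkeeping differ in
  undocumented ways between versions.
- Percent contribution inherits the path-dependence of step-credited gain;
  it is reproducible but, like its namesake, not a causal decomposition.
- Thinning to one point per cell assumes the environmental grid is the
  right bias-correction scale; no distance-based thinning is provided.
- GeoTIFF and projected coordinate systems are out of scope; the ASCII
  grid dialect is the canonical interchange format.
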