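# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `invasdm`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Presence-background maximum-entropy model

### Model

Presences are modelled as draws from a Gibbs density over environmental
space, `q(x) ∝ exp(λ·f(x))`, normalized over a finite background sample
representing the available environment. The fitted quantity is the weight
vector `λ`; the objective is the penalized gain

    G(λ) = mean_presence[λ·f] − log mean_background[exp(λ·f)] − Σ_j β_j|λ_j|.

`G(0) = 0`, and the unpenalized part is the log-likelihood ratio of the
fitted density to the uniform background density.

### Features

Five feature classes over the raw covariates, all normalized to [0, 1]
using training min/max (training = presences + background):

| class | form | count per variable |
|---|---|---|
| linear | `x'` | 1 |
| quadratic | `x'²` | 1 |
| product | `x'_a · x'_b` | 1 per pair |
| hinge | `max(0, x'−k)/(1−k)` and reversed | 2 per knot |
| threshold | `1[x' > k]` | 1 per knot |

Knots sit at the interior quantiles of the training values (`n_knots = 9`,
i.e. deciles, by default; the per-knot placement of the reference Java
implementation is not documented, so quantile knots are used as the
transparent choice). Constant variables cannot be normalized and are
dropped with a warning. At prediction time covariates are clamped to the
training range before the transform — this bounds projections onto novel
(e.g. future) climates.

### Regularization

`β_j = β_mult · s_j/√m` with `s_j` the feature SD over presences and `m`
the number of presences; a single schedule for all classes rather than
class-specific tables, preserving the multiplier's role while staying
documentable. `β_mult` defaults to 3. `s_j` is floored at 1e−3 so features
constant over presences remain weakly regularized rather than unbounded.

### Optimization

Cyclic coordinate descent. For feature `j`, with `w` the current softmax
weights over the background, the update is a Newton step on the smooth part
(gradient `p̄_j − E_w[f_j]`, curvature `Var_w[f_j]`, floored at 1e−10)
passed through the L1 soft-threshold, with the step clipped to |Δ| ≤ 1 and
halved (≤ 25 times) until the exact penalized gain does not decrease.
Accepted steps update `w` multiplicatively in O(n); weights are recomputed
from scratch every 25 passes to cancel drift. Convergence is declared when
a full pass improves the gain by less than `tol = 1e−6` (max 500 passes; a
non-converged fit warns and returns the partial model). Each accepted
step's gain increment is recorded as a trace entry `(feature, Δgain)`.

### Outputs

* raw: `exp(λ·f(x) − logΣ_background exp(λ·f))` — sums to 1 over the
  training background (asserted to 1e−8 in the tests).
* cloglog: `1 − exp(−e^H · raw)` with `H` the entropy of the fitted
  background distribution. For the constant model this gives
  `1 − e⁻¹ ≈ 0.632` everywhere, the conventional "typical environment"
  value.
* Variable contributions: trace gain increments credited to each feature's
  source variable (product features split evenly); negative variable totals
  floored at 0; normalized to 100. A permutation-importance fallback
  (`permutation_importance`) exists for models loaded without a trace and
  documents itself as such.
* Limiting factor: per cell, the variable whose replacement by its mean
  over presence training points raises the cloglog prediction the most
  (ties → first variable in order).

### Replication scheme

`fit_replicates` implements "five models with five-fold cross-validation"
as `n_reps` seeded repetitions of an `n_folds` partition of presences and
background; reported metrics and projections are means over the fits.

## 2. Data preparation

* **Filtering**: exact coordinate duplicates collapse (smallest id wins, so
  the result is order-independent); records with coordinate precision
  ≥ 0.1° are dropped (county-centroid records are ordinary records whose
  precision is the county's nominal radius; an override flag exempts them);
  geographic outliers are records whose nearest-neighbour distance exceeds
  10× the 99th-percentile nearest-neighbour distance — the rule is
  parameterized and can be disabled, since no standard definition exists.
* **Thinning**: one record per 50-km cell of a Lambert cylindrical
  equal-area grid ("50 km" then means the same area everywhere). The
  retained record is the earliest (ties by id), preserving invasion
  chronology for time slicing. The grid origin is a parameter because the
  thinning is mildly origin-sensitive and no convention is canonical.
* **Background**: candidate cells are non-masked raster cells whose centres
  lie within `buffer_km` (haversine) of any presence — the dissolved buffer
  union. Cells are drawn with probability ∝ cos(latitude) (cell area on a
  geographic grid) and points jittered uniformly within the cell.
* **AOO**: distinct half-open 30-arcsecond cells (anchored at −180, −90)
  containing at least one record.

## 3. Evaluation

AUC is the normalized Mann–Whitney statistic (ties half). TSS is maximized
over a threshold grid of midpoints between consecutive distinct scores
(clipped to [0, 1] on the cloglog scale); the smallest maximizing threshold
is returned, with the full confusion table. Splits are stratified by label
(80/20 by default) and seeded. All reports carry the background prevalence
and the phrase `negative_class: background`, because presence-background
TSS depends on the background-to-presence ratio in the test set.

MESS follows the standard four-branch similarity with *strictly-below*
percentile counting; the cell similarity is the minimum over variables and
the most-dissimilar variable the argmin. "Analogous" is strictly `> 0`.
Forecast evaluation of a historical model keeps only future presences and
background points in analogous cells; if no future presence lands there the
metrics are reported as undefined (an error), never silently zero.

## 4. Niche dynamics (PCA-env)

Axes are the first two principal components of the pooled
(centered, scaled) native + invaded background environments. Occurrence
density `o` and availability `e` are histogram counts on a shared R×R grid
(R = 100) smoothed with a Gaussian kernel; bandwidth per axis follows
Silverman's rule computed on the background scores. Occupancy is
`z = o/e`, rescaled to max 1.

**Stabilization.** `z` is only defined inside the *availability envelope*:
the smallest set of highest-`e` cells holding 99% of the `e` mass. Outside
it both kernels have decayed to numerical dust and `o/e` is a ratio of two
vanishing numbers whose spikes would otherwise dominate the rescaled
occupancy; `z = 0` there. For the expansion/stability/unfilling indices a
second guard treats densities below the 5% quantile of positive `z` as
kernel-tail leakage (parameter `trunc_quantile`, settable to 0).

Overlap is Schoener's `D = 1 − ½Σ|ẑ₁ − ẑ₂|` on mass-normalized grids.
Stability is the share of invaded occupancy mass in environments occupied
by the native niche; expansion is its complement (they sum to 100 exactly);
unfilling is the share of native mass unoccupied by the invaded niche.
Centroid shifts are reported for both the occurrence densities (`o`) and
the availability densities (`e`).

**Similarity test.** One-sided, as the question is posed in the field: *is
the invaded niche more similar to the native niche than expected by
chance?* The null relocates the invaded occupancy grid so that its centre
lands on a cell drawn uniformly from the invaded availability envelope,
truncating at the grid edge and renormalizing; `p = (1 + #{D_sim ≥
D_obs})/(n_perm + 1)` with `n_perm = 999`, so p is a positive multiple of
1/1000. Two behaviours follow from this construction and are verified in
the tests: (a) under the test's *null* — an invaded niche whose position is
genuinely random within its available environment — p is super-uniform
(> 0.05 in ~95% of seeded runs); (b) when invaded occurrences share the
native environmental distribution, the test detects the similarity (small
p): that scenario is the test's alternative, not its null.

## 5. Invasion dynamics

**Growth.** `AOO ~ year` and `log(AOO) ~ year` by least squares;
`AICc = n·log(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with k = 3 (intercept, slope,
variance) for both forms. The lower AICc is "selected", as the comparison
is conventionally made, but the two families' AICc values live on different
response scales; the log fit therefore also reports a Jacobian-corrected
value (`aicc + 2Σlog AOO`) that is strictly comparable to the linear one,
and the pipeline output flags this.

**Neighbour graphs.** Haversine distances; `knn:k` graphs symmetrized by
edge union (k-NN ties resolved deterministically by the search order);
`radius:r` graphs symmetric by construction. The default radius is 50 km;
analyses of this kind are run at several scales and no single radius is
canonical, so it is a parameter, not a resolved constant.

**Join counts.** Binary-weight presence-presence joins on a node set of
grid cells labelled occupied/unoccupied. One-sided pseudo-p for positive
autocorrelation with the `(1 + count)/(1 + n_perm)` convention (p never 0);
an exact-enumeration mode (`join_count_exact_p`) exhausts all label
placements on small graphs. The node set is a genuinely open design choice
(the source analysis does not define its absence class) and is exposed via
`occupancy_labels(stack, occ, buffer_km=...)`:

* *buffer-restricted nodes* (cells within `buffer_km` of a record)
  condition the permutation null on where records broadly are — the right
  reference for fine-scale (1-NN) contagion questions, since a smooth
  suitability gradient can otherwise masquerade as fine-scale clustering;
* *all-cells nodes* keep regional intensity variation in play — the right
  reference for coarse-scale clustering.

**Sequential models.** For each cutoff year: time-slice, rebuild the
background from the sliced presences, fit on an 80% split, evaluate
internally on the withheld 20%, compute MESS from the slice's background
against the full stack, and score the model on records *after* the cutoff
restricted to analogous climate. The proportion of projection cells with
cloglog ≥ 0.5 is reported per cutoff. Cutoffs with fewer than
`min_presences` (default 20) records are skipped with a warning.

## 6. The synthetic-data generator

The generator emulates the *structure* of a continental plant invasion
dataset, not any particular dataset:

* **Climate**: five variables on a 64×64 geographic grid (25–50°N,
  110–80°W by default), each a directional gradient plus Gaussian-smoothed
  white noise (correlation length = kernel SD in cells). Two variables
  (temperature: +0.25/cell northward; precipitation: +0.25/cell eastward;
  both with unit noise) are causal; three (seasonality, radiation,
  moisture) are noise-dominated decoys.
* **Truth**: logistic suitability in temperature and precipitation only,
  centred on the lower-third quantile of the linear predictor so the
  cool/dry south-west corner (where invasions are seeded) is moderately
  suitable while most of the grid is suitable — an invader far from
  equilibrium with a broadly suitable environment.
* **Spread**: yearly colonization from a 3×3 founder block at the most
  suitable cell of the south-west quadrant. Local dispersal is a Gaussian
  kernel truncated radially at 3 SD (default 30 km, 3 attempts per
  colonized cell per year); stratified mode adds jumps at `jump_rate` per
  colonized cell-year with a long Gaussian kernel. Establishment is
  accepted with probability equal to suitability. One record per cell at
  first colonization, mirroring herbarium-style first-detection data. Wave
  and stratified modes share one code path, so `jump_rate → 0` reproduces
  the wave trajectory exactly under the same seed.
* **Dispersal diagnostic** (`make_dispersal_contrast`): paired 18-year
  wave and jump-dominated simulations on a continental-extent 96×96 grid
  (20–60°N, 125–75°W). The jump-dominated regime uses a 5-km local kernel,
  1 attempt/cell/year, jump rate 0.3 and jump SD 800 km, so colonization is
  carried almost entirely by jumps and invaded records are scattered,
  mostly isolated nuclei; the continental extent is needed because on the
  smaller grid most 800-km jumps leave the domain and coarse-scale power
  collapses. Records within 250 km of the founder centre (the shared
  "native" core) are excluded before analysis.
* **Futures**: additive per-variable offsets (default +2 on temperature),
  preserving the mask.

What the generator does **not** emulate: temporal reporting effort trends,
spatial survey bias coupled to roads or settlements (a bias grid is
supported but not coupled to anything), categorical land cover, demography
(seed banks, herbicide-resistance evolution), and real climate covariance
structure. Passing tests therefore demonstrate the *machinery* is correct
and the *diagnostics* behave as designed under known dynamics — not that
any particular real invasion satisfies the models' assumptions.

## 7. Problem sizes and determinism

The bundled study runs on a 64×64 grid with ~2,000–3,500 simulated records,
1,000–2,000 background points, and 999 permutations for the permutation
tests; the replicated fit uses 2×5 folds in the acceptance script and 5×5
by default in the pipeline. These sizes were chosen so a complete study,
including 20-replicate calibration experiments, runs on a single CPU in
minutes while leaving every statistical property measurable. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
the pipeline writes sorted-key JSON and hashes every artifact into its
manifest, and a rerun with identical configuration reproduces the metric
reports byte-for-byte.

## 8. Known limitations

* Agreement with the reference Java Maxent is at the level of behaviour
  (AUC patterns, contribution rankings, regularization path), not
  bit-compatibility; knot placement and the β schedule are documented
  simplifications.
* Presence-background TSS and AUC depend on background prevalence; values
  are comparable within a study, not across background designs.
* The similarity test's translation null inherits the conservatism of the
  standard construction; it has low power against subtle niche shifts.
* The equal-area thinning grid's origin, the join-count node set, and the
  coarse join-count radius are exposed parameters because the field (and
  the source analysis) leave them under-specified; defaults are documented
  above.
* `cloglog ≥ 0.5` as a "suitable" threshold is conventional, and with
  weakly discriminating models large fractions of the map clear it; the
  threshold is a parameter.
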