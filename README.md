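# invasdm

Presence-background species distribution modelling (SDM) and
invasion-dynamics analysis for rapidly expanding species, exercisable end to
end on synthetic landscapes with known ground truth.

The package is aimed at invasion ecologists and SDM methodologists who want
to ask: *given only presence records accumulated during an ongoing invasion,
how well can a climate-suitability model describe — and forecast — the
range expansion?* Because an invader is, by definition, not at equilibrium
with its environment, every stage of that question is subtle: sampling is
biased, the occupied climate envelope shifts through time, and spread may be
driven by rare long-distance jumps rather than climate. `invasdm` implements
the full analysis chain and, crucially, a synthetic-data generator that makes
every stage testable against a known truth.

## What is implemented

* **Synthetic landscapes** (`invasdm.landscape`): multi-variable climate
  rasters (gradient + spatially correlated noise), a known logistic
  suitability surface, biased presence sampling, a yearly invasion simulator
  with wave-like or stratified (local kernel + rare long jumps) dispersal,
  and additive future-climate scenarios.
* **Data preparation** (`invasdm.occurrences`): duplicate/precision/outlier
  filtering, 50-km equal-area spatial thinning, latitude-weighted background
  sampling inside dissolved 100-km presence buffers, area of occupancy (AOO)
  on a 30-arcsecond grid, and time slicing.
* **Maximum-entropy SDM** (`invasdm.maxent`): a from-scratch
  presence-background Maxent with all classic feature classes (linear,
  quadratic, product, hinge, threshold), per-feature L1 regularization with a
  global multiplier (default 3), cloglog output, raster projection with
  clamping, trace-based variable contributions, and limiting-factor maps.
  `MaxentSDM` follows the scikit-learn estimator protocol
  (`fit(X, y)` / `predict` / `get_params`).
* **Evaluation** (`invasdm.evaluation`): rank-based AUC, TSS with threshold
  maximization, multivariate environmental similarity surfaces (MESS), and
  forecast evaluation of historical models restricted to analogous climate.
* **Niche dynamics** (`invasdm.niche`): PCA-env occupancy grids corrected for
  environmental availability, Schoener's *D*, niche
  expansion/stability/unfilling, centroid shifts, and the 999-permutation
  niche-similarity test.
* **Invasion dynamics** (`invasdm.spread`): record accumulation, AOO growth
  with linear vs log-linear AICc selection, sequential historical models with
  MESS-masked forecast scoring, and join-count spatial autocorrelation at
  multiple neighbour scales.
* **Pipeline and CLI** (`invasdm.pipeline`, `invasdm.cli`): a declarative,
  seeded, hash-manifested pipeline (`simulate → prepare → fit → project →
  niche → spread`) with an `invasdm` command-line front end.

## The model

Maxent estimates the distribution of presences over environmental space as
the Gibbs density over a background sample of the available environment,

```
q(x) ∝ exp(λ · f(x)),
```

where `f(x)` are features of the environmental covariates, normalized to
[0, 1]. Fitting maximizes the L1-penalized gain

```
G(λ) = mean_presence[λ·f] − log mean_background[exp(λ·f)] − Σ_j β_j |λ_j|,
β_j = β_mult · s_j / √m,
```

with `s_j` the feature's standard deviation over the `m` presences and
`β_mult` the regularization multiplier (default 3). Optimization is cyclic
coordinate descent (damped Newton step + soft-thresholding per feature),
which also yields the per-feature gain trace used for variable
contributions. Predictions are reported on the complementary log-log scale,
`cloglog = 1 − exp(−e^H · raw)`, with `H` the entropy of the fitted
background distribution.

Model evaluation uses background points as the negative class (AUC is the
probability that a random presence outscores a random *background* point;
TSS = TPR + TNR − 1 at the threshold maximizing the sum), and every report
states this to avoid misreading presence-background metrics as
presence-absence accuracy.

## Worked example

Recovering a known suitability surface from 500 sampled presences on a
synthetic five-variable landscape in which only temperature and
precipitation matter:

```python
import numpy as np
from scipy.stats import spearmanr
import invasdm as iv

stack, true_suit, records, native_range = iv.make_synthetic_study(seed=1)

occ = iv.sample_occurrences(true_suit, stack, n=500, seed=2)
bg = iv.build_background(occ, stack, buffer_km=20_000, n=1500, seed=3)
Xp = stack.extract(occ.lon, occ.lat)
Xb = stack.extract(bg.lon, bg.lat)
Xp_tr, Xb_tr, Xp_te, Xb_te = iv.evaluation.train_test_split_pb(
    Xp, Xb, 0.2, seed=4)

model = iv.MaxentSDM(beta_multiplier=3.0).fit_presence_background(
    Xp_tr, Xb_tr, list(stack.variables))
res = iv.evaluate(model, Xp_tr, Xb_tr, Xp_te, Xb_te)
print(f"AUC train {res.auc_train:.3f} | AUC test {res.auc_test:.3f} | "
      f"TSS {res.tss:.2f} at threshold {res.tss_threshold:.2f}")
for name, pct in iv.variable_contributions(model).items():
    print(f"  {name:<14s} {pct:5.1f} %")
pred = iv.project(model, stack)
ok = ~np.isnan(true_suit)
print(f"Spearman(cloglog, true suitability) = "
      f"{spearmanr(pred.cloglog[ok], true_suit[ok]).statistic:.3f}")
```

prints

```
AUC train 0.670 | AUC test 0.656 | TSS 0.29 at threshold 0.63
  temperature     64.8 %
  precipitation   34.5 %
  seasonality      0.5 %
  radiation        0.0 %
  moisture         0.3 %
Spearman(cloglog, true suitability) = 0.932
```

The model ranks cells almost exactly like the generating suitability
(Spearman 0.93) and credits ~99% of the fitted gain to the two causal
variables, while AUC stays modest — presence-background AUC is bounded well
below 1 when suitable environments are widespread, which is exactly the
situation for a generalist invader. The maximizing TSS threshold (0.63)
sits near the cloglog value of typical environments (1 − e⁻¹ ≈ 0.632).

The full study — invasion simulation, filtering and thinning, replicated
cross-validated fits, current and future projections, niche overlap between
the native and invaded range, AOO growth-curve selection, join-count
autocorrelation, and sequential historical models with MESS-masked forecast
scoring — runs as one pipeline:

```sh
invasdm all --out-dir study_out --seed 1
```

and writes CSV/ASCII-raster/JSON artifacts plus a manifest with content
hashes; a rerun with the same seeds reproduces the metric reports
byte-identically.

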