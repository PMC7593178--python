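# Methods

This note documents the models, algorithms and numerical choices behind
sdmkit, the assumptions they rest on, and what the simulator-based tests
do and do not demonstrate about real data.

## Data model and validation designs

The SWD (samples-with-data) table is the single currency: per record a
species label, X/Y coordinates, a binary label (presence = 1, contrast = 0)
and the covariate vector. The contrast class is either *background*
(random landscape points; presence-only designs) or *absence* (confirmed
non-occurrence). Coordinates are metadata only — no model uses them — but
they are preserved through I/O so externally constructed spatial folds can
be joined back by record order.

Partitioning is always stratified by class and fully determined by
`(table, parameters, seed)`:

* hold-out split: per class, the test size is `round(n * fraction)` with
  ties rounding *down* — documented so expected counts are exact;
* random k folds: per class, a seeded permutation dealt round-robin, so
  within-class fold sizes differ by at most one. Stratification is used
  because unstratified folds can produce single-class folds, which make
  AUC/TSS undefined;
* imported folds (e.g. spatial blocks) are validated against the
  every-fold-has-both-classes invariant and re-labelled 0..k-1.

With k folds, every reported train/validation value is the arithmetic mean
across folds.

## The Maxent-style model

A presence-vs-background binomial likelihood (logistic regression of
presence against background) on the expanded feature set, the standard
GLM-equivalent formulation of maximum-entropy presence-only modelling.

**Feature expansion.** For feature classes `l`, `q`, `p`, `h`: linear
`x_j`, quadratic `x_j^2`, all pairwise products `x_a x_b`, and hinge
features in both directions, `max(0, (x - t)/(max - t))` and
`max(0, (t - x)/(t - min))`. Knots sit at 20 equally spaced empirical
quantiles per variable and direction (configurable); knot quantiles are
computed on the combined presence + contrast training values. All non-hinge
columns are min-max scaled to [0, 1] using training ranges; at prediction
time covariates are clamped to the training range before feature
evaluation, so projections into novel environments saturate instead of
extrapolating.

**Penalty.** Each feature carries an L1 penalty
`lambda_j = reg * max(sd_j(presences), 1e-3) / sqrt(n_presences)` for
l/q/p features; hinge features receive a flat
`lambda = reg * 0.5 / sqrt(n_presences)` per knot. The flat hinge level
(0.5 is the upper bound of the standard deviation of a [0,1] variable) acts
as a shared per-variable budget: per-knot standard deviations would
systematically under-penalise dense knot sets. The penalised objective is
minimised with a single-penalty L1 solver after a reparameterisation that
keeps the problem well conditioned for any multiplier: the mean penalty
level is absorbed into the inverse regularisation constant
(`C = 1/mean(lambda)`) and the O(1) relative weights `lambda_j/mean(lambda)`
into the feature scaling. liblinear (deterministic coordinate descent,
tolerance 1e-4, intercept unpenalised up to a 1/10 scaling factor) is used;
the iteration cap is the model's `maxit` hyperparameter. Hitting the cap
records a non-convergence warning on the model rather than raising, so
tuning loops that deliberately probe low iteration counts never abort.

What this penalty preserves from the reference Maxent implementations is
monotone complexity control: the validation-score spread and the number of
non-zero coefficients decrease as the multiplier grows, and in the
infinite-penalty limit all non-intercept coefficients vanish. The exact
per-feature-class interpolation tables of the Java implementation are
deliberately not reproduced.

**Outputs.** With `eta(x)` the fitted linear predictor, raw output is
`exp(eta)/Z`, `Z` chosen so raw sums to one over the training background
(after the seeded 10,000-point cap, if applied). `H` is the entropy of that
raw distribution; cloglog output is `1 - exp(-exp(H) * raw)` (the default)
and logistic output `exp(H) raw / (1 + exp(H) raw)`. Prediction uses
per-row pairwise-sum reductions rather than BLAS matrix products so that
point and raster predictions are bit-identical regardless of batching. The
JSON model archive (hyperparameters, feature map, training ranges,
coefficients, normaliser, entropy) reproduces predictions bit-for-bit.

## The other families

* **ANN** — a single-hidden-layer network with sigmoid units, implemented
  directly: weights initialised uniformly on (−rang, rang), trained by
  L-BFGS-B on the cross-entropy plus `decay * ||theta||^2`, capped at
  `maxit` iterations. The direct implementation exists because the initial
  weight range is a first-class, tunable hyperparameter here, and because
  it keeps training deterministic under the seed.
* **BRT** — scikit-learn `GradientBoostingClassifier`; interaction depth
  maps to `max_depth`, shrinkage to `learning_rate`, bag fraction to
  `subsample`.
* **RF** — scikit-learn `RandomForestClassifier`; mtry maps to
  `max_features` (default `floor(sqrt(p))`), minimum node size to
  `min_samples_leaf`.

Their default output is the positive-class probability. The Maxent-style
method requires background contrast; the other three accept either design
but are conventionally used with presence/absence.

## Metrics

* **AUC**: rank-based Mann-Whitney estimate (ties count one half) —
  identical to the mean over all presence-contrast pairs. Background
  points are treated as negatives, the standard presence-background
  convention; this caps attainable AUC below 1 since background points
  legitimately fall in suitable habitat.
* **TSS**: `max_t sensitivity(t) + specificity(t) - 1` with `score >= t`
  predicting presence, `t` ranging over the distinct observed scores
  (exact maximisation, not a grid). Ties break toward higher sensitivity,
  then the lower threshold. The `>=` convention is a documented choice.
* **AICc**: Maxent only; `k` counts non-zero fitted coefficients,
  `lnL = sum over presences of ln(raw)` with raw renormalised over the
  evaluation extent — the full prediction raster when one is supplied,
  otherwise the table's background (a documented desk-scale deviation
  knob). Undefined (NaN, flagged not raised) when `n - k - 1 <= 0`. AICc
  uses all observations; requesting it with a fold design is an error.

Threshold rules for binary maps: maximum TSS, equal sensitivity and
specificity (observed score minimising the gap, smallest on ties), and
minimum training presence.

## Variable importance and selection

**Permutation importance**: per variable, the mean drop in the training
metric over `n_permutations` (default 10) joint shuffles of that column,
clamped at zero and normalised to sum to 100. If no shuffle changes the
metric (a null model) importance is uniform. **Jackknife**: retrain with
one candidate variable removed (same hyperparameters and seed) and report
the metric on the training data or under the validation design.

**var_sel** (collinearity removal) loops: rank variables by permutation
importance; take the most important one with `|rho| >= threshold`
(Spearman by default, Pearson by flag; computed on contrast records,
subsampled to 30,000 by default) against any other; jackknife the
correlated group on the *training* metric; remove the member whose absence
costs least, retrain, repeat until all pairwise correlations fall below
the threshold. The focal variable is itself a removal candidate by default
(`protect_focal=True` exposes the alternative reading). Ties break toward
the lower permutation importance, then name order. Postcondition, asserted
in tests: the retained set's maximum off-diagonal |rho| is below the
threshold.

**reduce_var** (parsimony) removes, one at a time, variables whose
importance falls below a percentage threshold. In stepwise mode the
lowest-importance sub-threshold variable goes each round. In jackknife
mode (the default) a sub-threshold variable is removed only if the
retrained model's *validation* metric does not fall below the current
model's; variables that fail the check are marked necessary and the scan
continues until no sub-threshold candidate remains. Postcondition: the
final validation metric is never below the initial one.

The training/validation asymmetry between the two functions is deliberate:
collinearity removal should preserve the information captured from the
data (over/underfitting is handled later by hyperparameter tuning), while
parsimony pruning explicitly guards generalisation. Both remove exactly
one variable per step because each removal changes the remaining
importances and ranks, and both keep at least one variable.

## Hyperparameter tuning

A `HyperGrid` maps hyperparameter names to candidate-value lists; the
total is the Cartesian product. All tuners share the fitness rule: rank by
validation metric descending, but flag any combination whose validation
score exceeds its training score as underfitting and rank it last; ties
break by training score, then insertion order. For AICc, ranking is simply
ascending with no underfit rule (no validation partition exists).

* `grid_search` evaluates every combination once.
* `random_search` evaluates a uniform without-replacement sample of
  `population_size` (default 20) distinct combinations.
* `optimize_model` is the genetic algorithm: initialise with
  `random_search`; each generation retain `round(size * keep_best)` elites
  plus `round(size * keep_random)` drawn uniformly without replacement
  from the remainder, then breed children by crossover — two distinct
  parents drawn uniformly, each hyperparameter inherited uniformly from
  one of them, then with probability `mutation_chance` one hyperparameter
  resampled uniformly from its domain *excluding both parents' values*
  (skipped when no third value exists) — until the population is back to
  size. Defaults: population 20, 5 generations, keep-best 0.4, keep-random
  0.2, mutation 0.4. `round` is half-to-even, documented so retention
  counts are reproducible. With zero generations the algorithm *is* the
  random search.

Training effort follows the closed form
`size + generations * (size - round(size*keep_best) - round(size*keep_random))`
— 60 with the defaults — counting training *requests*: a child duplicating
an already-evaluated combination is served from a combo-keyed cache and
logged as a cache hit, never retrained. Elitism guarantees the best
non-underfit fitness is non-decreasing across generations. Per-generation
best/mean fitness is logged (structured log lines replace interactive
charts throughout the package).

## Virtual-species simulator

Environmental layers are smooth Gaussian random fields: white noise
convolved with an isotropic Gaussian kernel of width `smoothness` cells
(wrap-around boundaries), standardised to mean 0, sd 1. Optional duplicate
layers are a source layer plus Gaussian noise, re-standardised — the
collinear pairs the selection tests rely on. True suitability is logistic:
`s = 1/(1 + exp(-(b0 + sum_j coef_j z_j)))`. Presences are drawn without
replacement with probability proportional to `s` (exponential-key weighted
sampling, so requested counts are exact), absences proportional to
`1 - s`, background uniformly without replacement; both presence/background
and presence/absence tables are returned.

Default study conditions (60x60 grid, 4 layers, coefficients +3/−2,
smoothness 5, 400 presences, 1000 background) represent a
moderately strong, spatially structured species. Two measured properties
of these conditions matter for interpreting results: (i) the
presence-background design has an intrinsic AUC ceiling (~0.71-0.80
depending on prevalence) because background points fall in suitable
habitat — scores near that ceiling indicate a model at the information
limit, not a weak model; (ii) on small, smooth grids a nominally
uninformative layer can genuinely correlate with the truth by chance, so
the parsimony test bed uses a larger grid (80x80), shorter correlation
length (3 cells) and eight candidate layers, making a 2 % importance share
a meaningful pruning threshold (mirroring real screening settings with
dozens of candidate predictors).

What the simulator does *not* emulate: sampling bias, spatially clustered
observation effort, covariate measurement error, non-additive or
non-monotone response shapes, and range-edge truncation. Passing tests
therefore demonstrate algorithmic correctness and recoverability under
idealised sampling, not field performance.

## Rasters, outputs, CLI

Rasters are single-band ESRI ASCII grids (plain text, unit-cell
geotransform; cell centre of (row, col) at `x = col + 0.5`,
`y = nrows - row - 0.5`), a deliberate format choice: human-readable,
diffable, dependency-free. Raster prediction equals point prediction on
every finite cell bit-for-bit; cells missing any covariate propagate as
missing; raw output over a full extent is renormalised to sum to one (the
AICc convention). Binary maps use `cell >= threshold`. Response curves
vary one covariate over its training range with the others fixed at their
training means. `model_report` writes a markdown report with a minimal
standalone HTML rendering plus machine-readable sidecars (metrics,
importance, thresholds, selection trace, tuning log as CSV/JSON) and
static ROC/response figures; sidecars are byte-stable under fixed inputs
and seed.

The `sdm` CLI is a thin layer over these functions, one verb per workflow
step, exit code 0 on success; all randomness flows from `--seed`.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline at desk
scale, chosen as the smallest sizes at which every claim is
distinguishable from noise: 50x50-80x80 grids, 150-500 presences per
species, feature classes up to `lqp` for tuned models, grids of 12-1,200
hyperparameter combinations, hold-out or 2-4-fold validation, and 10
seeds for every stochastic claim. The genetic-algorithm and random-search
budget counts (60 and 20) are scale-free invariants and hold at any size.

## Known limitations

* The Maxent-style penalty is a principled simplification, not a
  re-implementation of the Java/maxnet per-class penalty tables; absolute
  coefficient values differ from those implementations even where rankings
  agree.
* AICc counts non-zero coefficients as `k`, which under L1 regularisation
  is an approximation to effective degrees of freedom.
* liblinear's intercept is penalised at 1/10 weight rather than left
  fully free; at the fitted scales the effect is below the solver
  tolerance.
* `equal_sens_spec` and TSS thresholds are restricted to observed scores;
  with tiny samples the reported threshold can sit at a gap edge.
* The GA's `keep_random` fraction is taken of the population size and
  sampled without replacement from the non-elite remainder; other readings
  of "randomly retain a portion of the less performing models" exist.
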