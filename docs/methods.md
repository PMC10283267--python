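# Methods

This note documents the models, procedures, defaults and deliberate
design choices behind `clinselect`, and what the package's tests do and
do not establish.

## Data model and preprocessing

Every column is typed by the metadata schema; six kinds are supported.
Tooth-lists are sets of two-digit FDI / ISO 3950 codes; exactly 52
codes are admissible (quadrants 1–4 × positions 1–8 permanent,
quadrants 5–8 × positions 1–5 deciduous). "Area of the oral cavity"
codes such as sextants are *not* admitted: the value domain is the 52
tooth codes only. An empty tooth-list cell means "no teeth" (the empty
set); only the missing sentinel (default `NA`) means missing — the
clinical distinction between *no treated teeth* and *not recorded* is
real and is preserved. The metadata syntax itself (a CSV with header
`name,type,min,max,legend`, legend pairs `code=label` joined by `;`) is
this package's own definition: flat, diff-able and hand-editable.

Transform plans are fitted on training rows only and replayed
elsewhere, so no statistic of held-out or future data can leak into the
encoded features:

* **Continuous** variables are min-max rescaled to [0, 1] using the
  training minimum/maximum. Constant columns map to 0 (guarded
  denominator). Values outside the training range map outside [0, 1]
  and are *not* clipped — the transform stays monotone and affine.
* **Tooth-lists** are one-hot encoded into a fixed 52-column layout.
* **Categorical** variables with more than two declared levels are
  one-hot encoded by default (switchable); binary variables pass
  through as 0/1. A code outside the declared range at apply time
  yields an all-zero indicator block plus a warning rather than an
  error, because small clinical validation sets routinely miss levels.
* **Integer** kinds pass through unscaled; a user who wants them
  rescaled can declare them continuous.

Imputation admissibility: `mean` requires a continuous variable,
`most_frequent` a discrete scalar kind; `drop_rows` and `constant` are
universal. Target imputation is explicit in the task config; predictor
gaps default to the kind's natural fill (mean for continuous, most
frequent for discrete, empty set for tooth-lists), with fill values
fitted on training rows and stored in the plan.

## Classifier evaluation

One stratified 80/20 split (|validation| = round(0.2 · n); 230 records
give 184/46), then 3 stratified CV folds on the training part for a
fixed 13-member roster. Stratification is essential at the target
scale of n ≈ 230 with ~24% prevalence. The selection score of a
classifier is the fold-mean of the chosen metric — f1, precision or
recall on the class of interest for binary targets, macro-averaged for
multiclass — and ties break toward the earlier roster position. Roster
order follows the single-instance families first, with the decision
tree placed before the ensembles. Hyperparameters are frozen package
defaults (versioned as `ROSTER_VERSION`); hyperparameter optimization
is a deliberate non-feature. Two naive-Bayes variants (Gaussian and
Bernoulli) are included; the stacking ensemble stacks random forest,
Gaussian-process and logistic-regression bases under a logistic
meta-learner — "Gaussian" base read as Gaussian process rather than
Gaussian naive Bayes.

The winner is refitted on the full training set. Models whose raw
scores are not probabilities (the SVMs and the hinge-loss SGD linear
model) are wrapped in cross-validated sigmoid (Platt) calibration
fitted on training data; probabilistic models pass through. ROC AUC
uses the class-of-interest probability (binary) or one-vs-rest macro
averaging (multiclass), and is reported absent when the validation set
lacks a class. All remaining metrics derive from the confusion matrix;
balanced accuracy is the mean of per-class recalls and macro-f1 the
unweighted mean of per-class f1, both re-derivable from the reported
matrix.

Model bundles (zip of JSON metadata + serialized fitted model +
encoded training rows for explanation backgrounds, capped at 1000)
round-trip exactly: a loaded bundle reproduces the saved model's
probabilities bit-for-bit on conforming inputs.

## Feature selection

Exhaustive search runs for N ≤ 13 candidates (c = 2^N − N − 1 subsets
of size ≥ 2, enumerated full set first, sizes non-increasing); the
threshold is a config constant. Above it, the sequential-backward
variant starts from the full set 𝕋 (evaluated once), evaluates all
size-(T−k) subsets of 𝕋 per iteration, replaces 𝕋 by the iteration's
best subset, and halts when T − k < 2 (subsets of size 1 are never
evaluated). Default k = 2. The budget is fully determined by (N, k):
1 + Σ C(T, k) over the trajectory T = N, N−k, …, e.g. 715 for (20, 2)
and 2360 for (30, 2); the search's empirical call count equals this by
construction and by property test. The current 𝕋 itself is re-evaluated
only at initialization, and the global best is taken over the whole
trace, so the result always dominates the full-feature-set score.

Every subset is scored against the *same* stratified split and fold
assignment (both functions of the target labels and the seed only), so
subset scores differ only through the features, not through split
noise. The design matrix is built once over all candidate features and
column-sliced per subset; because every transform is per-variable,
this is provably identical to refitting the plan per subset, and the
package asserts equivalence against an independent brute-force loop
that calls the full evaluation workflow per subset. A subset's score
is its best classifier's cross-validated fold-mean; the held-out
validation is run once at the end, for the winning subset, to avoid
both double fitting and selection on the validation set. Subset-score
ties prefer the smaller subset (parsimony), then the earlier-enumerated
one. Long searches checkpoint the trace to disk after every iteration
and report progress against the deterministic budget.

## Shapley explanations

Both explainer paths compute **interventional** Shapley values of the
winning model's class-of-interest probability: the payoff of coalition
S for sample x is the model output averaged over background rows with
features in S from x and the rest from the background. Probability
space was chosen (over log-odds) because the reports speak to clinical
users in terms of predicted probabilities; tree outputs are normalized
leaf class fractions.

* `exact_enumeration` evaluates all 2^m coalitions of the m encoded
  columns; it refuses more than 16 columns with an explicit error —
  never a silent approximation.
* `tree_exact` decomposes a fitted decision tree into per-leaf games.
  For a sample/background pair, a leaf is reached under coalition S iff
  S ⊇ A (path features satisfied only by the sample) and S ∩ B = ∅
  (satisfied only by the background); a path feature satisfied by
  neither kills the leaf. The Shapley value of this
  unanimity-with-veto indicator game is (|A|−1)!|B|!/(|A|+|B|)! for
  members of A and −|A|!(|B|−1)!/(|A|+|B|)! for members of B; features
  off the path are dummies. Summing over leaves, weighting by leaf
  probability, and averaging over the background gives exact values at
  polynomial cost; forests average per-tree values (their probability
  is the per-tree mean, so linearity applies). Boosted models are not
  probability-additive over trees and therefore take the enumeration
  path.

Both paths share one value function and are verified against a third,
independent brute-force permutation-formula oracle to 1e-6 (in
practice machine precision). Additivity — base value + Σ contributions
= model probability per sample — holds exactly by construction.
Backgrounds are training rows stored in the model bundle, capped at
1000.

One-hot child columns are summed into their parent variable for all
global displays (exact, by additivity); the raw per-column values
remain in the bundle. Global importance ranks parents by mean
|contribution|, optionally split by a binary grouping variable (which
need not be a model predictor). The automatically proposed dependence
partner of a feature is chosen by a binned, size-weighted squared
correlation between candidate-partner values and the feature's
contributions within bins of the feature's own value — one
deterministic, model-agnostic rule used for all model families (exact
pairwise Shapley interaction indices were considered for tree models
and rejected as a second closed-form derivation with little payoff;
the heuristic recovers planted multiplicative interactions in the
package's simulation tests). Relevance clustering is average-linkage
hierarchical clustering of per-sample parent-contribution vectors
under Euclidean distance — both choices made here, as the common
defaults for explanation-space clustering. Decision-tree export emits
DOT text with encoded-column labels (parent name + code), so split
rules read clinically.

## Synthetic cohorts

The generator emulates the *marginal* structure of a paediatric
deep-sedation cohort: n = 230 records by default, a binary outcome at
24% prevalence, a `Healthy` subgroup at a 47.4/52.6 split, and a menu
of binary, ternary categorical (0–2), count (0–8), continuous and
tooth-list predictors. Tooth codes enter each list independently with
per-quadrant probabilities (deciduous quadrants 0.15, permanent 0.04 —
a paediatric mix). The outcome follows a logistic model over
standardized planted features (tooth-lists contribute through their
cardinality) plus optional products of standardized features as
interactions; the intercept is bisection-calibrated so the expected
prevalence matches the request, and an unreachable prevalence is an
explicit error. The "strong signal" benchmark plants three effects of
2.5 log-odds per SD among 20 candidates — near-deterministic signal,
which is what a recovery benchmark should plant.

What the fixtures do **not** emulate: correlated predictors, informative
missingness, measurement error, or any real cohort's joint
distribution. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure, not clinical
performance on real data.

## Numerical and scale choices

* All randomness flows from a single integer seed per task; identical
  seeds give byte-identical JSON reports. Timestamps live in a
  separate run log.
* Most-frequent imputation breaks ties toward the smallest code;
  subset-score ties toward smaller, earlier subsets — all
  deterministic.
* The planted-recovery benchmark and the acceptance script use the
  reduced two-member roster (logistic regression + decision tree) so a
  715-evaluation backward search over 10 seeds completes in minutes on
  one CPU; the full 13-member roster is exercised on single
  evaluations. Problem sizes in the test suite (subsets of 20–25
  samples for oracle comparisons, backgrounds of 30–80 rows) keep the
  brute-force Shapley oracles tractable while remaining exact.

## Known limitations

* Exact enumeration is infeasible beyond 16 encoded columns, so
  non-tree models over tooth-list predictors (52 indicator columns)
  cannot currently be explained; the CLI reports this and still writes
  the evaluation and model bundle.
* The backward search returns a local optimum above 13 features, by
  design; no forward/genetic/annealing strategies are provided.
* Calibration uses sigmoid scaling only; no isotonic option.
* Multiple imputation and model-based imputation are out of scope.
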