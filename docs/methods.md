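# Methods

## The optimization model

The optimizer is a generational genetic algorithm over candidate solutions
that couple a hyperparameter assignment with a feature-subset index list.
Fitness is the Bayesian Information Criterion computed from out-of-fold
predictions, BIC = p·ln(n) − 2·loglik, with p the number of *selected
features*, n the number of scored samples, and loglik the summed validation
log-likelihood in nats (class probabilities floored at 1e-12 so the
log-likelihood stays finite). Using the selected-feature count as the
complexity term is a deliberate choice: boosted trees and neural networks
have no natural parameter count on the same scale as a logistic model, while
p penalizes exactly the quantity the search varies and makes fitness
comparable across families.

Cross-validation adapts to model size: k is the smallest integer strictly
above n/p (integer ratios round up by one), stratified by label, optionally
capped (default cap 10 — an uncapped rule would demand hundreds of folds for
2-feature models, which the desk-scale configuration cannot afford and which
adds nothing statistically). If k exceeds the minority class count it falls
back to that count with a warning. Fold assignment and estimator seeds derive
from a single evaluation seed fixed per run, so a candidate's fitness is a
pure function of its (hyperparameters, subset) pair; identical candidates are
cached rather than refit, which also makes search-versus-enumeration
comparisons exact.

### Generation schedule

The full schedule is 100 models per generation: rank ascending by BIC, best
80 split into 40 recombination parents, 20 mutated, 20 discarded; 60 fresh
random models complete the next generation. Pairing for recombination is
ranked-adjacent (1–2, 3–4, …); the crossover copies genes before the midpoint
pivot from the first parent and averages genes from the pivot onward
(categoricals: seeded parent choice). The 20 mutated models are ranks 41–60;
ranks 61–80 are discarded; recombination parents do not survive into the next
generation (the arithmetic 20 + 20 + 60 = 100 forces this). Mutation shifts
one seeded hyperparameter by its declared step — default 10% of the bound
width, log-space where the parameter is log-scaled — reflecting at the
bounds. Feature subsets never recombine: the subsets of the top-60 records
are reallocated rank-order to the 40 bred children, so subset search is
driven by survival of good subsets plus fresh random injection.

### Plateau, elbow and warm restart

Evolution stops when the best-so-far BIC improves by less than 0.1%
(relative) over a 10-generation window — both values are configuration, not
data-derived. At the plateau, per-feature importances (|coefficient| for
logistic, gain for trees, permutation importance for the network, averaged
over folds and zero off-subset) are aggregated by mean over the best 60
records across all generations. The elbow of the best-BIC-per-feature-count
curve is the point of maximum perpendicular distance to the chord after
normalizing both axes; a linear curve or fewer than three distinct counts is
flagged degenerate and falls back to the maximum count. The warm restart
restricts the pool to features whose aggregated importance reaches the
importance of the feature ranked at the elbow count, then escalates the
cutoff to mean + m·SD for m = 2..10, each phase a fresh mini-run with the
reduced 50/20/10 schedule. Escalation stops at the first pool smaller than
the minimum subset size and skips duplicate consecutive pools, so with a few
dominant features only one or two phases actually run.

The importance-aggregation window (60 records) stays fixed even when the
population is scaled down: aggregating over too few records makes the
restricted pool miss features that appeared only in mid-ranked models, which
is the main failure mode of desk-scale runs.

### Classifier families

* **logistic_elasticnet** — scikit-learn `LogisticRegression` (saga solver),
  mixing parameter l1_mix ∈ [0, 1], regularization strength ∈ [1e-3, 1e3]
  (log scale; C = 1/strength).
* **boosted_trees** — XGBoost with the gbtree booster; eta [0.01, 0.5],
  max_depth [2, 10], n_estimators [50, 500], subsample and colsample
  [0.5, 1], lambda [0, 10], gamma [0, 5].
* **neural_net** — scikit-learn `MLPClassifier`: 3 hidden layers × 300 ReLU
  units, Adam, early stopping with patience 3 on validation loss (validation
  split 10% of each training fold, seeded); learning rate [1e-5, 1e-1] (log),
  batch size [16, 256], epochs [10, 200]. For binary outcomes the logistic
  output is equivalent to a 2-unit softmax.

These search ranges are the package's defaults, chosen to be generous for
broad exploration; they are *not* canonical values from any external source.
Tree and logistic runs reproduce exactly under a fixed master seed; network
runs reproduce within solver tolerance.

## Preparation chain

Order: sparsity filter → outlier trim → masked-NNMF imputation → instrument
agglomeration → min-max scaling → normalizing-transform selection. Every
fitted parameter (drop list, NNMF feature factors, scaler bounds, transform
choices) comes from the training partition alone and is applied unchanged to
test data; the outlier trim is the one stateless exception — it clips into
mean ± 3 sample SD computed on the observed entries of the partition being
transformed, by contract. A poisoning test asserts that perturbing the test
partition leaves every fitted parameter and every training artifact
bit-identical.

* **Sparsity filter**: features with missing fraction strictly above 0.40
  are discarded (a feature at exactly 40% is kept).
* **Masked NNMF**: values are shifted non-negative (offset recorded and
  undone), and W, H ≥ 0 minimize the squared error over *observed* cells
  only via mask-weighted multiplicative updates (rank 10 by default,
  tolerance 1e-5 relative, max 500 iterations; the masked objective is
  non-increasing by construction and the best iterate is returned on
  non-convergence). Only unobserved cells are replaced — observed entries are
  bit-identical. On new data the feature factor H is held fixed and only the
  per-subject weights are re-estimated.
* **Agglomeration**: Ward-linkage hierarchical merging of item columns on
  Euclidean distance, pooled to the root with the size-weighted mean, so the
  summary equals the mean of the leaf columns; deterministic.
* **Transform selection**: a feature consistent with normality by the
  Anderson–Darling test at the 5% level (statistic ≤ 0.787 on standardized
  values) is left untransformed; otherwise the minimum-statistic candidate
  among {untransformed, Yeo–Johnson power, rank-based quantile-to-normal}
  wins, ties preferring none > power > quantile. The AD statistic was chosen
  for tail sensitivity and sample-size stability.
* **Targets**: symptom items are agglomerated to one score; label 0 iff the
  score is exactly zero. Targets are built only from complete item sets.
* **SMOTEENN**: SMOTE with k = 5 minority neighbours synthesizes convex
  combinations until classes balance, then edited-nearest-neighbour cleaning
  (k = 3, unanimity rule) removes points of either class whose neighbours
  disagree — which can flip the majority, as heavy boundary cleaning removes
  many original majority points. Applied to the training partition only;
  synthetic provenance (parent pair and interpolation weight) is retained for
  auditing.
* **Univariate odds ratios**: per-unit ORs from single-predictor logistic
  fits with Wald 95% intervals; perfect separation is flagged, not silently
  reported.

## Connectivity metrics

Static connectivity is the Fisher z-transform of the Pearson correlation for
every unordered component pair of a subject's timecourses (upper triangle,
row-major). Correlations at |r| = 1 are capped at atanh(0.999999) with a
warning; constant components are an error. The published static measure
correlates spatial maps; this module correlates timecourses, the desk-scale
stand-in, and documents the difference here. Dynamic states use a
rectangular sliding window (default 45 s equivalent, inside the robust
40–60 s range; step 1 timepoint), k-means over upper-triangle-vectorized
window correlations pooled across subjects (10 seeded restarts; k by inertia
elbow over 2–8 when not fixed), and four per-subject fluidity metrics:
states traversed, switch count, total L1 distance summed over switches, and
maximal L1 span — interpreted as the largest pairwise L1 distance among
*visited* centroids, reading "span" as the extent of the visited set rather
than a consecutive-step quantity. State labels are 0-based. Nuisance
covariates are removed by OLS residualization with an intercept; residuals
are orthogonal to the covariates and rank-deficient designs fail loudly.

## The synthetic cohort generator

The generator emulates the statistical shape of a community-ascertained,
behaviourally enriched youth cohort: ~1120 subjects × 160 mixed-domain
predictors, non-normal marginals, low-rank correlation, binary condition
targets with case rates from ~12% to ~75%, and up to 40–60% missingness.
Predictors come from a Gaussian copula (low-rank-plus-noise correlated
normals, rank 5 by default) pushed through per-feature marginal transforms
(normal, lognormal with SD 0.4–1.0, or a skewed mixture). Labels follow a
logistic model on planted effects — linear (standardized), threshold
(indicator above the 70th percentile), and pairwise interaction with the
adjacent feature — with the intercept calibrated by root-finding so the
expected case rate matches the request; `noise_scale=0` switches to a
deterministic threshold rule for separability tests. MCAR missingness is
uniform; MAR missingness is logistic in one fully observed anchor feature
per domain block, intercept-calibrated to the target rate. All randomness
derives from one master seed through named substreams.

The ground truth records the generating scores, the Bayes-optimal class
probabilities and the planted indices, so downstream tests can compare any
trained model against the Bayes ceiling. Timecourses with planted
connectivity states sample each window from a zero-mean Gaussian with the
state's correlation matrix (windows are non-overlapping by construction), so
windowed sample correlations cluster around their generating centroids.

What the generator does *not* emulate: real instrument covariance or scoring
rules, site/batch structure, longitudinal drift, or realistic fMRI
autocorrelation within windows. Passing tests therefore demonstrate that the
machinery recovers structure it is designed to model — not that any clinical
result on real cohort data is reproduced.

## Problem sizes and study conditions

The parameter-recovery condition plants four linear effects of size 1.3
standardized units in a 40-feature pool at a 30% case rate, which puts the
empirical Bayes AUC at ≈ 0.90; training uses 400 subjects with a large
generated test partition, a 20-model population for at most 15 generations,
and subset sizes 2–8. The search-optimality check uses an 8-feature pool,
subsets fixed at size two and one 3-choice hyperparameter (84 configurations)
so exhaustive enumeration is exact and cheap. Imputation checks use rank-2
200×30 matrices at 20% missingness. These sizes are the package's chosen
desk-scale study conditions; the full-scale schedule (100-model generations,
~40k fits) is available through the default `EvolutionConfig`.

## Known limitations

* Feature subsets evolve only by whole-subset inheritance and fresh
  sampling; without the warm restart, recovery of multi-feature signals at
  small population sizes is unreliable. This mirrors the published design and
  is why the warm restart is on by default.
* BIC with the selected-feature complexity term is a search fitness, not a
  calibrated model-selection criterion across families.
* The network family's permutation-importance fallback is computed on a
  single validation fold for speed; importances for that family are noisier
  than for the other two.
* Post-resampling class proportions depend strongly on the ENN unanimity
  rule and data geometry; no attempt is made to reproduce any particular
  published post-resampling count.
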