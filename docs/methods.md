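# Methods

This note records the statistical model behind sigwrap, the defaults and
why they are what they are, the numerical conventions, and the design
choices made where the procedure was genuinely open.  The README gives
the algorithm outline; here we document the details a maintainer or
reviewer needs.

## Selection model and its assumptions

The method asks, for a ranked tail subset S_f of features, whether the
classifier's out-of-bag predictions get worse when the class association
of those features is destroyed.  Permutation happens only in the
out-of-bag (test) rows of each bootstrap; train matrices are never
touched and no model is refitted during a round, which is what makes the
procedure cheap (one model per bootstrap per round).

Assumptions worth stating:

* **Binary response, complete data.**  Exactly two classes with at least
  two samples each; missing or non-finite intensities are rejected at
  validation, since imputation is an upstream preprocessing concern.
* **Exchangeability under the null.**  Permuting a feature's test-set
  values within the out-of-bag rows is the null model of "this feature
  carries no class information the classifier uses".  Each feature of a
  candidate subset is permuted independently (see Design choices).
* **Monotone significance along the ranking.**  The half-interval search
  assumes that if the tail at rank r is significant, larger tails are
  too.  This holds when the aggregated ranking is roughly faithful to
  importance; a grossly wrong ranking degrades the search to a heuristic
  (as it does for any wrapper).

The reported accuracy of the final models is a mean out-of-bag balanced
accuracy over fresh bootstraps.  Because the samples used for selection
are reused for this estimate, it is mildly optimistic; external
validation is required for an unbiased figure.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `boot` | 50 | bootstraps per round; stability of selections plateaus well below this in sensitivity analyses of the protocol |
| `alpha` | 0.05 | max proportion of bootstraps where permuted accuracy reaches the original; the comparison is `accuracy_perm >= accuracy`, non-significance requires the proportion to be strictly `> alpha` |
| `methods` | plsda, rf, svm | the three wrapped classifiers; each runs independently with its own seed stream |
| `max_rounds` | 50 | safety net only; convergence normally happens within ~log2(p) + a few rounds |
| `permutations_q2y` | 1000 | response permutations in the Q2Y model-significance test |
| `n_trees` | 500 | Random Forest size; `mtry = floor(sqrt(p))`, minimum 1 |
| `svm_cost` | 1.0 | linear C-SVM cost |
| VIP filter thresholds | 1 and 1.5 | the two documented presets |
| RFE drop rule | `max(1, floor(0.2 p))` | worst-ranked 20% per iteration, at least one feature |

PLS-DA component admission: a component h is added while R2Yₕ ≥ 0.01 and
Q2Yₕ = 1 − PRESSₕ/RSSₕ₋₁ ≥ 0 (≥ 0.05 when n < 100), with PRESS from
stratified 7-fold cross-validation on the globally scaled matrix and
RSS₀ = (n−1)·var(y).  Components are capped at min(10, n−1, p); the
admission rule stops far earlier in practice.

## Classifier implementations

* **PLS-DA** is a bespoke PLS1 NIPALS engine: y is coded ±0.5 and
  centered, features are mean-centered and unit-variance scaled (sd from
  the training set, ddof 1; zero-variance features use divisor 1 and are
  flagged).  With a univariate response the NIPALS weight is the exact
  normalized covariance direction w = X′y/‖X′y‖, deflation of X and y
  per component.  VIP follows the standard explained-sum-of-squares
  weighted form, so Σⱼ VIPⱼ² = p identically.  When no component passes
  the admission rule the model is flagged non-informative: one component
  is still extracted so VIP ranking stays defined, predictions fall back
  to the training majority class (ties favour the positive level), and
  the reported Q2Y is the (typically negative) Q2Y₁ of the forced
  component — this keeps every bootstrap usable without biasing accuracy
  upward, and gives the permutation test a value for every permuted fit.
* **Random Forest** is an in-package numba-compiled CART forest matching
  the classical defaults: 500 trees on bootstrap resamples of the
  training rows, Gini splitting over mtry features drawn without
  replacement per node, grown to purity, majority vote (exact tie →
  positive level).  Importance is the raw out-of-bag permutation
  importance (mean decrease in OOB accuracy); features a tree never uses
  contribute exactly zero for that tree and are skipped, which is an
  exact shortcut, not an approximation.  The engine is written for the
  many-small-fits workload of this algorithm — thousands of forest fits
  per analysis — where per-tree overhead, not arithmetic, dominates
  general-purpose implementations.  Its behaviour is cross-checked
  against scikit-learn's forest in the test suite.
* **Linear SVM** delegates to libsvm (scikit-learn's `SVC`,
  kernel="linear", C=1) on the scaled features; the ranking metric is
  the squared primal weights recovered from the dual solution.  No class
  weighting is applied.

Features are scaled for PLS-DA and SVM only; the forest sees raw
intensities (trees are invariant to monotone transforms).

## Numerical conventions and degenerate inputs

* Ranks are dense, 1 = most important, ties broken by ascending feature
  index; every rank vector is a permutation of 1..p.  Median-aggregated
  ranks break ties by mean rank, then index.
* Half-interval midpoints round half away from zero and are clamped to
  the open interval (h, l) between the last significant and last
  non-significant candidate; the first candidate is always rank 1
  (permute everything).
* A PLS decision value of exactly 0 maps to the negative level; a forest
  vote tie maps to the positive level.  Both are documented tie-breaks,
  not accidents.
* Bootstraps are stratified within class (train size n, class
  proportions preserved) and redrawn — up to 100 times — until the
  out-of-bag set contains both classes, since balanced accuracy is
  undefined otherwise.
* Halving with odd p keeps ⌈p/2⌉ features, so the top-ranked feature is
  never dropped by a tie between halves.  When the one remaining feature
  tests non-significant the run terminates with an empty signature
  (halving a single feature cannot shrink the set further).
* Tier letters beyond E are lumped into E.
* Constant features are retained with a warning; classifiers tolerate
  them through the guarded scaling divisor.

## Randomness and reproducibility

A single `seed` drives everything.  Each classifier gets an independent
`SeedSequence([seed, method_index])` stream; bootstrap draws, forest
fits, CV fold stratification and permutations all consume integers from
that stream.  The forest kernels seed numba's own RNG explicitly at
every entry point, so results are independent of numpy's global state.
A fixed config therefore yields byte-identical `tiers.tsv` and
`accuracies.tsv` across reruns.  PLS fold stratification keys on the
lexicographic level order, so Q2Y (and its permutation p-value) does not
depend on which class is declared positive.

## What the synthetic generators emulate — and what they do not

`generate_planted` draws i.i.d. Gaussian features (optionally an
equicorrelated block through a shared latent factor) with a mean shift
of d·sd in the positive class for the informative features.  This
emulates the scale and class structure of a log-transformed peak table,
but **not** the heavy correlation, heteroscedasticity, missingness or
intensity-dependent noise of real LC-MS or microarray data.  Passing the
planted-recovery and null-control tests therefore demonstrates that the
engine controls false selections and finds genuine marginal signal at
realistic n/p ratios; it does not certify performance on strongly
correlated real data.

`spike_semisynthetic` reproduces the spiking protocol: purge every
feature significant by two-sided Wilcoxon rank-sum at BH-FDR ≤ 0.05,
then bisect the largest factor (≤ 10) that multiplies one surviving
feature's intensities in one class while keeping its BH-adjusted p-value
above the FDR level.  The multiplication acts on the stored values as-is
(on a log-scale table that is a power transform), and the base table
must be positive-valued for the factor to act monotonically.  Note that
on an *uncorrelated* synthetic scaffold the resulting target is capped
just below univariate detectability and carries little multivariate
advantage, so selectors miss it often; the construction is most
informative on scaffolds with real correlation structure, where
multivariate models can recover sub-univariate targets.

Scoring of repeated runs (`sensitivity_specificity`) defines sensitivity
per run as "every truth feature is in the union of the classifiers' S
signatures" and specificity as one minus the mean fraction of non-truth
features entering that union — per-run union-based definitions, chosen
as the decision of record.

## Design choices where the procedure was open

* **Per-feature independent permutation** of a candidate subset (not a
  joint row shuffle of the subset block): destroys each feature's class
  association individually.  A joint shuffle would preserve the
  within-subset correlation structure; either reading is defensible, the
  independent one is implemented and documented here.
* **Fresh permutations per candidate evaluation**, no caching across
  candidates of the search.
* **Stability protocol**: the ten 90% subsets are the complements of a
  seeded stratified 10-fold partition — deterministic, class-balanced,
  and every sample is left out exactly once.
* **RFE bootstraps are redrawn at each iteration**, so no model ever
  scores an out-of-bag set it saw while features being dropped were
  still present.
* **Accuracy estimator for full/S/S+A models**: mean out-of-bag balanced
  accuracy over `boot` fresh bootstraps.  This is an internal,
  resampling-based estimate; it is not comparable to accuracies computed
  by other estimators (cross-validation, external test sets).

## Problem sizes used by the shipped studies

The end-to-end studies run at desk scale, chosen as the smallest sizes
at which the statistical claims are meaningful: null control over 20
datasets (n = 40 balanced, p = 100, d = 0) and planted recovery over 10
datasets (n = 40, p = 200, one feature at d = 3) in the test suite;
`scripts/acceptance.py` uses 6 datasets per study at p = 100 plus
single-dataset stability, Q2Y-permutation and comparator analyses.

## Known limitations

* Binary responses only; no multi-class or regression extension.
* Hyperparameters are fixed by design (no tuning loops); the method's
  claims are about selection, not about squeezing classifier accuracy.
* The significance assessment is conditional on the ranking; features
  that are informative only jointly with features ranked far below them
  can be eliminated early (backward-selection limitation).
* Reported accuracies reuse the selection samples and are mildly
  optimistic; validate externally.
* Bootstraps are processed sequentially; they are independent by
  construction, so concurrent execution with per-bootstrap sub-seeds is
  possible but not implemented.
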