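# Methods

## The model

`explspace` studies one question: if a population contains hidden subtypes
within an observable binary condition, is the *explanation space* of a
diagnostic classifier a better place to look for them than the raw feature
space? The protocol:

1. **Superset split.** Multi-class labels `y ∈ {0..C−1}` are collapsed to a
   binary task: instances whose subclass belongs to a chosen superset A map
   to 1, the rest to 0. The binary label plays the role of an observable
   diagnosis; the subclasses play the role of hidden subtypes the classifier
   never sees.
2. **Diagnostic classifier.** A random forest of probability-averaging CART
   trees is trained on the binary task. Trees are grown on bootstrap
   resamples by maximising the Gini impurity decrease over `mtry` candidate
   features per node. Every node stores its training cover (the weight of
   training instances reaching it) and the positive-class weight fraction.
3. **Explanation space.** Every instance is mapped to its Shapley
   attribution vector `φ(x) ∈ R^p` of the forest's predicted probability,
   under path-dependent (cover-weighted) conditional expectations. The
   embedding preserves dimensionality and satisfies local accuracy
   exactly: `base_value + Σ_j φ_j(x) = P̂(y=1|x)`.
4. **Evaluation.** The superset-A instances are embedded by each of
   {none, PCA, Isomap, t-SNE} in both spaces, Ward-clustered at
   `k = |superset A|`, and scored: Davies–Bouldin, Calinski–Harabasz and
   Silhouette measure how well the representation separates the
   *ground-truth* subclasses; Adjusted Mutual Information measures how well
   the unsupervised Ward partition recovers them.

## Shapley attribution

Two independent routes are implemented. `brute_force_shap` evaluates the
defining sum over all feature coalitions, with `v(S)` computed by recursive
cover-weighted tree traversal; it is exponential in `p` and guarded at
`p ≤ 12`. `tree_shap` is the polynomial-time path algorithm: it pushes a
summary of all subset sizes down each root-to-leaf path, extending it at
every split and unwinding duplicate features, so that each leaf contributes
its value to every feature on its path with the correct permutation weight.
The two agree to better than 1e-8 on randomized forests (in practice to
machine precision); the test suite and the acceptance script both re-verify
this.

Choices worth making explicit:

* **Conditional expectations are path-dependent** (cover-weighted branch
  averaging), not interventional against a background dataset. This is the
  classical tree formulation; it needs no reference sample and keeps the
  attribution a function of the model and the instance alone.
* **The probability output is explained**, not log-odds: forest leaves hold
  positive-class fractions, so local accuracy is exact and the base value is
  the cover-weighted mean prediction.
* **The forest is trained on all instances and all are explained.** This is
  a deliberately optimistic protocol (explanations of training points); a
  `holdout` option trains on a subsample while still explaining everything.

## The synthetic benchmark

`SyntheticSpec` defaults: 1600 samples, 16 classes, 50 features of which 4
are informative, 4 redundant (fixed random linear combinations of the
informative ones) and 42 pure standard-Gaussian noise. Each class is one
isotropic Gaussian cluster centred on a distinct vertex of the 4-D hypercube
`{−class_sep, +class_sep}^4`, with `class_sep = 0.3` and
`within_cluster_sd = 0.1`; class-to-vertex assignment, column order and all
noise derive from a single seed, and identical specs are bit-identical.

The two geometry defaults encode the regime the method is designed for, and
they pull in opposite directions:

* the class signal must be buried: per-coordinate between-class variance
  (`class_sep² ≈ 0.09`) is an order of magnitude below the unit variance of
  each of the 42 noise features, so Euclidean distances, PCA directions and
  Ward merges in raw feature space are noise-dominated and subclass recovery
  there hovers near chance;
* the diagnostic task must still be learnable: the within-cluster spread is
  a third of the hypercube half-edge (vertex gap = `2·class_sep` = 6 sd), so
  axis-aligned splits isolate the class regions and the forest reaches
  ~0.95–1.0 holdout accuracy.

Increasing `within_cluster_sd` toward the half-edge makes the binary task
Bayes-error-limited and degrades the explanations into noise; decreasing
`class_sep` further eventually starves the forest. Both dials are exposed.

What the generator does *not* emulate: per-class covariance structure
(clusters are isotropic), label noise, unequal class sizes, heavy-tailed or
discrete features, and feature correlations beyond the redundant block. A
pass on this benchmark therefore shows that the pipeline recovers subtypes
*when the diagnostic signal is real but geometrically hidden*; it does not
certify performance on real cohorts, where the diagnostic signal itself may
be weak — in that regime the explanations inherit the classifier's noise.

## Forest defaults

`n_trees = 100`, `mtry = ⌈√p⌉`, `min_leaf = 1`, unlimited depth — the
conventional defaults of this classifier family. Thresholds are midpoints of
consecutive distinct sorted values; routing is left iff `x ≤ threshold`.
Splits with equal scores resolve to the lowest feature index, then the
lowest threshold, making training bit-deterministic under a seed (per-tree
streams are spawned from the master seed). Balancing, when requested, enters
as per-instance weights in the impurity and covers — equivalent in
expectation to inverse-frequency resampling, but deterministic.

## Evaluation statistics

All four statistics are implemented from first principles (scikit-learn
serves only as a cross-check oracle in the tests):

* `DB = (1/k) Σ_i max_{j≠i} (s_i+s_j)/d(μ_i,μ_j)`, `s_i` the mean distance
  to the cluster centroid. Identical centroids with nonzero dispersion raise
  an explicit division-by-zero error.
* `CH = [B/(k−1)]/[W/(n−k)]`; `W = 0` returns `+inf`.
* Silhouette: `(b−a)/max(a,b)` per sample, singleton clusters scoring 0.
* AMI: `[MI − E(MI)] / [mean(H_a,H_b) − E(MI)]` with the exact
  hypergeometric expectation (full summation over admissible cell counts,
  log-gamma arithmetic). The arithmetic-mean normaliser is the default; the
  `max` convention is a flag. Natural logarithms throughout (AMI is
  base-invariant). Two conventions are hard-coded: identical trivial
  partitions score 1.0, and a denominator of exactly 0 resolves by MI
  comparison.

Indices are computed against ground-truth subclass labels (they measure the
representation), AMI against the Ward partition (it measures unsupervised
recovery); `indices_against="clustering"` switches the former.

## Embedding and clustering

PCA is computed directly (centred SVD; each component's sign fixed so its
largest-magnitude loading is positive, making output deterministic). Isomap
and t-SNE delegate to scikit-learn with pinned settings — neighbourhood size
5, perplexity 30 (clipped below `(n−1)/3` for small inputs), learning rate
200, PCA initialisation — so results do not drift as library defaults
change. Ward linkage is scipy's; the test suite checks the resulting
partitions are *identical* to a from-scratch O(n³) implementation of the
Ward objective, and cluster labels are renamed in order of first appearance.

## Benchmark sizes and runtime

The default protocol (1600 × 50, 100 trees, full-dataset attribution, 8 grid
cells, 3 seeds) runs in roughly 40 s on one CPU: the attribution kernel is
compiled with numba and costs O(trees × leaves × depth²) per instance, which
is also why very deep forests on much larger samples get expensive — cap
`max_depth` or raise `min_leaf` when scaling up. The oracle sweeps in the
tests use forests of ≤ 8 features, depth ≤ 4 and ≤ 10 trees, where the
exponential enumeration is exact and fast.

## Known limitations

* Per-tree attribution assumes binary splits and axis-aligned thresholds;
  no categorical features or missing-value routing.
* The path-dependent expectation conditions on the tree's own training
  distribution; attributions of correlated features split credit in a
  model-dependent way (the redundant features in the benchmark absorb a
  share of the informative signal).
* Ward tie-breaks at exactly equal merge costs follow scipy's ordering,
  which the naive-oracle comparison avoids by using continuous random data;
  exact ties are measure-zero for such inputs.
* `k` must be supplied (default: the number of ground-truth subclasses in
  the evaluated superset); the package makes no attempt to select it.
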