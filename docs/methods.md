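# Methods

## Setting

An expression-to-expression model predicts a target gene's expression
*E<sub>cg</sub>* in condition *c* from the TF-expression vector
***E***<sub>c</sub> of that condition. Cross-validation of such models is only
meaningful relative to how *distinct* the test conditions are from the
training conditions: if replicates or same-context samples straddle the
split, held-out accuracy measures interpolation, not the generalizable
TF–gene relationships the model exists to capture. This package quantifies
that distinctness, constructs partitions that control it, and measures how
estimated accuracy depends on it.

## The distinctness score

For test condition *i* and training set *R*:

    eta(E_i, R) = |R| / sum_{j in R} 1 / D(E_i, E_j)

with D the min-max normalized Euclidean distance between TF-expression
vectors. Design points:

* **Global normalization.** D<sub>min</sub>/D<sub>max</sub> are the extremes
  over all off-diagonal pairs of the full condition set, computed once before
  any split and reused for every partition. Per-partition renormalization
  would make scores incomparable across partitions. Self-distances are
  excluded; including them would force D<sub>min</sub> = 0 for every dataset.
* **Harmonic mean.** Dominated by the closest training samples: one
  near-duplicate in training collapses the score, which is exactly the
  replicate-leakage phenomenon the score exists to flag.
* **Zero distances.** The globally closest pair normalizes to exactly 0; if it
  spans test/train, 1/D is undefined and we return the mathematical limit
  eta = 0 rather than injecting an epsilon: a test sample indistinguishable
  from a training sample has zero distinctness.
* **Collection score.** For an exhaustive K-fold collection, the mean of eta
  over all |C| conditions, each scored once against its fold's training set.
  The |C| denominator presumes exhaustive folds, so the collection score is
  refused for annealing-generated (non-exhaustive) collections; those are
  summarized per partition by the mean/median of their test samples' scores.
* **Raw vs z-scored features.** Distances are computed on the matrix as given;
  z-scoring features first is an explicit caller choice
  (`zscore_features=True` / `--zscore`), since reasonable pipelines differ
  here. The default is raw.

A degenerate geometry in which every pair of conditions is equidistant leaves
min-max normalization undefined and is rejected with an explicit error.

## Partition generators

* **RCV** — uniformly random, mutually exclusive, exhaustive folds, sizes
  differing by at most one.
* **CCV** — k-means (++-style initialization, one run per collection, up to
  300 iterations, relative tolerance 1e-4, seed-controlled) on the condition
  vectors; each cluster becomes one test fold. Fold sizes may be unequal.
  Empty-cluster runs (possible with fewer distinct points than k) are retried
  with fresh initializations up to 10 times, then error.
* **SACV** — simulated annealing over test sets of fixed size m. The objective
  is the partition's **mean** per-test-sample distinctness (the collection
  score's |C| denominator does not apply to a single non-exhaustive
  partition). Moves swap one uniformly chosen test condition with one
  uniformly chosen training condition; acceptance is the Metropolis rule
  (accept improvements always, worsenings with probability exp(Δη/T)). Every
  accepted state is recorded once; after discarding the first `burn_in`
  accepted states, `n_select` states are sampled uniformly without replacement
  and returned ordered by acceptance step, so distinctness trends upward
  across the selection. The swap objective is maintained incrementally in
  O(n) per proposal with periodic exact refreshes to cancel float drift.

### Annealing schedules

The default schedule (T₀ = 1, 500 iterations per level, cooling ×0.98 down to
1e-14, burn-in 50000, 30 selected partitions) is sized for compendium-scale
data: hundreds of conditions and test sets of hundreds of samples. Two
properties of the landscape matter when scaling the problem down:

1. The *critical temperature* is the scale of a single-swap change in mean
   distinctness, roughly (max η − min η)/m; far above it the chain is a
   neutral random walk over near-random partitions, far below it only
   improving moves are accepted.
2. When the test size equals the size of one condition cluster, the optimum
   (one full cluster as the test set) is reached through a sharp condensation:
   near the optimum every swap is a large worsening, so accepted states near
   the top are intrinsically scarce.

The demonstration schedule used by the tests and the acceptance script for
the 180-condition study data is therefore a *two-rung quench*: a long neutral
rung at T₀ = 1 (1040 iterations) that the burn-in discards, followed by a
quench (cooling factor 7e-5) to T ≈ 7e-5, where the test set condenses
quasi-greedily. This yields a selection that starts at the random-partition
level and climbs near-monotonically to the condensed optimum. Even so, the
low end of the selection consists of equilibrium random states, and the sign
of successive differences between such states is a coin flip — a small number
of local decreases among the first selected partitions is expected behavior,
not a defect.

For the distinctness-accuracy analyses the test size is set to twice the
cluster size (60 of 180), so that highly distinct test sets span more than
one unseen context; with single-cluster test sets, each gene's
accuracy-vs-distinctness relationship is dominated by its idiosyncratic
coefficient draw for that one cluster, and the population-level
anticorrelation weakens. At compendium scale the same holds naturally, since
test sets are larger there than a typical context cluster.

## Regression harness

* **Methods.** LARS (active-set size tuned over {1, 2, 5, 10, 20, 50} by inner
  5-fold CV, ties to the sparser model), Elastic Net (penalty over 20
  log-spaced values from 1e-8 to 1e2 × mixing {0.1, 0.5, 0.9}, inner 5-fold
  CV, exact ties to the stronger penalty), and RBF-kernel SVR with fixed
  conventional defaults (C = 1, kernel width 1/n_features, tube 0.1).
* **Normalization.** Features and target are z-scored with *training-fold*
  statistics only; test features are transformed with those statistics and
  predictions are inverse-transformed to the original target scale. This is
  the only leakage-free default; a deliberately leaky global-z-scoring variant
  (`global_zscore=True`) exists for replication studies. Zero-variance
  features on a fold are dropped with a warning; a zero-variance target is an
  error (its z-scoring is undefined); a fold with no informative features
  predicts the training mean.
* **Metrics.** Per gene: pooled out-of-fold Pearson correlation over all
  conditions (exhaustive collections only), per-partition test-set PCC and
  RMSD on the original scale, and the Spearman rank correlation (average
  ranks for ties) between partition distinctness and per-partition accuracy.
  Undefined correlations — constant vectors, test sets smaller than 3 — are
  reported as missing with a warning, never silently zero, and excluded from
  summaries.
* **Method comparison.** Per partition, the per-gene vector of RMSD
  differences (A − B) with quartile summaries, defined only for results
  computed on identical partitions and genes.
* Genes are independent tasks; any execution order gives identical results.

## Synthetic data generator

Emulates the statistical structure of a multi-context compendium without
claiming RNA-seq realism:

* **Conditions.** `n_clusters` isotropic Gaussian clusters of
  `samples_per_cluster` conditions in `n_features` dimensions. Centroids are
  drawn N(0, τ²I) with τ = separation × within_sd / √(2d), so the *expected*
  pairwise centroid distance equals `cluster_separation × within_sd`.
  Defaults (6 × 30, 50 features, separation 8, within-sd 1) give clusters
  that k-means recovers exactly while remaining close enough that random
  folds mix them — the regime where the RCV/CCV contrast is informative.
* **Targets.** Each gene has `regulators_per_gene` (default 5) standard-normal
  base coefficients on a random feature subset; each cluster perturbs the
  nonzero entries with N(0, context_shift_sd²) noise (default 0.5), and
  observations add N(0, noise_sd²) noise (default 0.5). Context shift on
  *coefficients* (not intercepts) ensures a pooled model cannot trivially
  generalize across contexts — the causal mechanism behind the over-optimism
  of random CV.
* **Replicates.** A `replicate_fraction` of conditions can be duplicated with
  jitter 0.01 × within_sd. Note one global consequence: a near-duplicate pair
  drives D<sub>min</sub> toward 0, which *rescales every other normalized
  distance upward*; replicates collapse the distinctness of affected samples
  while the collection mean may rise. Tests assert the mechanism (growth of
  near-zero scores), not a direction of the mean.
* **Held-out contexts.** Fresh clusters with fresh centroid draws and fresh
  per-cluster coefficient perturbations that share each gene's base
  coefficients — accuracy on them measures cross-context generalization with
  the training contexts' regulatory programs as the only transferable signal.

What passing tests on this generator do **not** show: robustness to count
noise, library-size and batch effects, non-Gaussian marginals, or the
unbalanced context sizes of real compendia. The distinctness score and the
CV comparisons depend only on cluster geometry, which is why Gaussian
isotropic clusters are a sufficient and analyzable stand-in.

## Numerical and interface choices

* All randomness flows from explicit integer seeds; identical seeds give
  bit-identical partitions, traces, predictions and output files. The
  composite pipeline records its root seed, parameters and per-stage timings
  in a manifest sufficient to reproduce any output.
* Expression/target matrices travel as TSV (gzip-transparent, `--transpose`
  for the features-by-conditions dialect); partitions as JSON keyed by
  condition ids; missing values are rejected rather than imputed, since every
  formula here assumes complete vectors.
* Medians of even-length score lists are the midpoint of the two central
  values. Distinctness problem sizes in the test-suite study data (180
  conditions, 50 features, 20 genes) were chosen as the smallest instances
  on which the cluster-geometry effects are comfortably resolved.

## Known limitations

* The temperature scale of the Metropolis rule is stated only up to the
  objective's normalization; mean-objective annealing at temperature T is
  equivalent to sum-objective annealing at temperature m·T. The `t_initial`
  parameter absorbs this choice.
* With test sets equal in size to one cluster, the annealing selection's top
  end is a single condensed state (see the schedule discussion above); users
  wanting a dense high-distinctness spectrum should choose test sizes that
  are not an exact multiple of the natural cluster granularity.
* Collection-level distinctness is undefined for non-exhaustive collections
  by construction; per-partition summaries are the supported alternative.
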