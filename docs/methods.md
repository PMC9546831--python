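# Methods

## Model of the problem

The package operates on binary-labelled numeric feature tables. Labels are
opaque categorical values; the minority class is always declared by the
caller, never inferred, because real datasets mark their rare class with
strings and integers interchangeably and a silent guess that swaps the
classes would invert every downstream quantity. Imbalance is summarised by
the equilibrium rate E = l/m (minority over majority count); oversampling
raises it to a target E′ ∈ (0, 1].

All geometry — neighbourhood search, clustering, centroid distances — is
Euclidean on raw feature values. Features are not standardised by default:
the published per-dataset centre distances this package reproduces are on
the raw scale (e.g. a distance of 196.66 on Pima is only possible
unstandardised). A `standardize` flag z-scores the features for every
geometric step and maps synthetic points back to the raw scale, which is the
right choice when features have wildly different units; it changes which
points are filtered and how clusters form, so it is off by default and
explicit.

## Pipeline

**Noise filter.** A minority sample whose k nearest neighbours, searched
over the *whole* dataset with itself excluded, are all majority-class is
deleted as an isolated point. The filter runs in a single pass against the
original dataset: one removal can never change another point's verdict, so
the result is independent of sample order. Majority samples are never
removed. The neighbourhood size `k_noise` defaults to 5, the k-NN convention
the whole SMOTE family builds on; it is exposed because the filter's
aggressiveness on heavily overlapping data depends on it directly.

**Clustering.** Lloyd's k-means on the kept minority samples, seeded by
k-means++ in its original form: first centre uniform, each next centre drawn
with probability proportional to squared distance from the nearest chosen
centre. Implementation details that matter for reproducibility: assignment
ties go to the lower cluster index; an emptied cluster is re-seeded at the
point farthest from its current centre; iteration stops only at a true fixed
point (centres are member means *and* no assignment changes), bounded by
`max_iter`; `n_init` restarts keep the best SSE; and a single integer seed
drives seeding, restarts and all synthesis randomness, so identical inputs
and seed give bit-identical output. k-means is implemented in-package
rather than delegated because these tie-break and repair rules are part of
the method's contract; an sklearn cross-check on separated blobs guards the
implementation.

**Cluster count.** The default is K = 2, the configuration under which the
published per-dataset weight table was produced. `n_clusters="auto"` picks K
from the SSE curve: SSE(K) for K = 1..k_max (best of 10 restarts each), and
the chosen K is the smallest whose relative drop to K+1 falls below a
threshold. The threshold default is 0.5 — "a split that fails to at least
halve the clustering error is diminishing returns". The rationale: carving a
single structureless blob into K pieces follows SSE ∝ K^(−2/d), so in low
dimension each extra cluster still removes 25–37% of the SSE; only genuine
structure produces drops far above one half (two well-separated blobs drop
~96% from K=1 to 2). A much smaller threshold can therefore never see the
curve "flatten" in 2-D and would run to k_max. K is additionally capped at
(kept minority − 1) so that by pigeonhole at least one cluster has two
members and can host interpolation.

**Weighting and quotas.** With d_i the distance from cluster centre i to
the majority-class centroid (feature-wise mean of all majority samples), raw
weights are W_i = 1 − d_i/Σd. Closer clusters — nearer the class boundary,
where misclassification happens — get strictly larger weights. Raw weights
sum to K−1, so they are renormalised to sum to 1; for the K = 2 default this
is the identity, and it makes the rule well-defined for any K. Degenerate
cases: K = 1 gets weight 1; all-zero distances give uniform weights. The
synthetic total is l_add = l′ − (l − l_outlier) with l′ = ⌊E′·m⌋. Flooring
is applied with a small epsilon guard because binary floating point makes
0.7 × 500 come out just under 350. Integer quotas n_i come from
largest-remainder rounding of W_i·l_add (remainder ties to the smaller
cluster index), which conserves Σn_i = l_add exactly on every input.
Clusters with fewer than two members cannot interpolate; their quota is
redistributed over viable clusters by renormalised weights, with a warning.

**Synthesis.** Within a cluster, seed samples are visited in random order
without replacement; a seed needing `need` more samples interpolates once
with each of its `need` nearest in-cluster neighbours when its neighbourhood
(k_eff = min(k_syn, cluster size − 1)) suffices, otherwise once with each of
its k_eff nearest, and the loop moves on; if a full pass leaves the quota
unfilled a fresh pass begins (this multi-pass fallback goes beyond the
method's published loop, which never needs it at its quota sizes).
"Nearest `need`" is resolved nearest-first with distance ties broken by
ascending index. γ is drawn fresh per synthetic sample.

The interpolation direction deserves its own paragraph. The method's native
rule is x_new = x + γ(x − x_k1): it *extrapolates away from* the neighbour,
reflecting it through the seed — the mirror image of classical SMOTE's
x_new = x + γ(x_k1 − x). Whether this reversal is intentional cannot be
settled from the text, so the package ships both: `mode="native"` (default)
implements the native rule verbatim, `mode="smote-standard"` the classical
one. Both satisfy an exact per-coordinate segment-containment identity
(synthetics lie on [seed, 2·seed − neighbour] and [seed, neighbour]
respectively) that the tests check to 1e-12, and no behaviour is silently
"corrected".

**Assembly.** The output dataset is every original sample except the
filtered minority outliers, in original order, followed by the synthetics
labelled as minority. The achieved rate is l′/m under the floor convention.

## Metrics

Minority = positive throughout. Precision, recall, specificity, F1, G-mean
= √(recall·specificity), and FPR are computed from the confusion counts;
zero-denominator ratios are reported as 0 with a flag (never NaN) so that
averaging over repeated splits stays well-defined. AUC is the tie-corrected
Mann–Whitney probability, computed through `sklearn.metrics.roc_auc_score`
on minority scores when the classifier exposes them, else on hard labels (a
two-point ROC); the report records which path was used. The independent test
oracle for AUC is the brute-force pairwise comparison sum. Overall accuracy
is deliberately not reported.

## Benchmark harness

Per repetition the data is partitioned uniformly into 10 near-equal groups;
3 random groups form the test set, 7 the training set. The defaults — 30
repetitions, balance rates (0.6, 0.7, 0.8, 0.9) — are the published
protocol; repetitions draw a *fresh* partition each time (the protocol's
wording also admits re-using one partition with different test groups; fresh
partitions were chosen as the cleaner randomisation and are flagged here as
an interpretation). Two split orders exist because the published train/test
totals are fractions of the already-balanced datasets, implying
resample-then-split; that order lets synthetic points reach the test set, so
split-then-resample (only the training portion is resampled, test rows stay
purely original) is also provided and is the recommended, leakage-free
protocol for real evaluations. Classifier adapters wrap sklearn's decision
tree and random forest at their library defaults; any object with
fit/predict/minority_scores plugs in. Classifier failures on individual
repetitions are logged and excluded from means rather than aborting the
grid. Rank tallies count, per (balance rate × classifier × metric) cell, how
often each resampler attains each rank of the mean metric, ties sharing the
better rank.

## Synthetic data

`make_imbalanced_blobs` emulates the structure the method assumes: Gaussian
majority and minority blobs plus optionally planted isolated minority points
inside the majority region. The default spec — one majority blob of 160 at
the origin, two minority blobs of 20 each at (±3, 0), spread 1.5, E = 0.25 —
has genuine class overlap, so imbalance actually costs a classifier
recall and oversampling has something to repair. Planted isolates must be at
least 3×spread from every regular minority sample (margin configurable) and
at least 1×spread from *each other* — isolates stacked on top of one another
would be mutual minority neighbours and mask each other from the filter they
exist to exercise; the placement property is re-verified post hoc. The
separated preset `isolation_spec` (minority blobs at ±8, spread 1) exists
because the overlapping default geometrically cannot host isolates at the
required margin: minority tails reach the majority centre, and the generator
correctly refuses ("spec infeasible") rather than placing them loosely.

What passing on these fixtures does **not** show: blob fixtures are
spherical, equal-variance, low-dimensional and noise-free apart from the
planted isolates. Real tabular data has correlated features, mixed scales,
and boundary geometry no Gaussian mixture matches; results on the fixtures
validate the mechanics (filtering, allocation arithmetic, determinism,
direction of effect), not expected metric values on any real dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run the arithmetic fixtures at the
published sizes (they are just arithmetic), the property suites at 100–1000
random instances, structure-recovery at 100 seeded fixtures, and the
direction-of-effect comparison at 30 repetitions on the 200-sample default
fixture — sizes at which every statistic involved is stable across seeds.
Tolerances: published weights to 1e-4 (their printed precision), published
percentages to 0.01 (they are rounded or truncated at two decimals),
segment containment to 1e-12, exact integer equality for all counts.

## Known limitations

- Binary classes only; no categorical-feature distances (SMOTE-NC style);
  dense matrices only.
- The native interpolation mode extrapolates outward; on non-convex minority
  regions this can place synthetics outside the minority support. Use
  `mode="smote-standard"` if that matters for your data.
- The noise filter can be aggressive on heavily overlapping data at small
  minority counts; it errors rather than proceeding when fewer than two
  minority samples survive.
- Weight renormalisation for K > 2 is this package's extension; published
  behaviour exists only for K = 2.
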