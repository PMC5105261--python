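# Methods

## Data model

An `AssayRecordSet` maps compound ids to outcomes in {+1 active, −1 inactive};
only the strings "Active"/"Inactive" (case-insensitive) are mapped when
reading activity tables, and all other outcome vocabulary (Inconclusive,
Unspecified, Probe, ...) is dropped with a logged count — inconclusive
outcomes are neither evidence of activity nor of inactivity. Merging assays
yields a `MultiLabelDataset`: an M × d feature matrix row-aligned with an
M × N label matrix over {+1, −1, 0}, where 0 marks a compound untested in an
assay. Compounds without a feature vector are excluded (the analogue of
compounds failing fingerprint generation). Every compound must retain at
least one observed label.

Imbalance is reported in both conventions used in HTS summaries: the percent
form is 100·actives/total interactions **truncated** at two decimals (77
actives among 424,929 interactions prints as 0.01%, which a conventional
round would report as 0.02%), and the fold form is round(inactives/actives),
the k of "1:k".

## Structure learning

The dependency structure over assay labels is a DAG learned by
constraint-based conditional-independence testing on the label matrix alone.

* **Test statistic.** For a pair (i, j) given conditioning set S, rows missing
  any involved label are dropped (pairwise-complete deletion; missingness is
  never a third category, so the test cannot latch onto the missingness
  mechanism). Within each configuration of S, the 2 × 2 table of (y_i, y_j)
  gets +0.5 added to every cell (Laplace smoothing keeps empty cells finite)
  and contributes a G-statistic 2·Σ O·ln(O/E) with one degree of freedom;
  strata with fewer than `min_stratum_rows` (default 5) rows are skipped and
  counted. The summed statistic is referred to a χ² tail. Independence is
  declared when p > α (default α = 0.05). Fewer than `min_rows` (default 10)
  complete rows in total is an error, not a verdict.
* **Skeleton.** The criterion conditions on the full remainder of the label
  set, so the search enumerates conditioning subsets of all other labels in
  increasing size, removing edge i–j at the first subset that renders the
  pair independent. For N ≲ 10 this is cheap, and it makes the skeleton
  order-independent and exactly monotone in α (every edge kept at a small α
  is kept at a larger one).
* **Orientation.** V-structures are oriented from separating sets
  (conflicting collider claims revert the edge to undirected), Meek rules
  propagate, and residual undirected edges are oriented from the lower to
  the higher assay id — unless that closes a cycle, in which case the
  reverse direction is taken. The result is always a DAG; tie-breaking is
  deterministic so repeated runs agree.

Structure is learned per training fold inside cross-validation by default; a
`leaky_structure` flag learns it once on the whole dataset for comparison
with protocols that did so.

## The DRABAL model

Classifiers are trained in topological order. For node l with parents
pa(l), the design matrix is `[X ‖ score_p for p in pa(l)]` where `score_p`
is parent p's predicted activity probability for **every** row — observed
and missing alike. Consequences:

* missing parent labels are imputed by the parent's classifier rather than
  coerced to negatives;
* train-time and test-time feature semantics are identical (scores in both),
  so no ground-truth labels are substituted at training time;
* rows whose own label for assay l is missing are excluded from l's training
  targets only — no classifier ever trains on imputed targets.

Parent scores default to the fitted parent's in-sample probabilities; the
`parent_scores="out_of_fold"` switch computes them by internal 5-fold
prediction on the observed rows to curb the optimism such in-sample scores
can carry. Class calls use a threshold of 0.5 on the probability scale
(configurable; score ≥ threshold → +1). One integer seed drives every
stochastic component; each node's estimator gets a seed derived
deterministically from (model seed, column index), and the same derivation
is used by the binary-relevance fitter so that DRABAL with an edgeless graph
is bit-identical to BR.

Base classifier families and defaults: random forest (500 trees), K-nearest
neighbours (K = 3, scores are neighbour-vote fractions: two positive
neighbours of three give 0.67), and RBF-kernel SVM at default cost with
Platt-calibrated probabilities so chain/score features are comparable across
families. Tests and the acceptance script use 25–150 trees, which keeps the
wiring and comparisons identical while fitting a desk-scale compute budget.

`impute_missing_labels` returns the completed score matrix (+1→1, −1→0,
missing→classifier probability); `screen` ranks compounds per assay by
descending score with ties broken by compound id.

## Baselines

* **BR**: one classifier per assay, trained on that assay's observed rows.
* **CC / CC-MLE**: a chain over a permutation of the assays; the i-th model
  consumes d + i − 1 columns. `as_negative` (CC-MLE) coerces all missing
  labels to −1 and feeds hard (coerced) labels forward at training;
  `score_impute` feeds predicted probabilities and coerces nothing. At
  prediction time both feed probabilities, matching training-time semantics
  of the probabilistic variant (the chain literature is split; probabilities
  avoid a train/test mismatch for `score_impute` and change little for
  `as_negative`).
* **RandomOrder-n**: n distinct seeded permutations, each chained with
  score imputation; the reported performance is the mean of the per-order
  metrics.

## Evaluation

Per assay, sensitivity/specificity/precision are computed over rows with an
observed actual label; imputed values are never treated as ground truth.
The macro averages compose into GMean, F1 and F0.5 (the composites are
functions of the averaged components, not averages of per-assay composites).
A per-assay component with an empty denominator contributes 0 and is logged;
none of the shipped experiments hits this case. Method comparison uses a
two-sided paired t-test on fold-wise metrics at the 5% level. A
zero-variance difference vector is degenerate for the t statistic and is
reported as not significant with p = 1 — this includes the constant non-zero
case, a deliberate conservative convention since no variance information
exists to justify a verdict. The Venn partition of correctly predicted
actual positives counts, for every exact subset of methods, the (row, assay)
positives that precisely those methods hit, plus the missed remainder.

## Synthetic data

The generator emulates integrated confirmatory screening data: independent
Bernoulli fingerprint bits (on-probability 0.3), N labels from a known DAG,
per-assay imbalance, and MCAR missingness.

* Each label owns a **disjoint** block of bits (default: equal partition),
  so inter-label dependence flows only through DAG edges and structure
  recovery is well-posed; real fingerprints share bits, which this default
  deliberately idealises.
* Label l is drawn from a logistic model: intercept + centred-block weights
  (weights N(0, scale) with a 0.5 magnitude floor so every block is
  informative; default scale 1.5) + one term per parent edge. The per-edge
  coupling c ∈ [0, 1] maps to the logit weight ln((1−ε)/ε) with
  ε = (1−c)/2, i.e. c is one minus twice the parent–child disagreement
  probability in the feature-free limit: c = 0 is independence, c = 0.8 a
  10% flip rate, c = 1 near-determinism (ε floored at 1e−4).
* Intercepts controlling imbalance are calibrated by bisection against a
  20,000-row pilot draw with common random numbers (monotone, deterministic);
  the contract is a realised fold within 20% of target on the pilot.
  `pubchem_like_spec` defaults to five assays with a two-parent hub plus a
  chain tail, target folds (33, 33, 40, 12, 4) and 30% missingness — the
  integrated-dataset regime at generator scale.
* Missingness is completely at random (each entry masked with probability ρ,
  default 0.3). Real missingness (untested compounds) is plausibly
  informative; no mechanism being established, MCAR is the default and a
  `positive_biased` mask (actives twice as likely masked) exists for
  robustness checks. Rows that would lose every label keep one randomly
  chosen entry, a negligible correction at N = 5, ρ = 0.3 (~0.2% of rows).

Because the generator idealises (disjoint blocks, independent bits, logistic
noise, MCAR), passing tests demonstrate correctness of the machinery and the
direction of the coupling benefit under the stated mechanism — not
performance levels on real fingerprint data.

## Problem sizes and experiment design

The shipped experiments are desk-scale by design:

* Structure recovery: 5-node hub-and-chain DAG, coupling 0.8, 30% missing,
  n = 20,000 rows, 10–20 seeds; null calibration: 4 independent labels,
  n = 5,000, α = 0.01, 20–50 seeds.
* Coupling benefit: 3 labels (one informative parent, two weak-feature
  children, coupling 0.9), M = 900 (600 train / 300 test), 30% missing,
  random forest with 150 trees, 20 replicates; the claim is the win *rate*
  of DRABAL's macro F1 over BR's, evaluated against the unmasked truth
  labels of the held-out rows.
* CV demonstration: the five-assay generator at M = 2,000 with folds
  (12, 12, 12, 8, 4) and weight scale 2.5 — milder than the (33, 33, 40)
  targets so that every fivefold split retains enough actives per assay for
  training, and with features informative enough that desk-scale forests
  learn at all. Metrics on a single dataset at this size carry substantial
  seed-to-seed variance (the sign of the DRABAL−BR difference can flip);
  the controlled win-rate experiment above is the calibrated claim.

## Known limitations

* Constraint-based structure learning needs N small (subset enumeration is
  exponential in N; `max_cond_size` caps it) and M large relative to 2^|S|
  strata.
* In-sample parent scores are optimistic for strong learners; the
  out-of-fold switch trades runtime for unbiased feedback.
* The fixed 0.5 threshold under strong imbalance yields low sensitivity;
  ranking (`screen`) is the intended operational output, and thresholds are
  configurable per model.
* No conditional-probability-table inference is performed; the DAG guides
  feature augmentation only.
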