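# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `rehablearn`. It states
no empirical result beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Data model

A subject record carries six features — completion time (s), age (y),
height (m), weight (kg), BMI (kg/m²) and a binary sex code (0 = female,
1 = male) — plus up to two categorical labels: *difficulty* (TUG: walk,
turn, stand_sit, normal, fast; FTSTS: slow, fast) and *condition*
(18 TUG classes, 13 FTSTS classes, both with `healthy` as reference).
Class orderings are frozen constants so integer codes are reproducible.
The row identity BMI = weight/height² (relative tolerance 1e−6) is
enforced at every pipeline stage.

## Cohort synthesis

Each class table of n rows is generated from its summary statistics
(μ, σ per feature, % female):

1. Every feature is drawn i.i.d. N(μ, σ²) and sorted ascending.
   Sorting aligns rank across features — a monotone coupling that
   encodes the near-linear relationships (slower completion time at
   higher age, higher BMI at higher age, heavier at higher BMI)
   reported for these mobility tests. Draws of strictly positive
   quantities are truncated at their physical bound by redraw; ages are
   clipped at 0.
2. *Variability insertion* relaxes the coupling: round(f·n) seeded
   index-pair swaps, each pair at most `swap_window` apart (default
   n/4), applied (a) to the age column alone (fraction
   `swap_fraction_age`, default 0.15) and (b) jointly to the linked
   block {BMI, weight, sex} (fraction `swap_fraction_bmi_block`,
   default 0.15). Joint swaps leave within-block correlations intact
   while decoupling the block from the sorted columns. Swaps are
   permutations, so per-column moments are exactly preserved.
3. The sex column starts as floor(n·%female) zeros followed by ones;
   its placement is randomised only through the joint block swaps.
4. Height is derived as h = √(w/BMI) — the only form dimensionally
   consistent with BMI = w/h²; a literal w/BMI ratio is available
   behind the off-by-default `literal_ratio` flag for compatibility
   experiments — then affinely rescaled so its sample mean and SD equal
   the class's height targets exactly, and BMI is recomputed as w/h².

The last step trades exact BMI moments for an exact row-wise BMI
identity and exact height moments: the recomputed BMI mean stays within
a few percent of its target, but its SD can drift substantially
(observed ~10–40 % with the shipped defaults) because weight and the
rescaled height are nearly independent after the block swaps. The
drift is measured on every generated class and emitted as a warning
above 10 %. Users who need tighter BMI moments should widen
`sigma_height` toward the natural SD of √(w/BMI) or accept looser
height moments.

Generation is deterministic: per-class RNG streams are spawned from
(seed, class index), and all Gaussian draws complete before any swap
draws, so the pre-swap columns are identical across variability
settings at equal seed.

`validate_correlations` compares a dataset's 6×6 Pearson matrix against
a reference matrix (e.g. from a recorded dataset) and is the intended
instrument for tuning the swap fractions; constant features are flagged
and excluded. The default fractions were chosen once as moderate
decoupling and are not calibrated to any particular reference.

### Default parameter files

The shipped per-class (μ, σ) files (`src/rehablearn/data/*.yaml`) are
**synthetic stand-ins**, flagged `non_canonical: true`. Published
sources for these tests report cohort statistics, but no consolidated
per-condition table is available to ship; the defaults were written
once to be clinically plausible (completion-time means increasing with
severity; demographics typical for each condition) and to lie inside
published cohort ranges (TUG: age [5, 112] y, height [0.81, 2.20) m,
weight (30, 136) kg; FTSTS: age (11, 93] y, height [0.94, 2.35) m,
weight (22, 120) kg — enforced as warning-level checks on load).
Results that depend on these files are illustrative of the method, not
reference clinical values.

## Preprocessing

* **Outlier removal**: single pass; column means/SDs computed once on
  the input, a record is dropped iff any continuous feature deviates
  more than 3 SDs. The binary sex code is not screened (a 3σ rule on a
  minority-rate binary code would delete a protected subgroup).
* **Normalization**: per-feature affine map of the training min/max to
  [−1, +1]; constant features map to 0; the inverse is exact to 1e−9.
  Fitted on training data only and carried with the trained models.
* **SMOTE**: minority classes are oversampled to the majority count.
  A synthetic record interpolates a random minority parent toward one
  of its k = 5 nearest same-class neighbours (k capped at class
  size − 1) with u ~ U[0, 1] in *raw* feature space; BMI is then
  recomputed from the synthetic weight and height, and sex is copied
  from the parent (a binary code cannot be interpolated). Majority
  records are never modified. Balancing runs on the whole labelled
  pool before any train/test split — this matches per-class totals that
  include test data but leaks synthetic neighbours across the split,
  so a warning is logged on every call.

Pipeline order: encode → outliers → SMOTE → normalize.

## Base models

Both models train on the same stratified 80/20 split with five-fold
stratified CV (fixed seed; a class smaller than the fold count raises
rather than silently degrading):

* **Boosted trees** (xgboost, exact greedy splits): softmax multiclass
  objective with probability output for >2 classes, the native
  logistic objective for 2; initial max_depth = 2 × number of classes.
  The default tuning grid is compact — learning_rate {0.1, 0.3} ×
  n_estimators {50, 100} × max_depth {3, 2C} — so a full run fits a
  single CPU; `full_boosted_grid()` exposes the wide 432-point grid
  over booster, η, estimators, depth, child weight, γ, subsampling,
  column sampling and both regularisers for offline tuning.
* **k-NN**: exact brute-force Euclidean on normalized features,
  probability = vote fraction among the k nearest (stable distance
  ties; vote ties to the lowest class code); k tuned over {1, 3, 5, 7,
  9}, initial 5. A bespoke store (rather than a tree index) keeps
  incremental insertion O(1) and makes the vote arithmetic exactly
  reproducible against an exhaustive oracle.

Each trained pair also carries per-class centroids (arithmetic feature
means in normalized space), normalized-space feature importances from
the booster (non-negative, unit sum), and the fitted normalization.

**Incremental updates** append the labelled record to the k-NN store,
add 5 boosting rounds fitted in place on the appended training set
(existing trees are never discarded; the native in-place update avoids
re-serialising a growing forest each session), and update the labelled
class's centroid as a running mean.

## Hybrid session engine

Per session: append the new completion time; fit a degree-2
least-squares polynomial to the history and take its derivative at the
last index as the improvement rate (histories shorter than 3 report
steady with rate 0); classify the record with both models on both
axes; compute each candidate class's centroid distance to the healthy
centroid; select per the improving→closest / worsening→farthest /
steady→baseline rule (distance ties to the boosted candidate); retrain
both models of both axes with the selected label; derive safety flags;
emit a transparent bundle (both predictions with probability vectors,
distances, baseline, branch).

Decided parameters (the field reports no standard values; all
configurable via `EngineConfig`):

| parameter | default | rationale |
|---|---|---|
| polynomial degree | 2 | captures recovery curvature, robust on short histories |
| steady band ε | 1 % of the user's mean completion time | scale-free per-user band |
| forcing threshold | 3ε | implausibly steep improvement |
| deterioration window | 3 consecutive worsening sessions | early but not jumpy |
| co-morbidity alert window / fraction | 10 sessions / 0.8 | persistent disagreement |
| fall timeout | 120 s | test started, never completed |
| physical time bounds | [1, 300] s | sensor sanity range |

Distances default to *centroid mode* (distance between the predicted
class's training centroid and the healthy centroid): the selection
rule's inputs are class labels, so a class-level distance is the
consistent reading; *point mode* (incoming point to healthy centroid)
is available but then both candidates tie and selection degenerates to
the tie-break. The healthy reference on the difficulty axis — which
has no "healthy" class — is the non-impaired class: TUG `normal`,
FTSTS `fast`.

The **co-morbidity drift alert** fires when ≥ 80 % of the boosted
model's last 10 raw condition predictions differ from the
clinician-initialised condition. It deliberately watches raw model
predictions rather than the post-selection finals: the steady branch
returns the baseline, so finals reproduce the initialised condition by
construction and could never reveal drift.

Static test-split evaluation (`evaluate_hybrid`) has no per-user
history, so each record is scored with steady status and its own
boosted prediction as baseline; when the two models agree — the common
case on separated data — the final class is the agreed one regardless
of branch.

### Self-reinforcement caveat

Retraining with self-selected labels is a positive feedback loop. On a
stationary stream that starts correctly classified, cumulative accuracy
is non-decreasing and the models specialise to the user — the intended
behaviour. The same loop can entrench an initial *error* (e.g. a
steady stream whose condition was mis-initialised stays at the
baseline and the models are pulled toward it); the drift alert watches
raw predictions precisely to surface this case while the evidence still
disagrees.

## Fixtures and the synthetic study conditions

* `fixture_experiment` emulates a small lab recording: 8 participants
  (ages 20–45, one female in eight — a deliberately biased convenience
  sample), per-difficulty counts TUG (walk 40, turn 40, stand_sit 40,
  fast 39, normal 24 → 183 rows) and FTSTS (slow 33, fast 40 → 73
  rows), completion times uniform within *disjoint* per-class ranges.
  The disjoint ranges make the fixture perfectly separable on time —
  by design, mirroring acted difficulty levels — so perfect fixture
  accuracy shows the pipeline is sound, **not** that real patients are
  this separable.
* `fixture_session_stream` realises named trends (improving /
  worsening / steady / forcing / abandon) around a base time with 2 %
  noise; abandoned streams end with a start-without-completion session.
* The individualisation study crosses fixture participants with every
  difficulty class, streaming stationary single-class sessions (class
  mid-range base time) through the full session loop with fresh model
  clones per combination. The acceptance script runs 8 individuals ×
  5 TUG difficulties × 200 sessions; the test suite runs a scaled-down
  4 × 5 × 40 version. The condition models for this study are trained
  on a synthetic cohort scaled to 40 records per class, a size chosen
  to keep a single-CPU run tractable while preserving all 18 classes.

What the fixtures do *not* emulate: measurement noise correlated with
demographics, overlapping class distributions, missing sessions,
within-user demographic change, or realistic class priors. Passing
tests on them validates algorithmic structure and bookkeeping, not
clinical performance.

## Numerical choices

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); derived streams use SeedSequence
  spawning or counter-based offsets below 2³¹. Equal seeds reproduce
  datasets value-for-value and training runs choice-for-choice
  (xgboost runs single-threaded with exact splits for determinism).
* Probability ties break to the lowest class code; baseline ties to
  the most recent tied class; association-table ties lexicographically.
* Degenerate inputs: constant features normalize to 0 and are excluded
  from correlation comparisons; a never-predicted class has precision
  defined as 0 and is flagged; empty histories/datasets raise typed
  errors rather than returning NaN.
* Macro (unweighted) averaging over classes present in the true labels
  for the summary metrics.

## Limitations

* The shipped cohort statistics are stand-ins; nothing downstream of
  them is a clinical reference value.
* SMOTE-before-split inflates test estimates on balanced fixtures (the
  logged leakage warning); use `preprocess` on training folds only if
  honest generalisation estimates are needed.
* The booster grows ~5 trees per class per session under incremental
  retraining; multi-year histories would need periodic compaction,
  which the package does not implement.
* Variability swap mechanics (count, locality) are one reasonable
  realisation of partial decoupling; matching a specific reference
  correlation matrix requires tuning the fractions via
  `validate_correlations`.
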