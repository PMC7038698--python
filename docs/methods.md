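# Methods

## Problem setting and model

We observe a stream of timestamped smart-home sensor events. Motion and door
sensors emit categorical states (ON/OFF, OPEN/CLOSE); environmental sensors
emit numeric samples. Annotations `label begin` / `label end` delimit
activity instances. A training set covers the *seen* activity classes
`T_tr`; the goal is to label instances of *unseen* classes `T_ts`,
`T_tr ∩ T_ts = ∅`, for which no sensor data exist.

The bridge is a semantic space shared by all labels: each activity name maps
to a word-embedding prototype `y_t ∈ ℝ^L`. The recognizer is a shallow
network — dense `n→128` (SELU), dense `128→L` (SELU), each followed by batch
normalization — capped by a *frozen* linear layer whose weight matrix holds
the L2-normalized seen-class prototypes as columns, then a softmax over the
seen classes. Training (Adam, categorical cross-entropy) can only shape the
layers below the frozen matrix, so minimizing the loss forces the `L`-dim
activation toward the training class's prototype direction: that activation
is the network's embedding of an input in word-vector space. At test time an
unseen instance is labeled by maximal cosine similarity between its embedding
and the unseen prototypes.

Assumptions worth stating explicitly:

- **Counts suffice.** An instance is summarized by how often each sensor
  activated; order and duration are discarded. This is adequate when
  activities occupy distinct sensor neighborhoods, and inadequate when two
  activities differ only in dynamics.
- **Congruence.** Transfer works only insofar as relations between activity
  names in embedding space mirror relations between their sensor profiles.
  The synthetic negative control below makes this assumption falsifiable.
- **Closed unseen set.** Prediction selects among a known list of candidate
  unseen labels (optionally inflated with distractors); this is standard
  zero-shot, not open-set detection.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| hidden widths | 128, L | L equals the embedding dimension (300 for Google-News; toy tables are smaller) |
| activation | SELU | self-normalizing choice, paired with LeCun-normal initialization |
| optimizer | Adam, lr 1e-3 | batch size 32, 200 epochs |
| batch norm | on | after each hidden layer's activation (placement is our choice; see below) |
| scaler | per-column standardization | fitted on the training count matrix only |
| loss | softmax cross-entropy | a regression-to-prototype MSE loss is available behind `loss="regression"` for comparison |
| class weights | off | optional inverse-frequency weighting for imbalanced seen classes |

All randomness (initialization, batch shuffling, simulation) flows from a
single integer seed through `numpy.random.default_rng`; identical config +
seed + data reproduce parameters and predictions exactly.

## Design choices made where the design was open

- **Embedding = the pre-frozen-layer activation.** The frozen layer is a
  plain matrix product with prototype columns, so the only representation
  living in word-vector space is the activation feeding it; `embed()`
  returns exactly that (after batch norm, in inference mode).
- **Prototype columns are L2-normalized**, making the logits proportional to
  cosine similarity and scale-comparable across classes.
- **Activation = {ON, OPEN}.** Door sensors participate in the counts on the
  same footing as motion sensors; OFF/CLOSE transitions are ignored. Numeric
  environmental sensors are excluded from the default vocabulary; an
  optional binarization counts value changes exceeding a threshold.
- **Multi-word labels average their token vectors** (lowercase; split on
  spaces, underscores and camel-case), the standard composition when only
  single-word vectors exist.
- **Ties break lexicographically** in nearest-prototype matching, for
  reproducibility.
- **Batch-norm placement** (after each hidden activation) and the
  **softmax/cross-entropy head** are our documented readings of an
  architecture that is described but not fully pinned down; the regression
  head exists as a flagged alternative.
- **Metric orientation.** Confusion matrices use rows = truth, columns =
  predicted; precision and recall follow their one-vs-rest definitions
  literally. Published metric tables in this line of work sometimes print
  the precision and recall columns exchanged relative to their own confusion
  matrices; accuracy and F-measure are invariant under that exchange (F1 is
  symmetric in P and R), which is how such tables stay internally
  reconcilable. One published scenario matrix is not reconcilable with its
  own metrics table under any orientation and is therefore excluded from
  worked-example tests.
- **Unlabeled gaps** (events between an `end` and the next `begin`) belong
  to no instance and are dropped; instance boundaries are inclusive of the
  annotated events themselves.

## The synthetic generator

`make_congruent_scenario(k_seen=5, k_unseen=3, n_sensors=30)` builds the
default study: each seen class dominates a disjoint block of sensors with an
expected `separation = 10` activations per instance against a background
rate of 0.5; 60 training instances per seen class and 200 test instances
total. Unseen class *u*'s feature profile is the convex mixture
`mixing[u] @ seen_profiles` with rows pairing consecutive seen classes at
weights (2/3, 1/3) — and its prototype is the *same* mixture of the
(orthonormal) seen prototypes, optionally noised. Event streams draw
per-sensor counts from a Poisson law, pair every ON with a later OFF, keep
timestamps strictly increasing, and wrap instances in begin/end markers, so
generated data traverse the real parser and featurizer; the generator also
returns its drawn counts so exact recovery is testable.

These sizes keep a full end-to-end run in a few seconds while leaving the
binomial uncertainty of a 200-instance accuracy small (99% half-width
≈ 0.086 at chance).

**Negative controls.** Permuting the unseen rows of the feature-side mixing
while leaving prototypes fixed breaks congruence. With a *transposition*,
one of the three classes stays congruent and the swapped pair is
consistently cross-assigned, so accuracy settles at ≈ 1/3 — exactly chance
level for three classes. A full *derangement* leaves no congruent class and
drives accuracy to ≈ 0, i.e. below chance: the errors are systematic, not
random, which is itself evidence that prediction is driven by the semantic
geometry rather than noise. Both controls are exercised.

**What the synthetic data do not emulate:** diurnal routine structure,
Markovian activity ordering, sensor noise/dropout, multi-resident
interleaving, and the hubness of real 300-d embedding neighborhoods (toy
tables are low-dimensional, where random distractors sit much closer to
prototypes than random English nouns do in 300-d). Passing synthetic tests
therefore demonstrates the correctness of the machinery and the
congruence-dependence of transfer, not field performance on real homes.

## Numerical notes

- SELU uses the standard constants (α ≈ 1.67326, λ ≈ 1.05070); weights are
  LeCun-normal.
- Batch normalization keeps running mean/variance (momentum 0.9, ε = 1e-5)
  for deterministic, batch-independent inference.
- Softmax is computed with max-subtraction; cross-entropy clamps log(0) with
  1e-12.
- Checkpoints are JSON; Python's float repr round-trips IEEE doubles, so a
  reloaded model reproduces predictions bit-for-bit.
- Degenerate inputs: zero vectors are rejected by cosine similarity;
  0/0 precision, recall or F1 are defined as 0; empty instances featurize to
  zero vectors; an all-zero Poisson draw is resampled (an annotated instance
  needs at least one event to carry its markers).

## Known limitations

- The count featurizer needs pre-segmented (annotated) instances; online
  windowing of unannotated streams is out of scope.
- Reproducing published household numbers exactly requires the original
  grid-searched hyperparameters, which are not public; the integration
  script demonstrates the pipeline on real data without asserting them.
- No correction for hubness or seen-class bias is applied; with many or
  semantically crowded unseen candidates (the knn distractor setting),
  accuracy degrades, as the distractor experiment shows.
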