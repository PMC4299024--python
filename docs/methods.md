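# Methods

This note documents the models, the estimation rules, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Signal model and featurization

The input is a triaxial acceleration stream in g at a nominal 20 Hz with
strictly increasing timestamps; irregular sampling is not resampled (out of
scope).  Each axis is smoothed by the causal average filter
`v_s(t) = (1/n) Σ_{i=t−n}^{t−1} v(i)` with n = 10.  The filter as written is
undefined for t < n; we use partial-prefix averaging (`v_s(0) = v(0)`, then
the mean of all available preceding samples) so the output keeps the input
length and no data is discarded.  Note the filter is a low-pass with its
first spectral null at f_s/n = 2 Hz: rhythmic movement above ~1.5 Hz
survives only at a few percent of its amplitude, which matters when
reasoning about what the downstream features can see.

Windows are l = 60 samples (≈3 s) long with 33% overlap, i.e. a step of
`l − round(0.33·l)` = 40 samples; a trailing partial window is discarded.
Twelve features per window, in fixed order: per-axis mean; per-axis
*population* variance (divide by l — the estimator choice is fixed for
reproducibility, not forced by theory); the three pairwise Pearson
correlations, defined as 0 when either axis is constant so the feature map
is total; and mean, population variance and mean absolute first difference
of the magnitude √(x²+y²+z²).  The signed mean derivative telescopes to
(m_T − m_1)/(l−1) and carries almost no information, hence the absolute
version.  Every window takes the majority label of its samples against the
half-open labeled intervals, ties resolved toward the interval appearing
earlier in time; windows outside every interval are `not_tagged`, which is
a first-class label everywhere downstream.

## Vector quantization

A codebook of M centroids is fit by k-means (k-means++ initialisation, 10
restarts keeping the lowest within-cluster sum of squares, 300 iterations,
seeded) on training windows only.  Features are not standardized by
default — the quantizer operates on raw feature scales, so means and
correlations (both O(1)) dominate the Euclidean metric over variances
(O(10⁻²)); a `standardize` flag exists for sensitivity analysis.
Assignment maps a window to the nearest centroid, ties to the lowest ID.
M = 300 is the default for real wrist data; for the synthetic scenario we
use M = 24 (see below).

## Sequence models

All tables are estimated by counting with additive smoothing α (default 1):

* emissions `B[q][k] ∝ count(primitive k under label q) + α`;
* transitions from adjacent window-label pairs, `A[i][j] ∝ count(i→j) + α`;
  π is always uniform.  A `uniform` transition mode (every entry 1/N)
  supports the no-transition-information ablation;
* k-mer conditionals per state from the concatenation of all of that
  state's episodes, `P(w|q) = (count(w) + α) / (L − k + 1 + α·M^k)` with
  overlapping counts; the table is stored sparsely (observed k-mers plus a
  shared default) because M^k = 90,000 at the default M and k and almost
  all entries are unobserved;
* the duration array κ(i) = max(1, ⌊min-run-length(i)/2⌋): halving the
  observed minimum allows deviance from training durations, flooring keeps
  κ a positive integer.

Smoothing with α > 0 is essential rather than cosmetic: at M = 300 unseen
primitives and k-mers at test time are certain, and the scores live in the
log domain.  With α = 0 unseen events score −∞, which the decoders handle,
but the default is α = 1 everywhere a log is later taken.

## Decoding

Both scorings are additive over a path, so one pair of dynamic programs
serves both.  The CRF score `Σ_t Σ_i ω_i f_i` uses f1 = log P(o_t|q_t),
f2 = log π(q_1) at t = 1 and log A[q_{t−1}, q_t] after, and
f3 = log P(o_t…o_{t+k−1} | q_t).  f3 depends only on the observations and
the state at t, so it folds into the emission term; at the last k−1
positions the k-mer would run past the end of the sequence and f3
contributes 0, which keeps scores comparable across paths.  With
ω = (1,1,0) the CRF score telescopes exactly to the HMM joint
log-probability — a reduction the tests assert path-for-path.  The
normalizer Z is never computed: the argmax over paths does not need it.
Feature weights are not gradient-trained; "training" the CRF means
estimating the frequency tables, and ω defaults to (1,1,1) but is
configurable.

The duration constraint requires every maximal run of state i — including
the first and last runs of the sequence — to span at least κ(i) positions.
The exact decoder runs on cells (state j, run length capped at κ(j)):
staying in j advances the run counter, entering j is allowed only from
another state's cap cell, and the path must end in a cap cell.  Cost is
O(T·(Σ_j κ(j) + N²)) time and O(T·Σκ) memory for backtracking.
Tie-breaking is toward the lowest state index at every argmax in both
decoders, so the vacuous-constraint case (all κ = 1) reproduces plain
Viterbi exactly, ties included.  Brute-force enumeration oracles (with
run-length filtering for the constrained case) are part of the public
decode module and the tests compare both programs against them on random
instances; on continuous random tables ties have probability zero, and the
tests assert path equality whenever the enumeration optimum is unique and
score equality always.

## Subclassing

Each labeled episode (maximal same-label run of windows) becomes an
instance: an M-bin histogram of its primitives, normalized to relative
frequencies because episodes differ in length and raw counts would
confound duration with content.  For each class in turn, k-means (seeded,
10 restarts) splits its instances for k = 2 … min(maxK, n_i − 1)
(maxK default 5), each split scored by the chosen validity index:

* Silhouette: mean over points of (b − a)/max(a, b); singleton clusters
  score 0;
* PBM: ((1/K)·(E1/EK)·DK)², E1/EK being distance sums to the global/own
  centroid and DK the largest centroid separation; EK = 0 returns +∞;
* GDI33 (generalized Dunn, variant (3,3)): min pairwise mean inter-cluster
  distance over max of twice the mean distance-to-centroid; all-zero
  diameters return +∞.

The index-optimal k becomes a candidate split, and the split is kept only
if it *strictly* improves leave-one-instance-out cross-validation accuracy
of a multinomial naive-Bayes classifier on the instance count vectors
(Laplace smoothing; predictions are mapped back to original classes before
scoring, matching how the full pipeline is evaluated).  Classes are
processed in sorted order and accepted splits update the running labeling,
so the final accuracy is monotonically non-decreasing by construction.
A `fixed` mode clusters each class into a user-supplied number of
subclasses with no gate — the programmatic replacement for choosing
fragment counts by eye from a dendrogram.  After relabeling, all model
tables including κ are re-estimated on the subclass labels, treating
subclasses as independent classes; predictions are mapped back before any
comparison with ground truth.  The catch-all `not_tagged` class is
eligible for subclassing like any other class.

## Evaluation

Leave-one-day-out: for each held-out day the codebook, every table, κ and
the optional subclassing are re-estimated from the other days only.
Accuracy is the fraction of window positions whose (mapped-back) predicted
class equals the ground truth, with `not_tagged` in the denominator like
any class.  The pooled confusion matrix accumulates counts over folds
(rows = truth); per-class sensitivity is the diagonal over the row sum,
undefined (NaN) for empty rows.  Training folds are concatenated in
canonical run-id order so results are invariant to how the run list was
ordered.  Two baselines ignore the accelerometer entirely: clock time is
discretized into 15-minute bins and either the training-majority class per
bin is predicted, or a plain-Viterbi HMM with time bins as observations
decodes the day.  Per-day accuracies are exported so external statistical
tooling can compare methods; the hypothesis tests themselves are out of
scope.

## Synthetic data generator

The generator emulates the structure the method assumes, at desk scale.
An activity owns one or more *regimes*: a mean orientation (the gravity
component in the wrist frame), per-axis Gaussian noise, and an optional
sinusoid modelling rhythmic movement as a one-dimensional motion along a
fixed direction in the sensor frame with a random per-episode phase.  The
directional model matters: it makes the inter-axis correlation pattern a
stable signature of the regime, where independent per-axis phases would
scatter each class over the whole correlation cube.

The default scenario has six classes: dominant sedentary `working`;
`meal`; short high-variance `hygiene` (1.3 Hz scrubbing); `exercise`
(1 Hz arm swing); a deliberately fragmented `commute` drawing per episode
either a walking regime (0.9 Hz swing, closest neighbour of `exercise`) or
a near-stationary vehicle regime that overlaps the idle posture except for
a weak 0.4 Hz sway; and `idle`, which is never labeled.  Oscillation
frequencies sit in the band the causal filter passes; mean orientations are
separated by ≥0.5 g except for the two deliberately confusable pairs
(commute-walk/exercise, commute-vehicle/idle).  The separation scale is
chosen against a measurable noise floor: window correlations of filtered
noise have an effective sample size of about 6, i.e. ~0.4 scatter per
correlation feature, and regimes closer than that in the unstandardized
feature space are not resolvable by the quantizer — "well separated" is
defined relative to that floor.

Days are schedules of episodes drawn by weight without immediate repeats,
durations uniform within per-class bounds, drawn only among classes that
fit the remaining day so no duration is truncated.  Idle episodes are
always untagged and 5% of activity episodes have their labels withheld
(ground truth retained in a trace), yielding ≈45% untagged time.  Short
*gesture bursts* (rate 0.5/min, 3–8 s) replace the signal with a regime of
some other activity while the label stays put — the transients that make
unconstrained decoding emit short spurious segments, i.e. exactly the
failure mode the duration constraint removes.  The default day is 3600 s
at 20 Hz and scenario pipelines use M = 24 primitives with k = 2: an
hour-long day carries seven regimes, so 24 centroids are ample and the
576-entry 2-mer table stays well estimated at these sequence lengths.

What the generator does not emulate: biomechanically realistic
accelerometry (no gravity rotation during movement, no heavy-tailed
artifacts), diurnal schedule structure (labels are independent of clock
time, so the time-of-day baselines perform near chance by design),
drift or missing samples.  Consequently, passing tests demonstrate that
the implementation recovers planted structure of the kind the method
assumes — not that the method reaches any particular accuracy on recorded
human data.

Because the catch-all class is deliberately a mixture (idle regime plus
withheld episodes of every other activity), it is itself fragmented; the
subclass search occasionally splits it, and that is correct behaviour.
The no-split expectation applies to the four single-regime activity
classes.

## Degenerate inputs and numerical conventions

Empty signals, empty windows, unknown states/primitives, patterns longer
than the text, classes absent from training, and infeasible duration
constraints (T too short for any valid path) all raise `ValueError`/
`KeyError` with the offending name in the message.  Constant windows give
exactly zero variance and zero correlation.  All stochastic rows normalize
to 1 within 1e−9 for any α ≥ 0.  Scores use −∞ for log 0 and the decoders
propagate it correctly; serialized models round-trip at full float
precision (CSV written with 17 significant digits and parsed with
round-trip precision).
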