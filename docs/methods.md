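# Methods

## Problem setting and model

The package classifies 1-second windows of waist-worn triaxial
accelerometer data into ten activity classes — stair ascent (A1),
stair descent (A2), walking (A3), running (A4), sitting (A5), four
directed falls (A6–A9: right, left, front, back) and lying (A10) —
and fuses three heterogeneous classifiers by plurality vote.  The
guiding assumptions are those of scripted activity-recognition
protocols: a single sensor at the waist, a known sampling rate
(64 Hz), ground-truth labels assigned per timestamp from annotated
activity intervals, and an eleventh "transition" label covering the
stretches between scripted activities that is removed before any
model is fitted.

Evaluation is subject-independent (leave-one-subject-out): activity
style varies more between people than within one person, so windows
from the test subject must never influence training.  Two rules
enforce this: segmentation happens strictly after the train/test
split, and every normaliser, projection and classifier is fitted on
training subjects only.

## Windowing

Fixed-size overlapping sliding windows: T = round(fs × window_seconds)
samples (64 by default) with stride round(T × (1 − overlap))
(overlap 0.5 → stride 32).  Trailing samples that do not fill a
window are dropped.  A window is kept only if all T sample labels are
identical and not in the drop set; the pre-filter window count is
K = floor((N − T)/stride) + 1 for a stream of N ≥ T samples, and a
stream shorter than one window yields an empty tensor rather than an
error.  Channels are ordered (Ax, Ay, Az, An) throughout, An being
the per-sample Euclidean norm, recomputed on read when absent or
inconsistent.

## Pipeline 1: handcrafted features

Per channel, 13 statistics per window; the composition was fixed as
10 time-domain metrics (mean, variance, standard deviation, maximum,
minimum, RMS, kurtosis, skewness, l2 norm, l1 norm) plus FFT energy,
maximum FFT magnitude and the dominant-frequency bin index, and the
lag-0 Pearson cross-correlation of the three raw-axis pairs:
13 × 4 + 3 = 55 features.  Including the dominant-frequency index as
a thirteenth per-channel metric and restricting correlations to the
raw-axis pairs is the only enumeration of the named metric families
that totals 55; it is a design choice of this package.

Numerical conventions, pinned so that tests are exactly reproducible:

* population (1/T) denominators everywhere; kurtosis is the
  non-excess fourth standardised moment, skewness the third;
* windows whose variance falls below 1e-24 g² are treated as constant:
  variance, standard deviation, skewness, kurtosis and any
  cross-correlation involving them are defined as 0 (static windows
  are common; NaNs would poison downstream models);
* the FFT is taken over the raw, un-tapered 64-sample window; energy
  is Σ|X[k]|²/T over all bins, which equals the time-domain sum of
  squares (Parseval) and is asserted to 1e-6 relative tolerance on
  every window; maximum magnitude and the dominant bin exclude DC so
  the gravity offset cannot dominate them.

Features are z-score normalised with mean and population standard
deviation fitted on the training fold only; zero-variance columns map
to 0.

ReliefF ranks the normalised features: for every training instance
(all instances by default, in index order, which makes the estimate
deterministic) the k = 10 nearest same-class hits and k nearest
misses of every other class are found under Manhattan distance on
range-normalised features; a feature's weight decreases by the mean
normalised difference to hits and increases by the prior-weighted
(P(c)/(1 − P(class))) mean difference to misses, averaged over
instances.  Distance ties break by instance index (stable sort).  By
default the ranking is computed and reported but all 55 features are
retained (`top_n_features` selects a prefix when set); no retention
cutoff is imposed because none is prescribed, and ranking alone
leaves the classifier's input unchanged.

The classifier is a one-vs-all RBF SVM, γ = 0.001 and C = 1000,
implemented as l binary machines whose per-sample penalties are
scaled by the inverse-frequency weight of the sample's multiclass
label; prediction is the argmax of the binary decision functions in
sorted class order.

## Pipeline 2: per-channel LDA + KNN

Each channel's raw T-sample window is the input vector of a
supervised linear discriminant projection with at most l − 1
components (default: the maximum).  The within-class scatter is
shrinkage-regularised (Ledoit–Wolf automatic coefficient, eigen
solver) because T = 64 can exceed the per-class window count in small
folds — falls contribute only a handful of windows per subject.  The
four per-channel projections are concatenated in channel order
(4 × 9 = 36 columns for ten classes) and classified by Euclidean
K-nearest neighbours with k = 5; k is configuration, as its optimum
is data-dependent.  Vote ties break by the tied class with the
smaller mean neighbour distance, then lexicographically — fixed rules
so that predictions are deterministic.

## Pipeline 3: per-channel 1D CNN

Each channel has its own convolution block: 3 filters of width 20
(stride 1, no padding) → ReLU → max-pool 3.  For T = 64 the feature
maps have length 64 − 20 + 1 = 45, pooled to floor(45/3) = 15,
flattened to 45 values per channel and concatenated to 180.  Two
fully connected ReLU layers of 1024 and 30 units feed a distinct
l-unit softmax output layer (the 30-unit layer is not reused as the
output).  Training minimises class-weighted categorical cross-entropy
normalised by the batch weight sum — a normalisation chosen so that
weighting a class by w is gradient-identical to duplicating its
samples w times — using mini-batch SGD with momentum 0.9, learning
rate 0.01, batch size 128 and 30 epochs by default.  Weights are
initialised from a uniform fan-in scheme driven by the configured
seed.  The implementation is plain single-threaded numpy with
hand-written backpropagation (verified against central differences in
the test suite), so seeded runs are bit-reproducible on CPU; GPU
execution is out of scope.

## Fusion, metrics and orchestration

The ensemble label is the plurality of the three pipeline labels;
when all three disagree the CNN's label is returned (the strongest
standalone pipeline), making the vote total and deterministic.

Reports are computed from the pooled out-of-fold confusion matrix
(rows actual, columns predicted).  Per class, precision, recall and
F1 follow the usual definitions with zero-denominator cases defined
as 0 (with a logged warning).  Macro averages are unweighted
per-class means; macro F1 defaults to the mean of per-class F1 — the
convention of standard classification-report tooling — with the
harmonic mean of macro precision and recall available via
`macro_f1="harmonic"`, since the two conventions disagree in the
second decimal on imbalanced data.  Weighted averages are
support-weighted means (weighted recall equals accuracy), and micro
averages pool TP/FP/FN, so micro precision = micro recall = accuracy
for single-label multiclass; both identities are asserted on every
generated report.

Leave-one-subject-out folds are planned in ascending subject order
and executed through joblib; every fold's randomness derives from
SeedSequence((root_seed, test_subject_id)), so the pooled result is
bit-identical for any worker count or scheduling.  A fold whose
training windows cover fewer than two classes is skipped with a
warning.  Class weights K_total/(l_present × K_i) are shared by the
SVM and CNN.

## Synthetic data generator

The generator emulates the statistical structure the pipelines
exploit, not biomechanics:

* dynamic activities are a gravity baseline plus a per-axis
  fundamental sinusoid and one harmonic (ratio 0.3) with white noise;
  stair classes differ from walking by amplitude ratios and a slow
  (0.2 Hz) vertical drift, running by higher frequency and amplitude
  (defaults: A1 1.5 Hz, A2 1.8 Hz, A3 2.1 Hz, A4 2.9 Hz; noise
  0.05–0.07 g);
* static activities are gravity-oriented constants (distinct unit
  orientations for sitting and lying) with 0.02 g noise;
* falls are 1.5-s events: a 1-s half-sine transient of peak 3 g
  (≥ 3× the walking amplitude scale) whose sign pattern on the (x, y)
  axes encodes the direction, while gravity rotates from upright to a
  direction-dependent lying orientation that persists for the
  remaining 0.5 s;
* transitions of 1–3 s, labelled "transition", separate consecutive
  activities so preprocessing must actually remove them;
* inter-subject variability: per-axis gains ~N(1, 0.03), frequency
  jitter ~N(1, 0.03), a fixed sensor-orientation offset of ~3°
  standard deviation; intra-subject variability: per-trial phases,
  noise realisations, ±3 % duration jitter and per-trial activity
  order permutation.

Class imbalance lives in the activity durations (walk 35 s dominates,
sit 22 s, falls 1.5 s are rare), chosen qualitatively to mirror
scripted protocols in which locomotion dominates and falls are brief.
All draws flow from a root seed via SeedSequence((seed, subject)) for
profiles and (seed, subject, trial) for trials, so any trial can be
regenerated independently.

What the generator does **not** model — and hence what passing tests
do not establish about real data: realistic gait harmonics beyond one
overtone, soft-tissue and clothing artefacts, sensor saturation and
quantisation (signals are continuous g values), posture drift within
an activity, and fall dynamics beyond a stylised transient.  The
parameter-recovery result (ensemble macro F1 ≈ 0.98 on 6 subjects ×
2 trials) demonstrates that the implementation recovers structure the
generator genuinely contains under subject-level distribution shift;
it is not a claim about field performance.

## Problem sizes and budgets

The recovery evaluation uses 6 subjects × 2 trials (~3,100 pure
windows, six LOSO folds), which completes in about a minute on one
CPU while leaving every class, including each fall direction, with
double-digit test support.  Unit and property tests use miniature
fixtures (tens to hundreds of windows); the ReliefF and KNN oracles
are exercised at ≤ 100 and ≤ 500 instances where brute force is
exact and fast.

## Known limitations

* The LDA+KNN pipeline is the weakest on dynamic classes (as its
  time-domain input is phase-sensitive); its accuracy (~0.64 on the
  default regime) drags the ensemble below the best single pipeline
  on ties where it pairs with an erroneous partner.  This ordering —
  features+SVM and CNN strong, LDA+KNN weakest — is intrinsic to
  projecting raw phase-shifted windows linearly.
* ReliefF weight estimates depend on the neighbourhood size k;
  duplicating features changes the distance metric and can reorder
  weakly relevant features unless k spans the classes.
* The CNN is intentionally small and CPU-bound; no architecture
  search, early stopping or validation-based tuning is performed.
* Fall windows are scarce by construction, so per-fall-class metrics
  on small synthetic datasets rest on few windows and are sensitive
  to single errors.
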