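# Methods

## Problem and scope

`frailwear` implements a supervised pipeline that classifies older adults
into the three Fried frailty phenotypes (non-frail / pre-frail / frail)
from a smartwatch recording of an instrumented supermarket-shopping
activity. Labels are inputs: the package does not administer the Fried
test. The original study's microservice deployment (MQTT topics, smartwatch
firmware, cloud choreography) is out of scope; the pipeline runs in-process
with a thin CLI.

## Session model and cleaning

A session is a uniformly sampled 7-channel stream (tri-axial accelerometer
and gyroscope in device units, integer heart rate in bpm) with a
contiguous, non-overlapping annotation of the 14 protocol phases. On disk a
session is three plain-text files (JSON header, samples CSV, phases CSV)
with a schema version; floats are written with `%.17g` and parsed with
round-trip precision so write∘read is the identity.

Cleaning order is fixed: heart-rate anomaly removal first, then
resampling. A heart-rate value is anomalous when it exceeds the
age-predicted maximum `220 − age`; equality is retained, since a maximum
denotes an attainable value. Anomalous values are masked and linearly
re-interpolated from surrounding valid readings rather than deleting the
whole row: the artefact is single-channel, and deleting rows would
fragment the motion stream that windowing depends on. The count of
replaced values is reported, so replaced + retained always equals the
input sample count. Resampling is per-channel linear interpolation onto a
uniform grid anchored at the first timestamp (heart rate re-rounded to
integer); linear interpolation is the simplest monotone method and the
stage's contract (uniform spacing, endpoint preservation, constants map to
constants) does not depend on anything fancier.

## Segmentation and features

Windows are 50 %-overlapped and phase-bounded: they restart at each phase
boundary so every window carries exactly one phase, which the per-phase
experiments require. Window length in samples is `floor(window_s × rate)`
(0.5 s at 25 Hz → 12 samples; the non-integer 12.5 is floored). A phase
shorter than one window yields a single truncated window instead of being
dropped, so every (participant, phase) pair contributes a record and the
78 × 14 grid stays rectangular.

Eight features per channel: mean, standard deviation (population, ddof 0),
Fisher–Pearson skewness and excess kurtosis (both biased-moment
estimators, both 0 by convention when the window is constant), max, min,
amplitude (max − min), and spectral energy — the sum of squared full
complex FFT magnitudes, DC included, divided by the window sample count.
By Parseval's identity this equals the plain time-domain sum of squares,
which the tests use as an independent oracle (relative tolerance 1e−9).
For truncated windows the normaliser is the actual sample count. Feature
names are `<channel>_<statistic>`, channel-major, and this order is frozen
because elimination traces reference features by name.

The analysis unit defaults to the *phase record*: the window-level vectors
of each (session, phase) are averaged, giving n_sessions × 14 rows (1092
for the default cohort). Window-level records are an explicit option; the
package asserts nothing about which unit the original study fed its
models. Phase packing (the "packed shopping" design) replaces the eight
in-store phases by one record per session holding their unweighted mean.

## Synthetic cohorts

No dataset for the protocol is public, so the generator is first-class,
tested code that defines the study conditions the rest of the package is
validated under.

* **Composition** — 12 frail / 47 pre-frail / 19 non-frail participants,
  ages uniform 65–90, sex drawn with the study's ~87 % female proportion,
  supermarket distance 50 m (two centres in three) or 100 m, 25 Hz.
* **Heart rate** — per class: a resting mean (frail 78 bpm, non-frail
  92 bpm; both sides of the 88 bpm boundary that separates the classes'
  session means), a between-participant baseline spread (5 / 3 bpm) and a
  within-session AR(1) wander (9 / 3.5 bpm) — frail participants wander
  over a visibly wider band. Pre-frail is the midpoint mixture (85 bpm),
  a neutral choice consistent with an ordered phenotype. Activity raises
  heart rate by 8 bpm in walking phases and 5 bpm in shopping phases.
  Values are clipped to [40, 220] and rounded to integers.
* **Motion** — walking phases carry a sinusoidal gait component with
  class-dependent cadence (1.5 / 1.75 / 2.0 Hz) and amplitude
  (1.0 / 1.5 / 2.0 device units, gyroscope at half amplitude); shopping
  phases attenuate the gait to 60 % and add sporadic reaching bursts on
  the gyroscope; sitting/standing phases are white noise (σ 0.3) around
  the gravity baseline on the vertical axis. No motion summary statistics
  were reported for the original cohort, so these are conventions chosen
  for qualitative plausibility, not facts about real frail gait.
* **Phase durations** — lognormal (σ 0.15) around per-phase medians
  (8–40 s); the two walking legs take `distance / gait speed` with
  class-dependent speed (0.7 / 0.95 / 1.2 m/s). A typical session is
  ~5 minutes (~8000 samples).
* **Separation knob** — one scalar rescales every class-conditional mean
  (heart rate, amplitude, cadence, gait speed) about its grand mean:
  0 collapses the classes, 1 is the default calibration, 2 is "high".
  Downstream cross-validated accuracy increases monotonically in it
  (tested at 0.25 / 1 / 2.5).
* **Anomaly injection** — off by default; a configurable per-sample rate
  inserts values above `220 − age` so the cleaning stage can be exercised.
* **Seeding** — one root seed; `numpy.random.SeedSequence` spawns one
  child per participant, so cohorts are byte-identical across runs and
  individual sessions are independently reproducible.

What the generator does **not** emulate: real gait biomechanics, sensor
drift and dropouts, posture transitions, cognitive/social correlates of
the in-store phases, or heart-rate kinetics (on/off transients). Passing
tests therefore demonstrate that the pipeline's mechanics are correct and
that it recovers planted class structure — not that the classifier
accuracies transfer to real cohorts.

## Selection, models, evaluation

Feature ranking is the impurity-decrease importance of a 500-tree random
forest with a fixed seed; ties keep column order. Elimination evaluates
every size from 56 down to 1, removing exactly the lowest-ranked survivor
and re-ranking after each removal. The same stratified folds are reused at
every size so the trace is comparable across sizes; the best size
maximises macro-F1 (accuracy and the other metrics are selectable) with
ties broken toward fewer features. Hyperparameters are re-tuned per subset
size by default; a frozen specification can be passed instead, and the
orchestrated pipeline freezes the grid winner of the full feature set —
at 56 subset sizes a full re-search per size adds nothing at the problem
sizes this package targets.

Classifiers: scikit-learn k-NN, SVC (one-vs-one multiclass; kernel names
radial/polynomial/linear/sigmoid; gamma ignored for linear) and random
forest (variables-per-split clamped to the current feature count), plus a
purpose-built per-feature naive Bayes whose class-conditional likelihood
is Poisson for non-negative integer-valued features when requested,
a Gaussian KDE when `use_kernel` is set, and a Gaussian otherwise — the
plain variant agrees with `GaussianNB`. k-NN and SVM see z-standardised
features with the scaler fitted inside each training fold only; RF and NB
consume raw features. The k-NN grid reads "odd k up to the square root of
the row count": a grid up to n² would be meaningless.

Folds are stratified at record level with a seeded per-class shuffle and
round-robin distribution of remainders; `k = n` degenerates to
leave-one-out (stratification is vacuous there), and an optional
participant-grouped assignment is not provided because the record-level
procedure is the one being replicated — note that record-level folds let a
participant's other phase records appear in training, which is precisely
why nearest-neighbour accuracy is high on both the original study's data
and these synthetic cohorts. Metrics come from one-vs-rest confusion
counts; overall sensitivity/specificity/F1 are macro averages (the
aggregation is labelled in output since single reported numbers for a
3-class problem are ambiguous), accuracy is trace/total, and zero
denominators yield 0 with a flag.

## Numerical and degenerate-input conventions

* Constant windows: sd = skewness = kurtosis = 0.
* Length-1 windows: same conventions; energy = x².
* Empty phases are an assembly error naming session and phase; empty
  sessions are valid on disk but excluded from matrices.
* All CSV floats round-trip exactly (`%.17g` out, round-trip parse in).
* Every stochastic routine takes an explicit seed; nothing reads global
  RNG state.

## Problem sizes

Tests and the acceptance script run cohorts of 7–78 sessions at 25 Hz
(~0.6 s to generate and ~3 s to featurise the full 78-session cohort),
elimination traces on 56-feature matrices of 98–1092 records, and
20-permutation nulls; these sizes make every stage's contract observable
while keeping a full run in the minutes range on one CPU.

## Known limitations

* Phase-level 1-NN accuracy saturates below 1.0 even at high separation:
  in the four static phases the 48 motion features are uninformative noise
  that dilutes the heart-rate signal in the standardised distance. This is
  a property of the analysis design, not a bug; the elimination stage
  exists precisely to discard such features.
* The pre-frail signal model is an interpolation, not an empirical fit.
* `use_poisson` naive Bayes only ever applies to the heart-rate-derived
  integer features in practice.
* The packed-shopping record inherits the unweighted mean convention even
  though in-store phases differ greatly in duration.
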