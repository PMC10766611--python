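# Methods

## Problem and model

`glycocast` predicts the clinical control class that a pediatric type-1
diabetes patient's HbA1c will fall into, from 14 days of continuous glucose
monitoring (CGM) data sampled every 15 minutes (96 readings/day, 1344 per
window). HbA1c reflects average blood glucose over roughly 90–120 days, so a
short CGM window carries a noisy but real signal about the future laboratory
value. Rather than regressing the continuous HbA1c, the task is posed as
ordinal classification over clinically motivated ranges: a four-class scheme
(≤7.5, 7.5–9, 9–12.5, >12.5 %) and a finer six-class scheme (≤6.5, 6.5–7.5,
7.5–8.25, 8.25–9, 9–10.5, >10.5 %). Boundaries are lower-exclusive /
upper-inclusive. Note the six-class partition does *not* strictly refine the
four-class one: the open-ended >10.5 range straddles the four-class boundary
at 12.5.

The classifier is a metric-learning architecture:

1. **Imputation.** A reading lives on a day × time-of-day grid and is
   correlated with its temporal neighbors and with readings at the same
   clock time on adjacent days. A single affine layer (8 inputs → 1 output,
   identity activation) is trained by gradient descent on standardized
   glucose to predict each reading from its 8 grid neighbors, using only
   samples whose 8 neighbors are present. Missing cells are filled in
   Jacobi-style rounds (all currently fillable cells at once, from the
   previous round's grid, so the result is order-independent); cells the
   rule can never reach (grid edges, long removal gaps) fall back to linear
   interpolation along time with end-fill. One model is fit per cohort, not
   per patient.
2. **Hand-crafted (DSP) features**, 17 per patient: three
   glucose-metabolising-capacity features `GMC^k` for k ∈ {1, 1.5, 2}, where
   `GMC_i = (BG_i − k·BG_{i+1}) / h^k` with h = 0.25 h the sampling step and
   the scalar feature is the mean of |GMC_i|; four time-in-range fractions
   (300–350, 70–180, 250–300, 180–250 mg/dL, bounds inclusive); the
   coefficient of variability σ/x̄ (population σ); integrated Welch spectral
   power (Hann window, 256-sample segments, 50 % overlap, mean removed; the
   full-band integral approximates the variance by Parseval); the low
   blood-glucose risk index LBGI = mean over readings of 10·g(x)² restricted
   to g(x) < 0, with g(x) = 1.509·((ln x)^1.084 − 5.381) (neutral point
   ≈ 112.9 mg/dL; a piecewise definition written directly on the squared
   risk would be vacuous since a square is never negative, so the standard
   inner-term sign split is used and both sides are exposed); three Haar
   wavelet detail
   powers from an orthonormal (periodized) 3-level cascade; and the
   across-day mean readings at 10 AM, 8 PM, 9 AM and midnight.
3. **Image encodings.** (a) A 24 × 1344 *binary trace image*: 24 contiguous
   20 mg/dL bins spanning [40, 520) on the rows (the printed 40–500 range in
   20-unit steps is reconciled with its stated 24-interval count by
   extending the top edge; out-of-range readings clamp), one one-hot column
   per reading. (b) A 20 × 14 *histogram image*: per day, counts over 20
   equal-width bins between that day's min and max (day max counted in the
   last bin; a flat day degenerates to bin 0), normalized by the global
   maximum. Before the CNN, binary images are width-reduced by
   non-overlapping column max-pooling with factor 4 (24 × 336), which
   preserves the trace envelope; histogram images pass through.
4. **Few-shot feature extraction.** Per image channel, a Siamese
   "separator": two identical 4-layer CNNs with shared weights
   (16/32/64/128 channels, 3×3 kernels, ReLU, 2×2 max-pool after the first
   three stages, adaptive average-pool to 4×8 after the last), a fully
   connected layer to a 4096-dim ReLU feature space, and a head that maps
   |f₁ − f₂| through one affine unit and a sigmoid. Pairs are sampled
   balanced (half same-class, half different-class, no self-pairs); the
   target is 0 for same-class and 1 for different-class pairs; the loss is
   binary cross-entropy, minimized with Adam. Both branch inputs are stacked
   into one forward pass, so weight sharing is structural rather than
   enforced. After training, the CNN alone is the feature extractor.
5. **Fusion and the FSLD distance.** Per patient, the binary features B
   (4096), histogram features H (4096) and standardized DSP features D (17)
   are concatenated into I (8209 elements; D is standardized with
   training-set statistics so clinical-scale features are commensurate with
   ReLU activations). For a pair (I₁, I₂) the element-wise FSLD transform is
   0 where |i₁ − i₂| ≤ a and |i₁ − i₂| / max(|i₁|, |i₂|) otherwise
   (a = 0.01 by default); a one-layer logistic model on the transformed
   vector J is trained on all (budgeted) training pairs toward 0 for
   same-class and 1 for different-class, giving a learned pseudo-distance in
   (0, 1). The target convention (small = same class) is the package's fixed
   choice and is recorded in the model manifest.
6. **Classification.** A query is assigned the majority class among the
   K = 10 gallery patients (the training set) with smallest learned
   distance; distance ties at rank K resolve by stable gallery order, vote
   ties uniformly at random under the run's seed.

Evaluation follows patient-level splits only (a patient is never in both
gallery and test side): stratified K-fold with full retraining per fold, or
repeated stratified 80/20 holdout. Accuracy is 100 × correct / total, and a
7-row channel ablation (every non-empty subset of {binary, histogram, DSP},
with the distance model retrained per subset and fused length 4096 / 4113 /
8192 / 8209 accordingly) mirrors the architecture's channel structure.

## Synthetic cohort generator

Clinical pediatric CGM cohorts with linked laboratory HbA1c are access-
restricted, so the package ships a generator that reproduces the statistical
structure the method assumes, and all tests and acceptance runs operate on
it.

Each patient draws an HbA1c uniformly inside their class range (support
[5, 15] %). The trace is: baseline mean glucose from the ADAG linear map
(28.7 × HbA1c − 46.7 mg/dL); three Gaussian-shaped meal excursions per day
(default 60 mg/dL peak, 40 min width, centered 08:00 / 13:00 / 19:00 with
±45 min daily jitter), centered to zero mean within each day so the 24-hour
average stays on the ADAG line (postprandial peaks in real traces are
balanced by lower fasting levels — HbA1c reflects the mean by definition);
and AR(1) noise with 15-minute lag-1 correlation 0.8 whose innovation SD is
8 + 4·max(0, HbA1c − 6) mg/dL, so glycemic variability grows with poorer
control, which is what makes CV and the risk indices informative. Values
clip to the sensor-plausible [40, 500] mg/dL. Missingness is injected as
random single slots (a rate, rounded to a count) plus contiguous blocks
(sensor removal), with the injected mask returned so recovery error is
measurable.

What the generator does *not* emulate: insulin–glucose physiology,
meal-size variation, exercise, sensor calibration drift, circadian
differences between weekdays and weekends, or the heavy-tailed missingness
of real wear patterns. Class-conditional mean glucose is strictly increasing
by construction, so passing end-to-end tests demonstrates that the
architecture recovers a signal of this kind — not that it attains any
particular accuracy on clinical data.

## Numerical and design choices

- **One-layer models** (imputer, distance) are affine maps trained by
  full-batch gradient descent / Adam on standardized inputs; divergence
  (non-finite loss) raises rather than silently degrading.
- **Determinism.** All randomness flows from one root seed through
  `numpy.random.SeedSequence` spawning; CNN training runs in float32 on a
  single CPU thread and is bit-reproducible, which the test suite asserts by
  comparing whole evaluation reports.
- **Timestamp snapping** on CSV input: nearest grid slot (tolerance half the
  15-minute step); duplicate readings in one slot are averaged; glucose
  outside (0, 600] mg/dL is rejected with a warning count.
- **Degenerate inputs:** constant cohorts make the glucose SD zero, in which
  case standardization degenerates to centering; a flat histogram day puts
  all mass in bin 0; FSLD at max(|i₁|,|i₂|) = 0 returns 0.
- **KNN tie-breaks** are the only randomness at prediction time and are
  seeded per query.
- **Pair budgets.** "All possible pairs" is quadratic in patients; above a
  configurable budget (default 50 000) a seeded balanced subsample is used.

## Problem sizes of the shipped evaluation profile

The default test/acceptance runs use the `desk_scale` profile: cohorts of 10
patients per class (four-class scheme, 40 patients), separator training with
3 epochs over 96 balanced pairs (batch 16, Adam 10⁻³), 40-epoch distance
training, and 5 repetitions of a stratified 80/20 holdout. On these
conditions the pipeline reaches well above twice chance accuracy, and a
shuffled-label cohort stays inside the binomial 95 % interval around chance,
which guards against information leaking from gallery construction or
imputer/standardizer fitting. Larger cohorts and longer training only help;
the profile is chosen so a full evaluation completes in minutes on one CPU
core.

## Known limitations

- The CNN stack is a compact CPU implementation in numpy; it is intentionally
  small (no augmentation, no regularization beyond early stopping by epoch
  count) and not tuned for large images or GPU-scale throughput.
- Accuracy figures on synthetic cohorts say nothing quantitative about
  clinical data; performance on real cohorts must be established on real
  cohorts.
- The imputer is a single cohort-level linear model; it cannot express
  nonlinear daily shape changes and long gaps degrade to linear
  interpolation.
- No probability calibration: the KNN vote is a hard decision.
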