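# Methods

`myobench` benchmarks nine pattern-recognition algorithms for myoelectric
control — offline and in a simulated real-time "motion test" — on synthetic
surface EMG (sEMG).  This note documents the generative model, the
processing pipeline, the classifier realizations, the statistics, and the
design decisions taken where the procedure admitted more than one
reasonable formulation.

## Recording protocol and data model

The emulated protocol records ten hand/wrist movements (open/close hand,
flex/extend hand, pronation/supination, side grip, fine grip, agree,
pointer) on 4 bipolar channels at 1000 Hz.  Each movement is held for 3 s
followed by 3 s of relaxation, three times, giving 18 s of data per motion
and a 180 s session.  Sample indexing is 0-based with half-open segments
`[start, end)`.  Relaxation periods carry the explicit label `rest` and are
trained as an eleventh class by default (`include_rest_class`), so the
real-time stage has a native way to stay quiet between contractions.

Sessions are stored as float32 multichannel WAV or headerless CSV with a
JSON sidecar (`fs`, `channels`, `schedule`, `metadata`).  Signal units are
arbitrary: every feature in the pipeline is either scale-invariant (ZC, SSC
with zero thresholds) or homogeneous of degree one (MAV, WL), and each
classifier sees normalized features or fits scale parameters itself.

## Synthetic EMG model

During isometric contraction, the interference pattern of many motor-unit
action-potential trains is well approximated by amplitude-modulated,
band-limited Gaussian noise; this is the standard surrogate for
feature-level analyses, and it reproduces exactly the statistics the
Hudgins features measure (per-channel amplitude and gross frequency
content).  Per sample `t`, channel `c`, movement `m`:

    x[t,c] = e(t) * A[m,c] * mvc_scale * g[t,c]
             + rest_noise_sd * n[t,c]
             + powerline_amp * sin(2*pi*50*t + phi_c)

with `g`, `n` independent unit-variance Gaussian processes filtered to
20–500 Hz (4th-order Butterworth, forward–backward), `e(t)` a trapezoidal
envelope with 0.25 s ramps (0 during rest), and `phi_c` a per-channel
phase.  Channels are mutually independent; cross-talk mixing is not
modelled.  Everything is deterministic given the seed.

Since the upper band edge (500 Hz) coincides with the Nyquist frequency at
fs = 1000 Hz, the band-pass degenerates to a 20 Hz high-pass — the sampled
process carries no power above Nyquist anyway, mirroring hardware whose
anti-aliasing low-pass sits at fs/2.

The activation matrix `A` (per-movement, per-channel amplitude in [0, 1])
emulates distinct muscle-synergy patterns.  Auto-generated rows are
`0.5 + 0.125 * min(separability, 4) * U` with `U ~ Uniform(-1, 1)` fixed by
the seed, so all rows coincide at separability 0, the mean pairwise row
distance grows proportionally with separability (saturating at 4, where
entries reach the [0, 1] bounds), and no clipping ever distorts the
geometry.  Default parameters: `separability = 1`, `rest_noise_sd = 0.02`,
`mvc_scale = 1`, `powerline_amp = 0` (set it positive to emulate residual
power-line interference).

**What the generator does not emulate.**  Real sEMG is non-stationary:
electrode lift-off and shift, fatigue, posture changes, and
repetition-to-repetition variability in how a contraction is performed.
The surrogate holds each movement's channel amplitudes constant across the
session.  Consequences for interpreting results are discussed under
*Known limitations*.

The real-time stream generator produces rest-only signal until
`cue_time_s + reaction_delay_s`, then a ramped sustained contraction of the
cued movement.  Virtual-subject defaults: 1.0 s pre-cue rest, 0.3 s
reaction delay.  These have no experimental reference values; they exist
because any simulation needs them, and they are configuration, not claims.

## Segmentation and features

Each 3 s contraction is trimmed by 15% per side (`floor(n * fraction)`
samples), keeping the central 70% so that some transient activity is
preserved; rest segments are windowed untrimmed.  Windows are 200 ms with
50 ms increments, never straddling a segment boundary (labels must be
unambiguous per window); window `i` covers `[i*inc, i*inc + win)` and its
timestamp is the window-end time.  A 2100-sample trimmed contraction gives
39 windows; a 3 s rest segment gives 57.

Per channel and window, the Hudgins time-domain set:

- **MAV** `= mean(|x|)`
- **ZC**: number of sign changes; `sign(0)` inherits the previous nonzero
  sign; a change counts only if the amplitude step reaches the dead-zone
  threshold (default 0 — the synthetic signal has no DC offsets, so a
  dead-zone would only discard information; real recordings may want one)
- **SSC**: interior samples where `(x_k - x_{k-1}) * (x_k - x_{k+1}) > 0`
  and the larger adjacent step reaches the threshold (default 0)
- **WL** `= sum(|diff(x)|)`

Features are channel-major (`ch1:(MAV,ZC,SSC,WL), ch2:(...)`), 16-D for
four channels.

## Normalization

Classifier-specific, fitted on training rows only, never clipped on
test data (clipping would silently distort KNN distances):

| scheme      | formula                                   | used by        |
|-------------|-------------------------------------------|----------------|
| `midrange2` | `2(x - (max+min)/2)/(max-min)` → [-1, 1]  | MLP, SVM, NMF  |
| `unitary`   | `(x - min)/(max - min)` → [0, 1]          | RFN            |
| `normlog`   | `log1p(x - min)/log1p(max - min)` → [0, 1]| SSOM, KNN      |
| `none`      | identity                                  | LDA, MLE, DT   |

"Norm-log" admits several formulations; the shift-log-rescale form above
is adopted because it guarantees a non-negative argument on training data
and maps the training extremes to exactly 0 and 1.  Test values below the
training minimum use the signed-log extension `-log1p(min - x)/...` so the
transform stays defined and strictly monotone under extrapolation (count
features such as ZC can legitimately fall below the training minimum).
Constant training columns are degenerate and map to 0.

## Classifiers

All nine are implemented in the package behind one train/predict contract;
scikit-learn appears only as an independent oracle in the test suite.  The
MLP consumes the validation rows for early stopping; all other classifiers
fit on training + validation rows.

- **MLP** — 16→16→16→C, logistic everywhere; per-sample backpropagation on
  squared error, learning rate 0.1, momentum 0.1, at most 200 epochs with
  seeded reshuffling; stops when validation misclassification fails to
  improve for 10 consecutive epochs, keeping the best-validation weights.
  Weight init uniform(-0.5, 0.5).  The output width equals the number of
  classes actually trained (11 with the rest class).
- **RFN** — regulatory feedback network.  Fitting stores the per-class mean
  of the unitary-normalized features; inference iterates the shunting
  fixed point `y_a <- (y_a/S_a) * sum_i w_ai x_i / f_i` with
  `f_i = sum_a y_a w_ai` (floored at 1e-9), T = 25 iterations from a
  uniform start.  Inputs are floored at 0 inside the classifier (the ratio
  form assumes non-negative drive).  With mutually orthogonal equal-support
  class patterns this reduces exactly to nearest-mean classification.
  Known property: the inference is ratio-based and therefore blind to
  patterns that differ only by an overall gain (collinear class means);
  see limitations.
- **SSOM** — supervised self-organizing map, 8×8 rectangular grid, Gaussian
  neighborhood, stochastic training on `[features ; one-hot(label)]`
  (β = 1): 200 epochs, learning rate 0.5→0.01 and radius (max grid side)/2→1,
  both exponential decay; units initialized from seeded training samples.
  Prediction finds the best-matching unit on the feature part only and
  returns the argmax of its label part.
- **LDA** — one binary linear discriminant per unordered class pair (pooled
  two-class covariance, equal priors), majority vote; vote ties broken by
  summed signed margins, then lowest class index.
- **SVM** — soft-margin C = 1, polynomial kernel
  `(x·y/d + 1)^3`, one-vs-one with the same vote rule.  Each binary dual is
  solved by SMO with maximal-violating-pair selection (KKT gap < 1e-3).
- **KNN** — K = 1, Euclidean; distance ties go to the first training index.
- **MLE** — full-covariance Gaussian per class, equal priors, prediction by
  maximum log-likelihood.  Covariances with condition number above 1e10
  get a ridge of `1e-6 * trace/d` on the diagonal; a failing Cholesky
  escalates the ridge rather than crashing.
- **DT** — CART: binary axis-aligned splits minimizing Gini impurity, grown
  until pure or no informative split, min-leaf 1, no pruning; ties broken
  toward the lowest feature index and threshold.
- **NMF/NNLS** — training feature vectors form the basis columns; a query
  is decomposed by non-negative least squares (Lawson–Hanson) and labelled
  with the class of the largest coefficient (per-class coefficient sums
  available behind `per_class_sum`).  All cost is paid at prediction time,
  which is why this classifier is by far the slowest to test.

## Offline evaluation

Stratified random split per class: 40% train, 20% validation, 40% test
(rounded per class, remainder to test; classes need ≥ 3 windows).
Stratification keeps small classes represented in every set; an
unstratified mode exists behind a flag.  The procedure repeats ten times
by default with fresh permutations; accuracy is computed on test rows
only and confusion counts are pooled.  Overlapping windows from one
segment can land on both sides of a random split; this is a property of
window-level randomization itself and affects every classifier —
memorization-style classifiers (KNN-1, NNLS) benefit from it the most.
Training and per-prediction testing wall-clock times are recorded as
metadata only: they are hardware-dependent and carry no scientific claim.

## Motion test

Each of the ten movements is cued three times in seed-randomized order.
Predictions fire every 50 ms on the latest 200 ms of signal, starting when
the buffer first fills; timestamps are window-end times.  The trial ends
at the 20th correct prediction or at 10 s after cue onset (the timeout
clock starts at the cue, reading the time budget as a trial budget).
Scoring anchors at the first non-rest prediction:

- selection time = first correct − first non-rest
- completion time = 20th correct − first non-rest
- real-time accuracy = 20 / (number of events between anchor and 20th
  correct), as a percentage
- completed = the 20th correct arrived before timeout

Aggregation: completion rate over all trials; the other three metrics
average over completed trials only (they are undefined otherwise, which
biases them toward well-classified movements — inherent to the metric
definitions, not a bug).  Trials whose non-rest predictions never include
a correct one leave selection time undefined and are excluded from that
aggregate.

## Statistics

Per metric, classifiers are compared as a completely randomized design:
one-way fixed-effects ANOVA, then Duncan's multiple range test at
α = 0.05.  The critical range for a span of `p` ordered means is
`q(1-(1-α)^(p-1); p, df_within) * sqrt(MSE/n_h)` with `q` the
studentized-range quantile and `n_h` the harmonic mean group size
(exact in the balanced case; the harmonic-mean extension handles mildly
unbalanced groups, e.g. after dropping undefined metrics).  Maximal
non-significant runs of the ordered means share a letter; overlapping
runs produce multi-letter memberships ("ab").  A Shapiro–Wilk p-value on
pooled residuals is logged per metric as an informal normality check; no
formal gate is applied.

## Benchmark scale and reproducibility

The full benchmark (`RunConfig`) defaults to 15 synthetic subjects with
ten-fold offline cross-validation.  The acceptance script and the
pipeline-trend integration test run a reduced shape — 5 subjects, 3
cross-validation repetitions — chosen so a complete run finishes in a few
minutes on one CPU while per-classifier means remain stable to well under
a percentage point.  A master seed fans out to per-subject, per-classifier
and per-trial sub-seeds via `numpy.random.SeedSequence`, so any slice
reruns identically in isolation.

## Numerical choices

- Covariance ridge: `1e-6 * trace/d * I` when the condition number exceeds
  1e10, escalating ×10 on Cholesky failure.
- SMO: kernel precomputed per class pair, stop at KKT gap 1e-3, iteration
  cap 200k (never reached on the benchmark data).
- Vote ties (LDA, SVM): summed signed margins, then lowest class index;
  argmax everywhere takes the lowest index on exact ties.
- Split rounding: `round()` per class for train and validation counts,
  remainder to test (117 windows → 47/23/47).
- Trim: `floor(n * fraction)` samples per side, making window counts
  deterministic.
- Degenerate streams (no non-rest prediction, too few correct) produce
  incomplete trial records, never exceptions.

## Known limitations

- The generator's stationarity means window-level splits share information
  between train and test through overlapping windows and identically
  distributed repetitions.  Model-based and memorization-based classifiers
  are therefore closer in offline accuracy here than they are on real,
  non-stationary recordings, where nearest-neighbor methods degrade
  sharply; KNN-1 in particular looks stronger on this benchmark than it
  does on human data.  Real-time metrics are less affected (the transient
  ramp and rest-to-movement transitions are genuinely out-of-sample).
- RFN cannot separate classes whose mean patterns are collinear (inference
  is gain-invariant); with unitary-normalized Hudgins features this
  matters only for movements with proportional channel profiles.
- The virtual subject never adapts: no visual-feedback compensation, no
  fatigue, no co-contraction strategy changes, so completion rates run
  higher than with humans in the loop.
- Timing metrics depend on host hardware and are excluded from all
  statistical claims.
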