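# myobench

Offline and real-time evaluation of myoelectric pattern recognition for the
decoding of hand movements.

Surface EMG (sEMG) pattern recognition maps muscle activity recorded from
forearm electrodes to intended hand/wrist movements — the control principle
behind modern myoelectric prostheses.  Offline classification accuracy on
pre-recorded windows is the field's most common metric, but it correlates
poorly with how usable a decoder is in continuous real-time control.
`myobench` implements both sides of that comparison as one reproducible
pipeline, for researchers who want to benchmark classifiers under a
motion-test protocol without access to restricted human recordings:

- **synthetic sEMG**: amplitude-modulated, band-limited (20–500 Hz) Gaussian
  noise with movement-specific per-channel activation patterns; 10 movement
  classes + rest, 4 channels, 1000 Hz, 3 s contraction / 3 s rest × 3
  repetitions (18 s per motion)
- **Hudgins time-domain features** per 200 ms window (50 ms increments,
  contractions trimmed to their central 70%): mean absolute value (MAV),
  zero crossings (ZC), slope sign changes (SSC), waveform length (WL) —
  16 dimensions over 4 channels
- **nine classifiers** behind one train/predict contract, each with its
  preferred feature normalization: MLP, RFN (regulatory feedback network),
  SSOM (supervised self-organizing map), one-vs-one LDA, polynomial-kernel
  SVM, 1-NN, Gaussian maximum likelihood (MLE), CART decision tree, and
  NNLS classification over training-sample bases (NMF)
- **offline evaluation**: stratified 40/20/40 train/validation/test split,
  repeated ten times with fresh randomization
- **motion test**: a discrete-time simulator of real-time control — a cued
  movement must accumulate 20 correct predictions within 10 s, predictions
  every 50 ms; metrics are real-time accuracy (recall between the first
  non-rest and the 20th correct prediction), selection time, completion
  time, and completion rate
- **statistics**: one-way ANOVA with Duncan's multiple range test at
  p < 0.05, emitting the classic means ± SD table with significance letters

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
from myobench import (SyntheticConfig, generate_session, extract_features,
                      ClassifierSpec, cross_validate)

session = generate_session(SyntheticConfig(seed=1))   # one synthetic subject
features = extract_features(session)
print(f"{features.n_windows} windows x {features.X.shape[1]} features, "
      f"{len(features.classes)} classes")

for name in ("LDA", "MLE", "KNN"):
    result = cross_validate(ClassifierSpec(name=name, seed=0), features, reps=3, seed=0)
    print(f"{name}: offline accuracy {result.mean_accuracy_pct:.1f} "
          f"± {result.sd_accuracy_pct:.1f} %")
```

prints

```
2880 windows x 16 features, 11 classes
LDA: offline accuracy 96.6 ± 0.5 %
MLE: offline accuracy 96.2 ± 0.6 %
KNN: offline accuracy 94.2 ± 0.1 %
```

Each 3 s contraction yields 39 overlapping windows (×3 repetitions × 10
movements = 1170 movement windows) and each rest period 57, for 2880
labelled 16-D feature vectors; the accuracies are means over three
randomized 40/20/40 splits, evaluated on the held-out 40% only.

The same pipeline is available from the shell:

```sh
myobench simulate --subjects 2 --seed 1 --outdir sessions
myobench eval-offline --session sessions/subject00.wav --classifier LDA --reps 10 --seed 0
myobench motion-test --classifier LDA --subjects 1 --seed 0
myobench benchmark --subjects 5 --reps 3 --seed 1 --outdir bench_out
```

`benchmark` writes `per_subject.csv` (per-subject, per-classifier metrics)
and `summary.csv`/`summary.md` — the seven-column table (offline accuracy,
training time, testing time, real-time accuracy, selection time, completion
time, completion rate) with means ± SD and Duncan significance letters.

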