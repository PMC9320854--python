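# Methods

This note records the models, conventions and numerical choices behind
`beatstream`, and what the synthetic benchmarks do and do not demonstrate.

## Beat labels and record handling

Beats are mapped from MIT-BIH annotation symbols to the five AAMI classes:
N ← {N, L, R, e, j}, SVEB ← {A, a, J, S}, VEB ← {V, E}, F ← {F},
Q ← {/, f, Q}. Every other annotation code (rhythm changes, noise marks,
comments) is a non-beat: it is excluded from RR computation and labeling,
which is standard MIT-BIH practice. The four paced-rhythm records
(102, 104, 107, 217) are excluded from training data. The default channel
is the first channel of the record (lead MLII in MIT-BIH); the source lead
for the reference results is not documented anywhere we could pin down, so
the choice is configurable and recorded here as a decision rather than a
fact.

The WFDB reader/writer implements the subset of the format the pipeline
needs: text headers, signal formats 16 (int16) and 212 (packed 12-bit), and
the MIT binary annotation format (including SKIP/AUX handling on read).
Round-tripping a record preserves sample indices and symbols exactly and
amplitudes to one ADC step, which is the property the synthetic fixtures
rely on.

## R-peak detection

The detector is the classic Pan-Tompkins cascade with the canonical
constants: ~5–15 Hz band-pass, five-point derivative, squaring, 150 ms
moving-window integration, dual adaptive thresholds on the filtered and
integrated signals with 0.125/0.875 running signal/noise updates, a 200 ms
refractory period, T-wave discrimination (slope comparison) for candidates
within 360 ms of the previous beat, and search-back at half threshold when
no beat appears within 1.66× the running 8-beat average RR.

Two deliberate deviations from the original design:

* the band-pass is a zero-phase Butterworth filter rather than the original
  integer-coefficient filters designed for 200 Hz, making the detector
  sampling-rate-agnostic (all windows are specified in milliseconds);
* the adaptive thresholds never drop below 1% of the strongest integrated
  QRS energy in the record. Thresholds learned on a beat-free stretch
  otherwise collapse toward zero and accept numerical ripple; the floor
  corresponds to a 10:1 amplitude range between the strongest and weakest
  acceptable QRS, well beyond physiological variation within one lead.

Detected integration peaks are refined to the R fiducial as the maximum
absolute band-passed amplitude within ±100 ms, and the refractory period is
re-enforced on the refined positions.

Two RR-labeling modes exist for building training tables: pairing each
detected peak to the nearest reference annotation within ±150 ms (unpaired
detections dropped), and an annotation-driven mode that computes RR
directly from reference annotation positions. The annotation-driven mode
is the default for reproducing evaluation tables because it is
deterministic and label-exact.

## Features

Nine features per beat from the 42 most recent intervals *ending at and
including* the current interval RR₀, plus the lookahead RR₊₁. The window
is counted in intervals, not seconds. Conventions the definition leaves
open, fixed here and covered by tests:

* standard deviation is the population form (divide by n = 42);
* a degenerate window (zero spread) yields tRR₀ = 0;
* the window average is always the trailing-window mean, never a
  patient-wise mean — required for streaming, where the full recording is
  never available;
* one table row per beat with ≥ 41 preceding intervals and ≥ 1 following
  interval, so n intervals yield max(0, n − 42) rows, and the label of a
  row is the class of the beat closing RR₀.

Because of the lookahead, any streaming deployment of these features emits
each prediction one beat late; this is inherent to the feature set, not an
implementation artifact.

## Oversampling

ROS duplicates minority rows uniformly with replacement until all classes
match the majority count. SMOTE draws a minority sample x_i, one of its
k nearest same-class neighbors x_zi (Euclidean, on the nine features,
k = 5 by default, clamped to class size − 1 so classes as small as the
15-member unknown class remain usable), and a single λ ~ U(0,1) shared
across all nine coordinates — every synthetic point therefore lies on the
segment between its parents. ADASYN uses the same interpolation but makes
each minority point's budget proportional to the fraction of foreign-class
points among its k nearest neighbors in the full dataset; when all weights
are zero (no foreign neighbors anywhere) the budget falls back to uniform.
Real-valued budgets are apportioned to integers by largest remainder, which
keeps the class total on the majority count while preserving the density
weighting; reference implementations that round per point instead can
overshoot by up to a few percent, which is a presentation difference, not a
modeling one.

## Splits

The inter-patient protocol split fixes 22 training and 22 test records;
records outside both lists are dropped. The intra-patient split shuffles
rows uniformly and gives the training side floor(0.7·n) rows — the only
rounding consistent with 450,625 balanced rows splitting into 315,437 and
135,188. When oversampling is combined with the random split, the
historical procedure (`before_split`) balances the **whole** table first,
so oversampled copies of training beats appear in the test set; this is
what the reference row counts imply, and it inflates test scores. The
leakage-safe `train_only` stage is provided and recommended for any new
work. Random-split experiments support repeated runs, each re-seeding both
the resampler and the splitter.

## Classifiers

Hyperparameters are fixed: DT (unlimited depth, seed 42), GB (100
estimators, learning rate 0.1, depth 3, seed 0), k-NN (k = 3), MLP (one
hidden layer of 128, α = 1e-5, ≤ 600 iterations, seed 42), RF (30 trees,
seed 42), SVM (RBF, γ = 0.8, C = 1), and a deep dense network
9→64→128→512→128→64→5 with ReLU hidden layers, softmax output,
L2 regularization 1e-4, Adam, batch size 512 and an iteration cap of 200
(its epoch budget is not pinned by any reference, so the cap is a package
default and configurable). The deep net is a scikit-learn `MLPClassifier`
with those widths; its objective (cross-entropy with L2) and output
(softmax) match the stated design.

Scale-sensitive estimators (k-NN, MLP, SVM, deep net) are fit behind a
`StandardScaler`. The absolute RR features are on a hundreds-of-ms scale
while ratio features sit near 1; with γ = 0.8 an RBF kernel on raw features
degenerates (all pairwise kernels ≈ 0), so standardization is the only
reading under which the fixed kernel width is meaningful. Tree ensembles
are scale-free and take raw features. Trained models record the feature
order and enforce it at prediction time.

## Metrics

Accuracy is trace/total of the 5×5 confusion matrix (rows actual, columns
predicted, order N, SVEB, VEB, F, Q). Per-class precision TP/(TP+FP) and
recall TP/(TP+FN) use the zero-division → 0 convention; F1 is their
harmonic mean with 0 when both vanish. Summary values are
support-weighted: Σ support_c · metric_c / total. Support-weighted recall
is algebraically the accuracy, and the report asserts it. These exact
conventions — weighted averaging with zero-division → 0, not macro
averaging — are pinned down by the stored reference matrices: applying the
engine to them reproduces every published summary percentage to the printed
two decimals (half-up rounding, applied only at report time).

Two known inconsistencies in the reference tables are recorded here: the
RF-on-ROS matrix's N row sums to one beat fewer than the corresponding
split table (accuracy rounds to 99.67 either way), and the intra-patient RF
summary accuracy (96.22) reflects a five-run average while its printed
matrix yields 96.21 — the matrix-derived value is the one asserted.

## Streaming loop

The loop consumes an iterator of events (timestamp, RR ms, HR bpm; HR is
round(60000/RR)). It buffers 42 intervals without classifying — the
middleware contract is that classification starts only once 42 intervals
have been collected — then classifies every subsequent beat as soon as its
lookahead interval arrives. Hence predictions = max(0, events − 43), and
the prediction sequence equals the batch pipeline's predictions on the same
series minus its first row (the beat closed by the warm-up buffer itself).
A separate streaming extractor without the warm-up convention reproduces
the batch feature table row-for-row; both behaviors are tested. Latency is
measured from event receipt to prediction emission; a mean above 1 s — the
inter-arrival budget of a 1 Hz source — triggers a warning, not an error,
since wall-clock speed is hardware-dependent.

## Synthetic data

The generators exist so every pipeline stage has a ground-truth oracle.

`gen_ecg` sums Gaussian QRS templates (default 1 mV, 80 ms full width) at
the cumulative positions of an RR schedule and optionally adds white noise
at a stated SNR, returning the exact peak indices. It deliberately has no
P/T waves, baseline wander or muscle artifact: detector scores of ~1.0 on
it validate the implementation of the cascade, not clinical performance.
The only realistic stressors applied are additive noise (tested at 20 dB
SNR) and rate variation (40–180 bpm).

`gen_rr_dataset` emulates rhythm only. A per-subject mean RR is drawn in
[700, 1000] ms with 3% relative jitter (resting adult range); ectopic
events are placed at least three beats apart and encode the standard
timing signatures — premature interval then compensatory pause, with
factors (relative to the mean) of 0.70–0.80 / 1.15–1.25 for SVEB,
0.60–0.70 / 1.30–1.40 for VEB (more extreme, disjoint prematurity ranges),
0.82–0.90 / 1.05–1.12 for F, and erratic uniform 400–1600 ms intervals for
Q. The default class mix is 80% N and 5% of each abnormality; all
intervals are clipped to [200, 3000] ms. These archetypes are separable by
construction (except where Q's uniform range overlaps the normal band), so
the ≥ 95% end-to-end accuracy they support shows the pipeline's plumbing
and the classifiers' capacity — it does **not** transfer to real ECG, where
class overlap under patient separation is the dominant difficulty (compare
the stored inter-patient reference results at ~92.6%).

## Problem sizes

The default test and reproduction runs use 20,000-beat synthetic datasets
for the end-to-end pipeline, 4,000 beats for the all-classifier comparison,
60–120 s ECG segments for detector scoring, and a 20-minute emulated
session (~1,170 beats at 1,024 ms mean RR) for the streaming report. These
sizes give stable two-decimal metrics while keeping a full run to a couple
of minutes on one CPU.

## Known limitations

* No morphology: fusion and unknown beats are defined morphologically in
  clinical practice; an RR-only feature set cannot truly capture them, and
  the synthetic archetypes for F and Q are timing conventions, not
  physiology.
* The `before_split` oversampling stage reproduces the historical numbers
  but leaks; use `train_only` for honest estimates.
* The WFDB layer covers formats 16/212 and single-annotator beat files;
  multi-segment records and other signal formats are out of scope.
* Detector constants assume adult resting/ambulatory ECG; extreme
  bradycardia below 40 bpm lengthens the search-back horizon accordingly.
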