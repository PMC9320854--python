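# beatstream

Continuous heartbeat classification from RR intervals, built for real-time
monitoring with wearable heart-rate sensors.

## The problem

Chest-strap sensors (e.g. Polar H10) broadcast one message per second
containing the latest RR interval — the time in milliseconds between two
consecutive R-peaks of the ECG — and the heart rate. Unlike raw ECG, this
stream is available live, which makes RR-only classification the natural
basis for continuous, long-term monitoring outside the clinic. The question
is how far rhythm alone (no wave morphology) can carry automatic beat
classification into the five AAMI classes: normal (N), supraventricular
ectopic (SVEB), ventricular ectopic (VEB), fusion (F) and unknown (Q).

The package is aimed at biomedical-signal and ML practitioners who want a
complete, testable RR-interval pipeline: WFDB-dialect I/O for MIT-BIH-style
records, Pan-Tompkins R-peak detection, feature extraction, class
rebalancing, training/evaluation under both patient-separation paradigms,
and a streaming classification loop — plus synthetic generators so every
stage runs and is verified without external data.

## The method

For each beat, nine features are computed from a trailing window of the
**42** most recent RR intervals ending at the current interval RR₀, with a
one-interval lookahead RR₊₁:

| feature | definition |
|---|---|
| RR₀, RR₋₁, RR₊₁ | current, previous and next RR interval (ms) |
| RR₀/avgRR, RR₋₁/avgRR, RR₊₁/avgRR | normalization by the window mean avgRR |
| RR₋₁/RR₀, RR₊₁/RR₀ | beat-to-beat ratios |
| tRR₀ = (RR₀ − avgRR)/stdRR | z-score against the window (population std) |

The trailing window keeps the features computable in a stream; the RR₊₁
lookahead delays each prediction by exactly one beat. Premature
(ectopic) beats appear as RR₀/avgRR ≪ 1 followed by a compensatory pause
(RR₊₁/RR₀ > 1.3).

Because normal beats dominate any recording, the training table is
rebalanced by random oversampling (ROS), SMOTE or ADASYN; SMOTE/ADASYN
synthesize minority points by

```
x_new = x_i + λ (x_zi − x_i),   λ ~ U(0, 1),
```

with x_zi one of the k = 5 nearest same-class neighbors (ADASYN
additionally weights each x_i by the fraction of foreign-class points among
its neighbors). Seven classifiers are provided (decision tree, gradient
boosting, k-NN, MLP, random forest, RBF-SVM, and a deep 9→64→128→512→128→64→5
dense network) under two evaluation paradigms: the **inter-patient**
protocol split (22 training / 22 test records, disjoint patients) and the
**intra-patient** random 70/30 split. Evaluation reports the 5×5 confusion
matrix, accuracy = trace/total and support-weighted precision/recall/F1
(weighted recall ≡ accuracy).

## Worked example

```python
from beatstream.features import build_feature_table
from beatstream.metrics import confusion_matrix, evaluate
from beatstream.models import ModelSpec, predict, train
from beatstream.resampling import ResamplingSpec, random_oversample
from beatstream.splits import SplitSpec, random_split
from beatstream.synthetic import gen_rr_dataset

ds = gen_rr_dataset(n_beats=20_000, seed=1)          # labeled RR sequence
table = build_feature_table(ds.rr, ds.labels)        # 19,957 rows x 9 features
balanced = random_oversample(table, ResamplingSpec("ros", seed=1))
train_part, test_part = random_split(balanced, SplitSpec(seed=1))
model = train(ModelSpec("RF"), train_part)
pred = predict(model, test_part)
print(evaluate(confusion_matrix(test_part["label"].tolist(), list(pred))))
```

prints

```
accuracy 99.93%  precision 99.93%  recall 99.93%  f1 99.93%
      precision  recall     f1   support
N        1.0000  0.9964 0.9982 4736.0000
SVEB     1.0000  1.0000 1.0000 4831.0000
VEB      1.0000  1.0000 1.0000 4783.0000
F        1.0000  1.0000 1.0000 4890.0000
Q        0.9964  1.0000 0.9982 4706.0000
```

i.e. a 30-tree random forest separates the five rhythm archetypes almost
perfectly on the held-out 30% after oversampling; the residual confusions
are erratic "unknown" intervals that happen to fall in the normal range.
The `examples/` directory holds one short script per capability (detection,
features, oversampling, training, streaming, reference metrics), and the
`beatstream` CLI chains the same stages from a shell:

```bash
beatstream simulate --n-beats 2000 --seed 3 --out rr.csv
beatstream extract --rr-csv rr.csv --out feat.csv
beatstream resample --input feat.csv --method smote --out bal.csv
beatstream train --features bal.csv --method RF --out rf.joblib
beatstream stream --model rf.joblib --source rr.csv --duration 300
```

## Scope

Bluetooth transport, sensor pairing and signal-strength measurement are out
of scope: the streaming loop consumes any iterator of RR events, so a real
transport adapter can be slotted in without changing the loop. Training on
the actual MIT-BIH Arrhythmia Database requires downloading it from
PhysioNet into a local directory and pointing `beatstream.wfdb_io.read_record`
(or `beatstream detect`) at it; the repository itself ships no ECG data.
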