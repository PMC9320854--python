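"""Rebalance an imbalanced beat table with ROS, SMOTE and ADASYN.

Normal beats dominate any real recording; oversampling equalizes class
counts before training.  ROS duplicates rows; SMOTE/ADASYN interpolate new
points between same-class neighbors (x_new = x_i + lambda (x_zi - x_i)).
"""

from beatstream.features import build_feature_table
from beatstream.resampling import ResamplingSpec, resample
from beatstream.synthetic import gen_rr_dataset

ds = gen_rr_dataset(n_beats=5000, seed=3)
table = build_feature_table(ds.rr, ds.labels, "demo")
print("original:", table["label"].value_counts().to_dict())

for method in ("ros", "smote", "adasyn"):
    out = resample(table, ResamplingSpec(method, k_neighbors=5, seed=0))
    print(f"{method:7s}", out["label"].value_counts().to_dict())
print("-> every class is brought up to the majority count; originals are kept")
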