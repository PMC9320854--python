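"""Published MIT-BIH reference values used to cross-check the metric engine.

These are the reported per-class beat counts of the MIT-BIH Arrhythmia
Database feature table (after paced-record exclusion) and reference
confusion matrices for classifiers trained on it under the inter-patient
protocol split, the intra-patient random split, and the random split of
ROS-oversampled data.  They serve as fixed inputs: feeding each matrix to
:func:`beatstream.metrics.evaluate` must reproduce the corresponding
reported summary metrics, which pins down the averaging conventions
(support weighting, zero-division -> 0, trace/total accuracy, half-up
rounding).

Row/column order is the package's fixed class order (N, SVEB, VEB, F, Q);
rows are actual labels, columns are predictions.  Two matrices are
real-valued because they average five repeated runs.
"""

from __future__ import annotations

import numpy as np

from beatstream.metrics import ConfusionMatrix

__all__ = [
    "ORIGINAL_CLASS_COUNTS",
    "ADASYN_CLASS_COUNTS",
    "CM_SVM_PROTOCOL",
    "CM_NN_PROTOCOL",
    "CM_RF_RANDOM",
    "CM_ANN_RANDOM",
    "CM_RF_ROS",
    "CM_DT_ROS",
    "CM_ANN_ROS",
]

#: Original (imbalanced) class counts of the MIT-BIH feature table.
ORIGINAL_CLASS_COUNTS: dict[str, int] = {
    "N": 90_125,
    "SVEB": 2_781,
    "VEB": 7_009,
    "F": 803,
    "Q": 15,
}

#: Reported class counts after ADASYN (near, not exactly, the majority count).
ADASYN_CLASS_COUNTS: dict[str, int] = {
    "N": 90_125,
    "SVEB": 90_332,
    "VEB": 89_215,
    "F": 90_293,
    "Q": 90_120,
}

#: SVM, inter-patient protocol split.
CM_SVM_PROTOCOL = ConfusionMatrix(np.array([
    [43588, 49, 622, 0, 0],
    [1159, 79, 599, 0, 0],
    [808, 64, 2349, 0, 0],
    [385, 0, 3, 0, 0],
    [6, 1, 0, 0, 0],
]))

#: Single-hidden-layer neural network, inter-patient protocol split.
CM_NN_PROTOCOL = ConfusionMatrix(np.array([
    [43170, 199, 872, 18, 0],
    [789, 279, 768, 1, 0],
    [619, 55, 2535, 12, 0],
    [382, 0, 5, 1, 0],
    [6, 0, 1, 0, 0],
]))

#: Random forest, intra-patient random 70/30 split (original class balance).
CM_RF_RANDOM = ConfusionMatrix(np.array([
    [26734, 20, 206, 15, 0],
    [129, 594, 85, 0, 0],
    [420, 43, 1698, 3, 0],
    [211, 0, 6, 50, 0],
    [6, 0, 0, 0, 0],
]))

#: Deep net, intra-patient random split; mean of five repetitions.
CM_ANN_RANDOM = ConfusionMatrix(np.array([
    [26776.2, 28, 214.6, 15.2, 0],
    [112.8, 632.6, 88.6, 0, 0],
    [392.6, 44.6, 1663, 10.8, 0],
    [178, 0, 9.4, 46.6, 0],
    [5.75, 0.75, 0.5, 0, 0],
]))

#: Random forest trained on ROS-oversampled data, random split.
CM_RF_ROS = ConfusionMatrix(np.array([
    [26626, 32, 370, 44, 2],
    [0, 26900, 0, 0, 0],
    [0, 0, 27083, 0, 0],
    [0, 0, 0, 27049, 0],
    [0, 0, 0, 0, 27081],
]))

#: Decision tree trained on ROS-oversampled data, random split.
CM_DT_ROS = ConfusionMatrix(np.array([
    [26148, 141, 576, 205, 5],
    [0, 26900, 0, 0, 0],
    [0, 0, 27083, 0, 0],
    [0, 0, 0, 27049, 0],
    [0, 0, 0, 0, 27081],
]))

#: Deep net trained on ROS-oversampled data; mean of five repetitions.
CM_ANN_ROS = ConfusionMatrix(np.array([
    [24773.4, 255.8, 943.4, 1073.6, 27.8],
    [84.2, 26670.75, 146.5, 2.4, 0],
    [334.4, 123.8, 26277.75, 310.4, 0.4],
    [50, 0, 13.6, 26992, 0],
    [0, 0, 0, 0, 27082],
]))
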