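"""The seven reference classifiers over the nine RR features.

Six scikit-learn estimators — decision tree (DT), gradient boosting (GB),
k-nearest neighbors (KNN), a single-hidden-layer perceptron (MLP), random
forest (RF), RBF support vector machine (SVM) — plus a deep fully-connected
network (ANN) with hidden widths 64-128-512-128-64, ReLU activations, a
softmax output over the five AAMI classes, L2 weight regularization 1e-4
and the Adam optimizer, realized as a scikit-learn ``MLPClassifier``.

Scale-sensitive estimators (KNN, MLP, SVM, ANN) are fit behind a
standardization step: the absolute features are on a hundreds-of-ms scale
while ratio features sit near 1, and the fixed RBF width (gamma = 0.8) and
neural-net initializations presuppose unit-scale inputs.  Tree ensembles
are scale-free and take the raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from beatstream.features import FEATURE_COLUMNS
from beatstream.wfdb_io import AAMI_CLASSES

__all__ = ["METHODS", "ModelSpec", "TrainedModel", "make_estimator", "train", "predict"]

METHODS = ("DT", "GB", "KNN", "MLP", "RF", "SVM", "ANN")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier choice plus optional hyperparameter overrides.

    Defaults per method: GB 100 estimators / learning rate 0.1 / depth 3 /
    seed 0; KNN k=3; MLP one hidden layer of 128, alpha 1e-5, 600
    iterations, seed 42; RF 30 trees, seed 42; SVM RBF gamma 0.8, C 1;
    DT unlimited depth, seed 42; ANN as in the module docstring.
    """

    method: str = "RF"
    overrides: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method.upper() not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")


_DEFAULTS: dict[str, dict[str, Any]] = {
    "DT": {"random_state": 42},
    "GB": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3, "random_state": 0},
    "RF": {"n_estimators": 30, "random_state": 42},
    "KNN": {"n_neighbors": 3},
    "MLP": {
        "hidden_layer_sizes": (128,),
        "alpha": 1e-5,
        "solver": "adam",
        "max_iter": 600,
        "random_state": 42,
    },
    "SVM": {"kernel": "rbf", "gamma": 0.8, "C": 1.0},
    "ANN": {
        "hidden_layer_sizes": (64, 128, 512, 128, 64),
        "activation": "relu",
        "alpha": 1e-4,
        "solver": "adam",
        "batch_size": 512,
        "max_iter": 200,
        "random_state": 42,
    },
}

_CLASSES = {
    "DT": DecisionTreeClassifier,
    "GB": GradientBoostingClassifier,
    "RF": RandomForestClassifier,
    "KNN": KNeighborsClassifier,
    "MLP": MLPClassifier,
    "SVM": SVC,
    "ANN": MLPClassifier,
}

#: estimators whose geometry presupposes unit-scale inputs
_SCALED = {"KNN", "MLP", "SVM", "ANN"}


def make_estimator(spec: ModelSpec):
    """Instantiate the (possibly pipeline-wrapped) estimator for a spec.

    ``spec.overrides`` replace the method's defaults key-by-key.
    """
    m = spec.method.upper()
    params = dict(_DEFAULTS[m])
    params.update(spec.overrides)
    est = _CLASSES[m](**params)
    if m in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class TrainedModel:
    """A fitted estimator plus the metadata needed for safe prediction."""

    estimator: Any
    method: str
    feature_columns: tuple[str, ...]
    training_class_counts: dict[str, int]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        model = joblib.load(Path(path))
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def train(
    spec: ModelSpec, train_table: pd.DataFrame, allow_single_class: bool = False
) -> TrainedModel:
    """Fit the classifier for ``spec`` on a feature table.

    Training is deterministic for every seeded method.  A single-class
    table is rejected unless ``allow_single_class`` is set (useful only for
    degenerate smoke cases with neighborhood methods).
    """
    X = train_table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = train_table["label"].to_numpy()
    classes = pd.unique(y)
    if len(classes) < 2 and not allow_single_class:
        raise ValueError("training table contains a single class; nothing to discriminate")
    unknown = set(classes) - set(AAMI_CLASSES)
    if unknown:
        raise ValueError(f"labels outside the AAMI classes: {sorted(unknown)}")
    est = make_estimator(spec)
    est.fit(X, y)
    counts = pd.Series(y).value_counts().to_dict()
    return TrainedModel(est, spec.method.upper(), tuple(FEATURE_COLUMNS), counts)


def _as_matrix(model: TrainedModel, features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.feature_columns if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        return features[list(model.feature_columns)].to_numpy(dtype=float)
    arr = np.asarray(features, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != len(model.feature_columns):
        raise ValueError(
            f"expected {len(model.feature_columns)} features, got {arr.shape[1]}"
        )
    return arr


def predict(model: TrainedModel, features) -> np.ndarray:
    """Predict AAMI class labels for a feature vector, matrix or table.

    Pure: repeated calls on the same model and input agree exactly.
    """
    return model.estimator.predict(_as_matrix(model, features))
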