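"""Class rebalancing for the beat feature table.

Three oversampling schemes equalize every class count to the majority
class: Random Oversampling (ROS) duplicates existing minority rows; SMOTE
synthesizes new points by linear interpolation between a minority sample
``x_i`` and one of its k nearest same-class neighbors ``x_zi``,

    x_new = x_i + lambda * (x_zi - x_i),    lambda ~ Uniform(0, 1);

ADASYN uses the same interpolation rule but allocates the per-sample
generation budget by local density — minority points with more
foreign-class neighbors (harder points) seed more synthetics.

All three operate on the nine-feature space with Euclidean neighbor
distances, preserve every original row, and are deterministic under a seed.
One lambda is drawn per synthetic sample and shared across all nine
coordinates, so every synthetic point lies on the segment between its two
parents (hence inside the minority class's axis-aligned bounding box).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from beatstream.features import FEATURE_COLUMNS

__all__ = ["ResamplingSpec", "random_oversample", "smote", "adasyn", "resample"]


class ResamplingError(ValueError):
    """A class cannot be oversampled (empty, or too small to interpolate)."""


@dataclass(frozen=True)
class ResamplingSpec:
    """Oversampling configuration: method, neighbor count, and seed.

    The target is always "equalize to the majority class count"; the
    effective k is clamped to (class size - 1) so very small classes
    remain usable.
    """

    method: str = "ros"
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method.lower() not in {"none", "ros", "smote", "adasyn"}:
            raise ValueError(f"unknown resampling method {self.method!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _class_counts(table: pd.DataFrame) -> pd.Series:
    if "label" not in table.columns or len(table) == 0:
        raise ResamplingError("feature table must be non-empty and carry a 'label' column")
    return table["label"].value_counts()


def _synthetic_frame(template: pd.DataFrame, x_new: np.ndarray, label: str) -> pd.DataFrame:
    frame = pd.DataFrame(x_new, columns=list(FEATURE_COLUMNS))
    frame["label"] = label
    # mirror any bookkeeping columns of the input table
    for col in template.columns:
        if col not in frame.columns:
            frame[col] = -1 if col == "beat_index" else "synthetic"
    return frame[list(template.columns)]


def random_oversample(table: pd.DataFrame, spec: ResamplingSpec | None = None) -> pd.DataFrame:
    """Duplicate minority rows uniformly with replacement until every class
    count equals the majority count.  Original rows are all retained."""
    spec = spec or ResamplingSpec("ros")
    counts = _class_counts(table)
    majority = int(counts.max())
    rng = np.random.default_rng(spec.seed)
    parts = [table]
    for label in counts.index:
        need = majority - int(counts[label])
        if need <= 0:
            continue
        pool = table.index[table["label"] == label].to_numpy()
        if pool.size == 0:
            raise ResamplingError(f"cannot oversample empty class {label!r}")
        picks = rng.choice(pool, size=need, replace=True)
        parts.append(table.loc[picks])
    return pd.concat(parts, ignore_index=True)


def _interpolate(
    X: np.ndarray,
    seeds: np.ndarray,
    neighbor_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized x_new = x_i + lambda (x_zi - x_i) for chosen seed rows."""
    zi = neighbor_idx[seeds, rng.integers(0, neighbor_idx.shape[1], size=seeds.size)]
    lam = rng.uniform(0.0, 1.0, size=seeds.size)[:, None]
    xi = X[seeds]
    return xi + lam * (X[zi] - xi)


def _same_class_neighbors(X: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn.kneighbors(X, return_distance=False)
    # drop each point itself (first column after ties are resolved by index)
    out = np.empty((X.shape[0], k), dtype=int)
    for r in range(X.shape[0]):
        row = [j for j in idx[r] if j != r][:k]
        while len(row) < k:  # duplicate coordinates can hide self-index
            row.append(row[-1])
        out[r] = row
    return out


def smote(table: pd.DataFrame, spec: ResamplingSpec | None = None) -> pd.DataFrame:
    """SMOTE: equalize every class to the majority count with interpolated
    synthetics.  Requires at least two rows in each minority class."""
    spec = spec or ResamplingSpec("smote")
    counts = _class_counts(table)
    majority = int(counts.max())
    rng = np.random.default_rng(spec.seed)
    parts = [table]
    for label in counts.index:
        need = majority - int(counts[label])
        if need <= 0:
            continue
        X = table.loc[table["label"] == label, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        if X.shape[0] < 2:
            raise ResamplingError(f"class {label!r} has fewer than 2 rows; cannot interpolate")
        k = min(spec.k_neighbors, X.shape[0] - 1)
        neighbors = _same_class_neighbors(X, k)
        seeds = rng.integers(0, X.shape[0], size=need)
        x_new = _interpolate(X, seeds, neighbors, rng)
        parts.append(_synthetic_frame(table, x_new, label))
    return pd.concat(parts, ignore_index=True)


def adasyn(table: pd.DataFrame, spec: ResamplingSpec | None = None) -> pd.DataFrame:
    """ADASYN: density-weighted SMOTE.

    Each minority point's budget is proportional to the fraction of
    foreign-class points among its k nearest neighbors in the *full*
    dataset; real-valued budgets are apportioned to integers by largest
    remainder so the class total lands on the majority count.  When every
    minority point sees only same-class neighbors the weights are all zero
    and the budget falls back to uniform.
    """
    spec = spec or ResamplingSpec("adasyn")
    counts = _class_counts(table)
    majority = int(counts.max())
    rng = np.random.default_rng(spec.seed)
    X_all = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y_all = table["label"].to_numpy()
    k_density = min(spec.k_neighbors, X_all.shape[0] - 1)
    nn_all = NearestNeighbors(n_neighbors=k_density + 1).fit(X_all)
    parts = [table]
    for label in counts.index:
        need = majority - int(counts[label])
        if need <= 0:
            continue
        mask = y_all == label
        X = X_all[mask]
        if X.shape[0] < 2:
            raise ResamplingError(f"class {label!r} has fewer than 2 rows; cannot interpolate")
        idx_all = nn_all.kneighbors(X, return_distance=False)
        weights = np.empty(X.shape[0])
        minority_rows = np.flatnonzero(mask)
        for r in range(X.shape[0]):
            neigh = [j for j in idx_all[r] if j != minority_rows[r]][:k_density]
            weights[r] = np.mean(y_all[neigh] != label) if neigh else 0.0
        total = weights.sum()
        if total == 0:
            budgets = np.full(X.shape[0], need / X.shape[0])
        else:
            budgets = weights / total * need
        # largest-remainder apportionment keeps the total on budget while the
        # per-point allocation stays proportional to the density weights
        g = np.floor(budgets).astype(int)
        short = need - int(g.sum())
        if short > 0:
            order = np.argsort(-(budgets - g))
            g[order[:short]] += 1
        k = min(spec.k_neighbors, X.shape[0] - 1)
        neighbors = _same_class_neighbors(X, k)
        seeds = np.repeat(np.arange(X.shape[0]), g)
        if seeds.size:
            x_new = _interpolate(X, seeds, neighbors, rng)
            parts.append(_synthetic_frame(table, x_new, label))
    return pd.concat(parts, ignore_index=True)


def resample(table: pd.DataFrame, spec: ResamplingSpec) -> pd.DataFrame:
    """Dispatch on ``spec.method`` (``none`` returns the table unchanged)."""
    method = spec.method.lower()
    if method == "none":
        return table
    return {"ros": random_oversample, "smote": smote, "adasyn": adasyn}[method](table, spec)
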