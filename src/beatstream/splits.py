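"""Train/test splitting under the inter-patient and intra-patient paradigms.

The inter-patient ("protocol") split assigns whole MIT-BIH records to train
or test, so no patient contributes beats to both sides — the clinically
realistic and harder setting.  The intra-patient ("random") split pools
beats across patients and shuffles them 70/30, which inflates apparent
accuracy.  When oversampling is combined with the random split, the
historical procedure oversamples the *whole* table before splitting
(``before_split``), which leaks synthetic copies of training beats into the
test set; a leakage-safe ``train_only`` stage is provided and recommended
for new work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from beatstream.resampling import ResamplingSpec, resample

__all__ = [
    "PROTOCOL_TRAIN_RECORDS",
    "PROTOCOL_TEST_RECORDS",
    "SplitSpec",
    "protocol_split",
    "random_split",
    "split_with_oversampling",
]

#: Inter-patient protocol: records whose beats form the training set.
PROTOCOL_TRAIN_RECORDS: tuple[str, ...] = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
)

#: Inter-patient protocol: records whose beats form the test set.
PROTOCOL_TEST_RECORDS: tuple[str, ...] = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)


@dataclass(frozen=True)
class SplitSpec:
    """Split configuration.

    ``oversample_stage`` controls where rebalancing happens relative to the
    split: ``none``, ``before_split`` (historical procedure; test rows are
    oversampled too) or ``train_only`` (leakage-safe).  ``repetitions`` is
    the number of independent random-split runs reported for the
    intra-patient paradigm.
    """

    mode: str = "random"
    train_fraction: float = 0.7
    seed: int = 0
    oversample_stage: str = "none"
    repetitions: int = 5

    def __post_init__(self) -> None:
        if self.mode not in {"protocol", "random"}:
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.oversample_stage not in {"none", "before_split", "train_only"}:
            raise ValueError(f"unknown oversample stage {self.oversample_stage!r}")


def protocol_split(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inter-patient split by the fixed 22/22 record lists.

    Rows from records outside either list (e.g. paced records) are
    excluded entirely.
    """
    rid = table["record_id"].astype(str)
    train = table[rid.isin(PROTOCOL_TRAIN_RECORDS)]
    test = table[rid.isin(PROTOCOL_TEST_RECORDS)]
    return train.reset_index(drop=True), test.reset_index(drop=True)


def random_split(
    table: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform row-level 70/30 shuffle split.

    The training side gets ``floor(train_fraction * n)`` rows — the rounding
    consistent with a 450,625-row oversampled table splitting into 315,437
    training and 135,188 test rows.  Deterministic under ``spec.seed``;
    train and test are disjoint and their union is the input.
    """
    spec = spec or SplitSpec()
    n = len(table)
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(np.floor(spec.train_fraction * n))
    train = table.iloc[order[:n_train]]
    test = table.iloc[order[n_train:]]
    return train.reset_index(drop=True), test.reset_index(drop=True)


def split_with_oversampling(
    table: pd.DataFrame,
    split_spec: SplitSpec,
    resampling_spec: ResamplingSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the configured oversampling stage around the configured split."""
    stage = split_spec.oversample_stage
    if stage != "none" and resampling_spec is None:
        raise ValueError("oversample stage requested but no resampling spec given")
    if stage == "before_split":
        table = resample(table, resampling_spec)
    if split_spec.mode == "protocol":
        train, test = protocol_split(table)
    else:
        train, test = random_split(table, split_spec)
    if stage == "train_only":
        train = resample(train, resampling_spec)
    return train, test
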