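import numpy as np
import pytest

from beatstream.features import build_feature_table
from beatstream.models import ModelSpec, train
from beatstream.splits import SplitSpec, random_split
from beatstream.synthetic import gen_rr_dataset


@pytest.fixture(scope="session")
def rr_dataset_small():
    """300-beat labeled synthetic RR dataset (all five classes present)."""
    return gen_rr_dataset(
        {"N": 0.76, "SVEB": 0.06, "VEB": 0.06, "F": 0.06, "Q": 0.06},
        n_beats=300,
        seed=2,
    )


@pytest.fixture(scope="session")
def feature_table_small(rr_dataset_small):
    return build_feature_table(rr_dataset_small.rr, rr_dataset_small.labels, "s0")


@pytest.fixture(scope="session")
def synthetic_split():
    """A 4000-beat dataset split 70/30 — shared across model smoke tests."""
    ds = gen_rr_dataset(n_beats=4000, seed=7, mean_rr_ms=850.0)
    table = build_feature_table(ds.rr, ds.labels, "s7")
    return random_split(table, SplitSpec(seed=7))


@pytest.fixture(scope="session")
def trained_rf(synthetic_split):
    train_table, _ = synthetic_split
    return train(ModelSpec("RF"), train_table)
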