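import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beatstream.features import (
    FEATURE_COLUMNS,
    WINDOW_SIZE,
    InsufficientHistoryError,
    RRWindow,
    StreamingExtractor,
    build_feature_table,
    extract_features,
)


def _oracle(window, lookahead):
    """Direct arithmetic on the 42 values (population std)."""
    w = np.asarray(window, dtype=float)
    rr0, rrm1, rrp1 = w[-1], w[-2], float(lookahead)
    avg, std = w.mean(), w.std()
    t = (rr0 - avg) / std if std > 0 else 0.0
    return np.array([rr0, rrm1, rrp1, rr0 / avg, t, rrm1 / avg, rrm1 / rr0, rrp1 / avg, rrp1 / rr0])


def test_constant_series_features():
    """43 equal intervals: absolute features 800, ratios 1, tRR0 forced to 0."""
    feats = extract_features(RRWindow(np.full(42, 800.0), 800.0))
    assert np.allclose(feats, [800, 800, 800, 1, 0, 1, 1, 1, 1])
    assert feats[FEATURE_COLUMNS.index("tRR0")] == 0.0


def test_premature_beat_features_match_direct_arithmetic():
    """41x800 ms then RR0=1000, lookahead 600: values from the arithmetic oracle."""
    window = np.concatenate([np.full(41, 800.0), [1000.0]])
    feats = extract_features(RRWindow(window, 600.0))
    assert np.allclose(feats, _oracle(window, 600.0))
    named = dict(zip(FEATURE_COLUMNS, feats))
    assert named["RR0_avg"] == pytest.approx(1.2426, abs=1e-4)
    assert named["RRm1_RR0"] == pytest.approx(0.8)
    assert named["RRp1_RR0"] == pytest.approx(0.6)
    assert named["RRp1_avg"] == pytest.approx(0.7456, abs=1e-4)
    assert named["tRR0"] == pytest.approx(6.40, abs=0.01)


@settings(derandomize=True, max_examples=50)
@given(
    scale=st.floats(min_value=0.5, max_value=4.0),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_ratio_features_scale_invariant(scale, seed):
    """Uniform time rescaling doubles absolute features, fixes ratios and tRR0."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(600.0, 1100.0, size=WINDOW_SIZE)
    look = float(rng.uniform(600.0, 1100.0))
    base = extract_features(RRWindow(w, look))
    scaled = extract_features(RRWindow(w * scale, look * scale))
    assert np.allclose(scaled[:3], base[:3] * scale)
    assert np.allclose(scaled[3:], base[3:], rtol=1e-9)


def test_window_contract_enforced():
    with pytest.raises(InsufficientHistoryError):
        RRWindow(np.full(41, 800.0), 800.0)
    with pytest.raises(InsufficientHistoryError):
        RRWindow(np.full(43, 800.0), 800.0)


@pytest.mark.parametrize("n_beats,expected_rows", [(44, 1), (43, 0), (10, 0), (1000, 957)])
def test_feature_table_row_counts(n_beats, expected_rows):
    n_intervals = n_beats - 1
    rng = np.random.default_rng(1)
    intervals = rng.uniform(700, 900, size=n_intervals)
    labels = ["N"] * n_intervals
    table = build_feature_table(intervals, labels, "r")
    assert len(table) == expected_rows
    # brute-force enumeration of positions with 41 predecessors and a successor
    brute = sum(1 for j in range(n_intervals) if j >= WINDOW_SIZE - 1 and j + 1 < n_intervals)
    assert len(table) == brute


def test_feature_table_labels_and_values_align():
    rng = np.random.default_rng(3)
    intervals = rng.uniform(700, 900, size=60)
    labels = [f"L{i}" if i == 45 else "N" for i in range(60)]
    labels = ["VEB" if i == 45 else "N" for i in range(60)]
    table = build_feature_table(intervals, labels, "r")
    row = table[table["label"] == "VEB"]
    assert len(row) == 1
    j = 45
    expected = _oracle(intervals[j - WINDOW_SIZE + 1 : j + 1], intervals[j + 1])
    assert np.allclose(row[list(FEATURE_COLUMNS)].to_numpy()[0], expected)
    assert int(row["beat_index"].iloc[0]) == j + 1


def test_per_beat_labels_accepted():
    intervals = np.full(50, 800.0)
    per_beat = ["N"] * 51  # one label per beat; beat i+1 closes interval i
    per_interval = ["N"] * 50
    a = build_feature_table(intervals, per_beat)
    b = build_feature_table(intervals, per_interval)
    assert a.equals(b)
    with pytest.raises(ValueError):
        build_feature_table(intervals, ["N"] * 48)


def test_streaming_extractor_reproduces_batch_row_for_row():
    rng = np.random.default_rng(9)
    intervals = rng.uniform(600, 1000, size=200)
    table = build_feature_table(intervals, ["N"] * 200)
    rows = list(StreamingExtractor().feed(intervals))
    assert len(rows) == len(table)
    positions = [j for j, _ in rows]
    assert positions == list(range(WINDOW_SIZE - 1, 199))
    feats = np.vstack([f for _, f in rows])
    assert np.allclose(feats, table[list(FEATURE_COLUMNS)].to_numpy())
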