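import numpy as np
import pytest

from beatstream.features import build_feature_table
from beatstream.models import predict
from beatstream.stream import WARMUP_EVENTS, StreamEvent, emulate_source, run_stream
from beatstream.synthetic import gen_rr_dataset


def test_event_heart_rates():
    events = list(emulate_source([1000.0, 1000.0, 800.0]))
    assert [e.hr_bpm for e in events] == [60, 60, 75]
    assert [e.timestamp for e in events] == pytest.approx([1.0, 2.0, 2.8])


def test_invalid_schedule_rejected():
    with pytest.raises(ValueError):
        list(emulate_source([]))
    with pytest.raises(ValueError):
        list(emulate_source([800.0, -5.0]))
    with pytest.raises(ValueError):
        StreamEvent(0.0, 0.0, 60)


def test_twenty_minute_session_event_count():
    """~1172 events fit in 1200 s at mean RR 1024 ms (cumulative-sum oracle)."""
    ds = gen_rr_dataset({"N": 1.0}, n_beats=1400, seed=6, mean_rr_ms=1024.0)
    events = list(emulate_source(ds.rr, duration_s=1200.0))
    expected = int(np.sum(np.cumsum(ds.rr.intervals_ms) / 1000.0 <= 1200.0))
    assert len(events) == expected
    assert 1130 <= len(events) <= 1210  # near 1200/1.024


@pytest.mark.parametrize("n_events,expected", [(41, 0), (42, 0), (43, 0), (44, 1), (45, 2), (100, 57)])
def test_prediction_count_is_events_minus_warmup(n_events, expected, trained_rf):
    """No prediction before 42 intervals are buffered plus one lookahead."""
    ds = gen_rr_dataset({"N": 1.0}, n_beats=200, seed=1)
    events = list(emulate_source(ds.rr.intervals_ms[:n_events]))
    report = run_stream(events, trained_rf)
    assert report.n_events == n_events
    assert report.total_beats == expected == max(0, n_events - WARMUP_EVENTS)


def test_stream_equals_batch_beat_for_beat(trained_rf):
    """Streaming predictions match the batch pipeline on the same RR series
    (the stream skips the first eligible beat: pure warm-up)."""
    ds = gen_rr_dataset(
        {"N": 0.8, "SVEB": 0.05, "VEB": 0.05, "F": 0.05, "Q": 0.05}, n_beats=400, seed=12
    )
    table = build_feature_table(ds.rr, ds.labels)
    batch = list(predict(trained_rf, table))
    report = run_stream(emulate_source(ds.rr), trained_rf)
    assert report.labels() == batch[1:]
    assert report.total_beats == len(table) - 1


def test_all_normal_stream_predicts_all_normal(trained_rf):
    ds = gen_rr_dataset({"N": 1.0}, n_beats=200, seed=3, mean_rr_ms=850.0)
    report = run_stream(emulate_source(ds.rr), trained_rf)
    assert report.total_beats == len(ds.labels) - WARMUP_EVENTS
    assert set(report.class_counts) == {"N"}
    # class counts sum to total predictions
    assert sum(report.class_counts.values()) == report.total_beats


def test_model_mismatch_fails_before_consuming(trained_rf):
    bad = type(trained_rf)(trained_rf.estimator, "RF", ("x", "y"), {})
    events = iter(list(emulate_source([800.0] * 50)))
    with pytest.raises(ValueError):
        run_stream(events, bad)
    assert next(events).rr_ms == 800.0  # nothing was consumed


def test_duration_cutoff_and_latency_logged(trained_rf):
    ds = gen_rr_dataset({"N": 1.0}, n_beats=300, seed=4, mean_rr_ms=800.0)
    report = run_stream(emulate_source(ds.rr), trained_rf, duration_s=60.0)
    assert report.n_events == int(np.sum(np.cumsum(ds.rr.intervals_ms) / 1000.0 <= 60.0))
    assert all(p.latency_s >= 0 for p in report.predictions)
    assert np.isfinite(report.mean_latency_s)


def test_jsonl_log_roundtrip(tmp_path, trained_rf):
    import json

    ds = gen_rr_dataset({"N": 1.0}, n_beats=60, seed=5)
    report = run_stream(emulate_source(ds.rr), trained_rf)
    out = tmp_path / "log.jsonl"
    report.write_jsonl(out)
    lines = [json.loads(l) for l in out.read_text().splitlines()]
    assert len(lines) == report.total_beats
    assert {"timestamp", "rr_ms", "hr_bpm", "features", "label", "latency_s"} <= set(lines[0])
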