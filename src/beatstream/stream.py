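"""Real-time per-beat classification of a 1 Hz RR-interval event stream.

Emulates the middleware of a wearable monitoring setup: a chest-strap
sensor broadcasts one event per second carrying the latest RR interval and
heart rate; the loop buffers intervals until 42 have been collected, then
classifies each subsequent beat from the nine trailing-window features and
logs the prediction with its processing latency.

Because the feature set includes the next interval (RR+1), each beat's
prediction is emitted one event after the beat itself — an inherent
one-beat lag of the feature definition.  With the 42-interval warm-up this
makes the number of predictions ``max(0, n_events - 43)``, and the
prediction sequence equals the batch pipeline's predictions on the same RR
series with the first eligible beat dropped (the warm-up intervals are
never classified themselves).

The event source is any iterable of :class:`StreamEvent`, so a Bluetooth
transport adapter can be slotted in without touching the loop.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from beatstream.features import FEATURE_COLUMNS, WINDOW_SIZE, StreamingExtractor
from beatstream.models import TrainedModel, predict
from beatstream.rpeak import RRSeries

__all__ = ["StreamEvent", "PredictionLog", "StreamReport", "emulate_source", "run_stream"]

#: Warm-up intervals plus the one-interval lookahead: events consumed before
#: the first prediction.
WARMUP_EVENTS = WINDOW_SIZE + 1


@dataclass(frozen=True)
class StreamEvent:
    """One 1 Hz sensor emission: RR interval (ms), heart rate (bpm), time (s)."""

    timestamp: float
    rr_ms: float
    hr_bpm: int

    def __post_init__(self) -> None:
        if self.rr_ms <= 0:
            raise ValueError("rr_ms must be positive")


@dataclass(frozen=True)
class PredictionLog:
    """One classified beat: when, its features, and how long processing took."""

    timestamp: float
    rr_ms: float
    hr_bpm: int
    features: np.ndarray
    label: str
    latency_s: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp,
                "rr_ms": self.rr_ms,
                "hr_bpm": self.hr_bpm,
                "features": dict(zip(FEATURE_COLUMNS, map(float, self.features))),
                "label": self.label,
                "latency_s": self.latency_s,
            }
        )


@dataclass
class StreamReport:
    """Outcome of a streaming session."""

    n_events: int
    predictions: list[PredictionLog] = field(default_factory=list)

    @property
    def total_beats(self) -> int:
        return len(self.predictions)

    @property
    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.predictions:
            out[p.label] = out.get(p.label, 0) + 1
        return out

    @property
    def mean_latency_s(self) -> float:
        if not self.predictions:
            return float("nan")
        return float(np.mean([p.latency_s for p in self.predictions]))

    def labels(self) -> list[str]:
        return [p.label for p in self.predictions]

    def write_jsonl(self, path: str | Path) -> None:
        Path(path).write_text("".join(p.to_json() + "\n" for p in self.predictions))


def emulate_source(
    rr_schedule: RRSeries | Sequence[float],
    duration_s: float | None = None,
    realtime: bool = False,
) -> Iterator[StreamEvent]:
    """Turn an RR schedule into the sensor's event stream.

    Events are emitted in order at the cumulative interval times;
    ``hr_bpm = round(60000 / rr_ms)``.  With ``duration_s`` the stream stops
    at the first event past that time (emulating a fixed-length session);
    with ``realtime`` the generator sleeps between events to pace emission,
    otherwise it runs as fast as the consumer pulls.
    """
    intervals = np.asarray(
        rr_schedule.intervals_ms if isinstance(rr_schedule, RRSeries) else rr_schedule,
        dtype=float,
    )
    if intervals.size == 0:
        raise ValueError("empty RR schedule")
    if np.any(intervals <= 0):
        raise ValueError("RR intervals must be positive")
    t = 0.0
    for rr in intervals:
        t += rr / 1000.0
        if duration_s is not None and t > duration_s:
            return
        if realtime:
            time.sleep(rr / 1000.0)
        yield StreamEvent(timestamp=t, rr_ms=float(rr), hr_bpm=int(round(60000.0 / rr)))


def run_stream(
    events: Iterable[StreamEvent],
    model: TrainedModel,
    duration_s: float | None = None,
    latency_warn_s: float = 1.0,
) -> StreamReport:
    """Consume an event stream and classify each beat once the buffer fills.

    The first :data:`WARMUP_EVENTS` intervals are buffered without
    classification; afterwards every arriving event closes the lookahead of
    the previous beat, which is featurized and predicted immediately.
    Processing latency is measured from event receipt to prediction
    emission; a mean above ``latency_warn_s`` is reported as a warning in
    the log, not an error.

    Raises ``ValueError`` before consuming any event if the model was not
    trained on the nine-feature layout.
    """
    if tuple(model.feature_columns) != tuple(FEATURE_COLUMNS):
        raise ValueError(
            f"model features {model.feature_columns} do not match the "
            f"streaming layout {FEATURE_COLUMNS}"
        )
    extractor = StreamingExtractor()
    report = StreamReport(n_events=0)
    skipped_first = False
    for event in events:
        if duration_s is not None and event.timestamp > duration_s:
            break
        report.n_events += 1
        t0 = time.perf_counter()
        row = extractor.push(event.rr_ms)
        if row is None:
            continue
        if not skipped_first:
            # the beat closed by the warm-up buffer itself is not classified:
            # classification starts only after 42 intervals have been collected
            skipped_first = True
            continue
        _, feats = row
        label = str(predict(model, feats)[0])
        latency = time.perf_counter() - t0
        report.predictions.append(
            PredictionLog(
                timestamp=event.timestamp,
                rr_ms=event.rr_ms,
                hr_bpm=event.hr_bpm,
                features=feats,
                label=label,
                latency_s=latency,
            )
        )
    if report.predictions and report.mean_latency_s > latency_warn_s:
        import warnings

        warnings.warn(
            f"mean per-beat processing time {report.mean_latency_s:.3f} s exceeds "
            f"{latency_warn_s:.1f} s; predictions lag the sensor",
            RuntimeWarning,
            stacklevel=2,
        )
    return report
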