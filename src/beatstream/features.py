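"""Nine RR-interval series features over a trailing 42-interval window.

Each classified beat is described only by local rhythm: the current RR
interval (RR0, the interval the beat closes), its predecessor (RR-1), its
successor (RR+1), normalizations by the mean of the 42 most recent
intervals ending at and including RR0 (avgRR), beat-to-beat ratios, and a
z-score of RR0 against that window (tRR0).  The window is trailing so the
features are computable in a streaming setting from previously seen data
only — except for the one-interval lookahead RR+1, which delays every
prediction by a single beat.

The standard deviation is the population form (divide by n); a degenerate
window (zero spread) yields tRR0 = 0.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from beatstream.rpeak import RRSeries

__all__ = [
    "WINDOW_SIZE",
    "FEATURE_COLUMNS",
    "InsufficientHistoryError",
    "RRWindow",
    "extract_features",
    "build_feature_table",
    "StreamingExtractor",
]

#: Number of trailing RR intervals in the averaging window (including RR0).
WINDOW_SIZE = 42

#: Feature order used in every table, model and CSV export.
FEATURE_COLUMNS = (
    "RR0",
    "RRm1",
    "RRp1",
    "RR0_avg",
    "tRR0",
    "RRm1_avg",
    "RRm1_RR0",
    "RRp1_avg",
    "RRp1_RR0",
)


class InsufficientHistoryError(ValueError):
    """Raised when fewer than 42 trailing intervals or no lookahead exist."""


@dataclass(frozen=True)
class RRWindow:
    """The 42 most recent RR intervals ending at RR0, plus the next interval."""

    intervals_ms: np.ndarray
    lookahead_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals_ms", np.asarray(self.intervals_ms, dtype=float))
        if self.intervals_ms.size != WINDOW_SIZE:
            raise InsufficientHistoryError(
                f"window must hold exactly {WINDOW_SIZE} intervals, got {self.intervals_ms.size}"
            )
        if np.any(self.intervals_ms <= 0) or self.lookahead_ms <= 0:
            raise ValueError("RR intervals must be positive")

    @property
    def avg_rr_ms(self) -> float:
        return float(np.mean(self.intervals_ms))

    @property
    def std_rr_ms(self) -> float:
        return float(np.std(self.intervals_ms))  # population form


def extract_features(window: RRWindow) -> np.ndarray:
    """The nine-feature vector for the beat closing the last window interval.

    Order follows :data:`FEATURE_COLUMNS`.  Absolute features are in ms and
    scale with the rhythm; ratio features and tRR0 are dimensionless and
    invariant under uniform time rescaling.
    """
    w = window.intervals_ms
    rr0 = float(w[-1])
    rrm1 = float(w[-2])
    rrp1 = float(window.lookahead_ms)
    avg = window.avg_rr_ms
    std = window.std_rr_ms
    t_rr0 = (rr0 - avg) / std if std > 0 else 0.0
    return np.array(
        [rr0, rrm1, rrp1, rr0 / avg, t_rr0, rrm1 / avg, rrm1 / rr0, rrp1 / avg, rrp1 / rr0]
    )


def _interval_labels(labels: Sequence[str], n_intervals: int) -> Sequence[str]:
    # accept per-interval labels (class of the beat closing each interval) or
    # per-beat labels (one longer; beat i+1 closes interval i)
    if len(labels) == n_intervals:
        return labels
    if len(labels) == n_intervals + 1:
        return labels[1:]
    raise ValueError(
        f"labels length {len(labels)} matches neither the {n_intervals} intervals "
        f"nor the {n_intervals + 1} beats"
    )


def build_feature_table(
    rr: RRSeries | np.ndarray,
    labels: Sequence[str],
    record_id: str = "",
) -> pd.DataFrame:
    """Feature table with one row per beat having full history and lookahead.

    A row is emitted for every interval position with at least 41 preceding
    intervals and one following interval; the first 41 positions and the
    final one are skipped, so a series of ``n`` intervals yields
    ``max(0, n - 42)`` rows.  Each row carries ``record_id``, ``beat_index``
    (index of the beat closing RR0, counting the first beat as 0), the nine
    features, and the AAMI label of that beat.
    """
    intervals = np.asarray(rr.intervals_ms if isinstance(rr, RRSeries) else rr, dtype=float)
    n = intervals.size
    cols = ["record_id", "beat_index", *FEATURE_COLUMNS, "label"]
    if n < WINDOW_SIZE + 1:
        return pd.DataFrame(columns=cols)
    lab = _interval_labels(labels, n)

    windows = np.lib.stride_tricks.sliding_window_view(intervals, WINDOW_SIZE)
    # window k spans intervals [k, k + 41]; RR0 = interval k + 41
    w = windows[: n - WINDOW_SIZE]  # those with a lookahead interval
    j = np.arange(WINDOW_SIZE - 1, n - 1)  # RR0 positions
    rr0 = intervals[j]
    rrm1 = intervals[j - 1]
    rrp1 = intervals[j + 1]
    avg = w.mean(axis=1)
    std = w.std(axis=1)
    t_rr0 = np.where(std > 0, (rr0 - avg) / np.where(std > 0, std, 1.0), 0.0)
    frame = pd.DataFrame(
        {
            "record_id": record_id,
            "beat_index": j + 1,
            "RR0": rr0,
            "RRm1": rrm1,
            "RRp1": rrp1,
            "RR0_avg": rr0 / avg,
            "tRR0": t_rr0,
            "RRm1_avg": rrm1 / avg,
            "RRm1_RR0": rrm1 / rr0,
            "RRp1_avg": rrp1 / avg,
            "RRp1_RR0": rrp1 / rr0,
        }
    )
    frame["label"] = [lab[k] for k in j]
    return frame[cols]


class StreamingExtractor:
    """Incremental feature extraction, one RR interval at a time.

    Feeding a series interval-by-interval reproduces
    :func:`build_feature_table` row-for-row: after interval ``k`` (0-based)
    arrives, the beat closing interval ``k - 1`` can be classified (interval
    ``k`` is its lookahead), provided ``k - 1`` has 41 predecessors.
    """

    def __init__(self) -> None:
        # intervals seen so far, the newest WINDOW_SIZE of them
        self._buffer: deque[float] = deque(maxlen=WINDOW_SIZE)
        self._count = 0

    def push(self, interval_ms: float) -> tuple[int, np.ndarray] | None:
        """Consume one interval; return ``(rr0_position, features)`` if a beat
        became classifiable, else ``None``.

        The newly pushed interval acts as the lookahead RR+1; the buffer of
        the previous 42 intervals is the trailing window whose last element
        is RR0.
        """
        if interval_ms <= 0:
            raise ValueError("RR intervals must be positive")
        out = None
        if self._count >= WINDOW_SIZE:
            window = RRWindow(np.asarray(self._buffer, dtype=float), interval_ms)
            out = (self._count - 1, extract_features(window))
        self._buffer.append(interval_ms)
        self._count += 1
        return out

    def feed(self, intervals: Iterable[float]) -> Iterator[tuple[int, np.ndarray]]:
        for x in intervals:
            row = self.push(x)
            if row is not None:
                yield row
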