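"""Synthetic ECG and labeled RR-interval generators.

Two generators make the entire pipeline exercisable with no external data:

``gen_ecg``
    A QRS-template train: Gaussian complexes of known amplitude and width
    placed at the cumulative positions of an RR schedule, plus optional
    white Gaussian noise at a stated SNR.  The exact peak positions are
    returned as ground truth, which turns R-peak detector evaluation into
    an oracle comparison.

``gen_rr_dataset``
    A labeled RR-interval sequence with class-dependent rhythm structure.
    Archetypes encode only RR timing — the signature the classifier
    actually uses: a normal rhythm is quasi-regular around a per-subject
    mean; supraventricular and ventricular ectopic beats are premature
    (short RR) followed by a compensatory pause, with ventricular beats
    drawn more extreme; fusion beats show intermediate prematurity; unknown
    beats get erratic uniform intervals.  No morphology is simulated, since
    only interval features feed the models.

Both are deterministic under a seed.  All generated intervals are bounded
to the physiological range [200, 3000] ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from beatstream.rpeak import PeakList, RRSeries
from beatstream.wfdb_io import AAMI_CLASSES, BeatAnnotation, EcgRecord, write_record

__all__ = [
    "EcgSynthesisSpec",
    "RRClassArchetype",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_CLASS_MIX",
    "gen_ecg",
    "gen_rr_dataset",
    "write_synthetic_wfdb",
    "write_rr_csv",
]

#: Physiological guard rails for generated intervals (ms).
RR_BOUNDS = (200.0, 3000.0)

#: Canonical symbol written into synthetic WFDB annotations for each class.
_CLASS_SYMBOL = {"N": "N", "SVEB": "A", "VEB": "V", "F": "F", "Q": "Q"}


@dataclass(frozen=True)
class EcgSynthesisSpec:
    """Settings for the QRS-template ECG generator.

    ``rr_schedule`` is either an explicit list of intervals (ms) or a
    ``(mean_ms, jitter_ms)`` pair sampled as a clipped normal.  The QRS
    template is a Gaussian of the given peak amplitude whose ``width_ms``
    is its full (6-sigma) extent; a typical QRS spans ~80 ms.
    """

    sampling_rate: float = 360.0
    duration_s: float = 30.0
    rr_schedule: tuple[float, float] | list[float] = (1000.0, 20.0)
    qrs_amplitude_mv: float = 1.0
    qrs_width_ms: float = 80.0
    noise_snr_db: float | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.qrs_width_ms <= 0:
            raise ValueError("qrs_width_ms must be positive")


def _schedule(spec: EcgSynthesisSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.rr_schedule, tuple) and len(spec.rr_schedule) == 2:
        mean, jitter = spec.rr_schedule
        n = int(np.ceil(spec.duration_s * 1000.0 / mean)) + 8
        rr = rng.normal(mean, jitter, size=n)
    else:
        rr = np.asarray(spec.rr_schedule, dtype=float)
    return np.clip(rr, *RR_BOUNDS)


def gen_ecg(spec: EcgSynthesisSpec, seed: int = 0) -> tuple[EcgRecord, PeakList]:
    """Synthesize a single-lead ECG with exact ground-truth R-peak indices.

    Raises ``ValueError`` if the QRS template is wider than half the
    smallest interval (complexes would merge).
    """
    rng = np.random.default_rng(seed)
    rr = _schedule(spec, rng)
    if spec.qrs_width_ms * 2 > float(np.min(rr)):
        raise ValueError(
            f"QRS template width {spec.qrs_width_ms} ms too wide for the "
            f"smallest interval {np.min(rr):.0f} ms"
        )
    fs = spec.sampling_rate
    n_samples = int(round(spec.duration_s * fs))
    t = np.arange(n_samples) / fs

    # first beat after a short settle-in, then cumulative RR positions
    peak_times = 0.4 + np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    peak_times = peak_times[peak_times < spec.duration_s - 0.1]
    peak_idx = np.round(peak_times * fs).astype(np.int64)

    sigma_s = spec.qrs_width_ms / 6.0 / 1000.0
    clean = np.zeros(n_samples)
    half = int(np.ceil(4 * sigma_s * fs))
    for idx in peak_idx:
        lo, hi = max(0, idx - half), min(n_samples, idx + half + 1)
        clean[lo:hi] += spec.qrs_amplitude_mv * np.exp(
            -0.5 * ((t[lo:hi] - idx / fs) / sigma_s) ** 2
        )
    signal = clean
    if spec.noise_snr_db is not None:
        p_signal = float(np.mean(clean**2))
        p_noise = p_signal / (10.0 ** (spec.noise_snr_db / 10.0))
        signal = clean + rng.normal(0.0, np.sqrt(p_noise), size=n_samples)
    record = EcgRecord("synthetic", fs, signal, "SYN")
    return record, PeakList(peak_idx, fs)


@dataclass(frozen=True)
class RRClassArchetype:
    """Rhythm rule for one AAMI class.

    For ectopic archetypes the premature interval is drawn uniformly from
    ``premature_range`` x mean RR and the following compensatory pause from
    ``pause_range`` x mean RR.  ``Q`` uses ``erratic_range_ms`` absolute
    uniform intervals instead.
    """

    aami_class: str
    premature_range: tuple[float, float] | None = None
    pause_range: tuple[float, float] | None = None
    erratic_range_ms: tuple[float, float] | None = None


#: Default archetypes: ventricular beats more extreme than supraventricular,
#: fusion intermediate, unknown erratic.
DEFAULT_ARCHETYPES: dict[str, RRClassArchetype] = {
    "SVEB": RRClassArchetype("SVEB", premature_range=(0.70, 0.80), pause_range=(1.15, 1.25)),
    "VEB": RRClassArchetype("VEB", premature_range=(0.60, 0.70), pause_range=(1.30, 1.40)),
    "F": RRClassArchetype("F", premature_range=(0.82, 0.90), pause_range=(1.05, 1.12)),
    "Q": RRClassArchetype("Q", erratic_range_ms=(400.0, 1600.0)),
}

#: Default study mix: a dominant normal rhythm with 5% of each abnormality.
DEFAULT_CLASS_MIX: dict[str, float] = {"N": 0.80, "SVEB": 0.05, "VEB": 0.05, "F": 0.05, "Q": 0.05}


@dataclass(frozen=True)
class RRDataset:
    """Generated RR series with one label per interval (class of the beat
    closing it) — directly consumable by the feature builder."""

    rr: RRSeries
    labels: list[str]
    mean_rr_ms: float


def gen_rr_dataset(
    class_mix: dict[str, float] | None = None,
    n_beats: int = 20_000,
    archetypes: dict[str, RRClassArchetype] | None = None,
    seed: int = 0,
    mean_rr_ms: float | None = None,
    jitter_frac: float = 0.03,
) -> RRDataset:
    """Generate a labeled RR-interval sequence.

    A base quasi-regular normal rhythm (per-subject mean drawn in
    [700, 1000] ms unless given, relative jitter ``jitter_frac``) is
    interleaved with archetype events at the requested class proportions.
    Each ectopic event occupies a premature interval (its beat carries the
    class label) followed by a compensatory-pause interval closed by a
    normal beat; events are spaced at least three beats apart so their
    signatures never overlap.

    Returns per-interval labels: ``labels[i]`` is the class of the beat
    ending interval ``i``, the alignment expected by
    :func:`beatstream.features.build_feature_table`.
    """
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {sum(mix.values())}")
    unknown = set(mix) - set(AAMI_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes in mix: {sorted(unknown)}")
    if n_beats <= 44:
        raise ValueError("n_beats must exceed 44 (window + lookahead)")
    arch = dict(DEFAULT_ARCHETYPES)
    if archetypes:
        arch.update(archetypes)

    rng = np.random.default_rng(seed)
    mu = float(mean_rr_ms) if mean_rr_ms is not None else float(rng.uniform(700.0, 1000.0))
    n_intervals = n_beats - 1
    intervals = rng.normal(mu, jitter_frac * mu, size=n_intervals)
    labels = ["N"] * n_intervals

    # event slots: every third beat position, away from the edges, shuffled
    slots = np.arange(2, n_beats - 2, 3)
    rng.shuffle(slots)
    cursor = 0
    for cls in ("SVEB", "VEB", "F", "Q"):
        frac = mix.get(cls, 0.0)
        n_events = int(round(frac * n_beats))
        if n_events == 0:
            continue
        if cursor + n_events > slots.size:
            raise ValueError(
                f"class mix too dense: {sum(v for k, v in mix.items() if k != 'N'):.2f} "
                "abnormal fraction exceeds the 1/3 event capacity"
            )
        for b in slots[cursor : cursor + n_events]:
            a = arch[cls]
            if a.erratic_range_ms is not None:
                intervals[b - 1] = rng.uniform(*a.erratic_range_ms)
            else:
                intervals[b - 1] = rng.uniform(*a.premature_range) * mu
                intervals[b] = rng.uniform(*a.pause_range) * mu
            labels[b - 1] = cls
        cursor += n_events

    intervals = np.clip(intervals, *RR_BOUNDS)
    rr = RRSeries(intervals, np.cumsum(intervals) / 1000.0)
    return RRDataset(rr, labels, mu)


def write_synthetic_wfdb(
    path: str | Path,
    record_id: str,
    dataset: RRDataset,
    sampling_rate: float = 360.0,
    seed: int = 0,
) -> None:
    """Render a labeled RR dataset as a WFDB fixture (signal + annotations).

    The ECG is a QRS train at the dataset's beat times; annotations carry
    the canonical symbol of each beat's class, so reading the fixture back
    reproduces the labels through the AAMI mapping.
    """
    intervals = dataset.rr.intervals_ms
    duration = 0.4 + float(np.sum(intervals)) / 1000.0 + 1.0
    spec = EcgSynthesisSpec(
        sampling_rate=sampling_rate,
        duration_s=duration,
        rr_schedule=list(intervals),
        noise_snr_db=None,
    )
    record, peaks = gen_ecg(spec, seed=seed)
    record.record_id = str(record_id)
    beat_labels = ["N"] + list(dataset.labels)  # first beat opens the series
    annotations = [
        BeatAnnotation(int(idx), _CLASS_SYMBOL[beat_labels[i]], beat_labels[i])
        for i, idx in enumerate(peaks.sample_indices)
        if i < len(beat_labels)
    ]
    write_record(path, record, annotations)


def write_rr_csv(path: str | Path, dataset: RRDataset) -> None:
    """RR stream as CSV (time_s, rr_ms, hr_bpm, label), one row per interval."""
    rr = dataset.rr
    frame = pd.DataFrame(
        {
            "time_s": rr.end_times_s,
            "rr_ms": rr.intervals_ms,
            "hr_bpm": np.round(60000.0 / rr.intervals_ms).astype(int),
            "label": dataset.labels,
        }
    )
    frame.to_csv(path, index=False)
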