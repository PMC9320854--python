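"""WFDB-dialect ECG record and annotation I/O with AAMI class mapping.

Reads and writes the PhysioNet waveform-database layout used by the MIT-BIH
Arrhythmia Database: a text header (``.hea``), a binary signal file
(``.dat``, formats 16 and 212 supported), and a binary beat-annotation file
(``.atr``, MIT annotation format).  Beat symbols are mapped onto the five
AAMI heartbeat classes (N, SVEB, VEB, F, Q); every other annotation code
(rhythm changes, noise marks, comments) is flagged as a non-beat and
excluded from RR computation and labeling.

The reader and writer round-trip exactly on sample indices and symbols,
which is what lets the synthetic module stand in for the real database.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AAMI_CLASSES",
    "NON_BEAT",
    "PACED_RECORDS",
    "AnnotationError",
    "RecordIntegrityError",
    "BeatAnnotation",
    "EcgRecord",
    "map_symbol_to_aami",
    "exclude_paced",
    "read_record",
    "write_record",
    "beat_annotations",
    "beats_to_frame",
]

#: Fixed class order used everywhere in the package (label encoding, matrices).
AAMI_CLASSES: tuple[str, ...] = ("N", "SVEB", "VEB", "F", "Q")

#: Sentinel returned for annotation codes that do not mark a heartbeat.
NON_BEAT = "non-beat"

#: MIT-BIH records consisting of paced rhythm, excluded from training data.
PACED_RECORDS: frozenset[str] = frozenset({"102", "104", "107", "217"})

# MIT-BIH beat symbol -> AAMI class.  The mapping is total over the 15 beat
# symbols and its preimages are disjoint; anything else is a non-beat.
_SYMBOL_TO_AAMI: dict[str, str] = {
    # Normal: normal, left/right bundle branch block, atrial/nodal escape
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    # Supraventricular ectopic: atrial premature (plain/aberrated),
    # nodal premature, supraventricular premature
    "A": "SVEB", "a": "SVEB", "J": "SVEB", "S": "SVEB",
    # Ventricular ectopic: premature ventricular contraction, ventricular escape
    "V": "VEB", "E": "VEB",
    # Fusion of ventricular and normal
    "F": "F",
    # Unknown: paced, fusion of paced and normal, unclassified
    "/": "Q", "f": "Q", "Q": "Q",
}

# Standard WFDB annotation codes (ecgcodes) <-> symbols, the subset needed for
# MIT-BIH beat and common non-beat annotations.
_CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    22: '"', 24: "p", 25: "B", 26: "^", 27: "t", 28: "+", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 37: "x", 38: "f", 41: "r",
}
_SYMBOL_TO_CODE: dict[str, int] = {s: c for c, s in _CODE_TO_SYMBOL.items()}

# Special annotation pseudo-codes (field modifiers).
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


class AnnotationError(ValueError):
    """Malformed annotation symbol or unreadable annotation stream."""


class RecordIntegrityError(ValueError):
    """Annotations inconsistent with the signal (out of order / out of range)."""


@dataclass(frozen=True)
class BeatAnnotation:
    """One reference annotation: an annotated sample position and its labels.

    ``aami_class`` is one of :data:`AAMI_CLASSES` for beat symbols and
    :data:`NON_BEAT` otherwise.
    """

    sample_index: int
    symbol: str
    aami_class: str

    @property
    def is_beat(self) -> bool:
        return self.aami_class != NON_BEAT


@dataclass
class EcgRecord:
    """Single-channel ECG signal in millivolts at a known sampling rate."""

    record_id: str
    sampling_rate: float
    signal: np.ndarray
    channel_name: str = "MLII"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.signal.ndim != 1 or self.signal.size == 0:
            raise ValueError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.sampling_rate


def map_symbol_to_aami(symbol: str) -> str:
    """Map a single-character MIT-BIH annotation symbol to its AAMI class.

    Returns :data:`NON_BEAT` for any code that does not mark a heartbeat
    (rhythm changes, artifacts, comments), which callers drop from beat
    sequences.

    Raises
    ------
    AnnotationError
        If ``symbol`` is not exactly one character.
    """
    if not isinstance(symbol, str) or len(symbol) != 1:
        raise AnnotationError(f"annotation symbol must be a single character, got {symbol!r}")
    return _SYMBOL_TO_AAMI.get(symbol, NON_BEAT)


def exclude_paced(record_ids: Iterable[str | int]) -> list[str]:
    """Drop the paced-rhythm records (102, 104, 107, 217), preserving order.

    IDs are normalized to strings; absent IDs are a no-op.
    """
    return [str(r) for r in record_ids if str(r) not in PACED_RECORDS]


# ---------------------------------------------------------------------------
# Header (.hea)
# ---------------------------------------------------------------------------


@dataclass
class _SignalSpec:
    filename: str
    fmt: int
    gain: float
    baseline: int
    description: str


@dataclass
class _Header:
    record_id: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[_SignalSpec] = field(default_factory=list)


def _parse_header(path: Path) -> _Header:
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise AnnotationError(f"empty header file: {path}")
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    header = _Header(name, n_sig, fs, n_samples)
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        filename = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain_tok = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_tok.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gain = float(g)
            baseline = int(b.rstrip(")"))
        else:
            gain = float(gain_part)
            # ADC zero (token 4) is the baseline when no explicit one is given
            baseline = int(tok[4]) if len(tok) > 4 else 0
        if gain == 0:
            gain = 200.0  # WFDB convention for unspecified gain
        description = " ".join(tok[8:]) if len(tok) > 8 else filename
        header.signals.append(_SignalSpec(filename, fmt, gain, baseline, description))
    return header


# ---------------------------------------------------------------------------
# Signal (.dat) — formats 16 (little-endian int16) and 212 (packed 12-bit)
# ---------------------------------------------------------------------------


def _read_dat(path: Path, fmt: int, n_sig: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0[s0 > 2047] -= 4096  # 12-bit two's complement
        s1[s1 > 2047] -= 4096
        flat = np.empty(2 * len(b), dtype=np.int32)
        flat[0::2] = s0
        flat[1::2] = s1
    else:
        raise AnnotationError(f"unsupported WFDB signal format {fmt}")
    n_frames = len(flat) // n_sig
    return flat[: n_frames * n_sig].reshape(n_frames, n_sig)


def _write_dat(path: Path, adc: np.ndarray, fmt: int) -> None:
    flat = adc.reshape(-1).astype(np.int32)
    if fmt == 16:
        path.write_bytes(flat.astype("<i2").tobytes())
    elif fmt == 212:
        if flat.size % 2:
            flat = np.append(flat, 0)
        v = flat & 0xFFF
        s0, s1 = v[0::2], v[1::2]
        out = np.empty((len(s0), 3), dtype=np.uint8)
        out[:, 0] = s0 & 0xFF
        out[:, 1] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
        out[:, 2] = s1 & 0xFF
        path.write_bytes(out.tobytes())
    else:
        raise AnnotationError(f"unsupported WFDB signal format {fmt}")


# ---------------------------------------------------------------------------
# Annotations (.atr) — MIT annotation format
# ---------------------------------------------------------------------------


def _read_annotations(path: Path) -> list[tuple[int, str]]:
    data = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if word == 0:  # end of annotation stream
            break
        if code == _SKIP:
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            skip = (hi << 16) | lo
            if skip >= 1 << 31:
                skip -= 1 << 32
            pending_skip += skip
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += interval + (interval & 1)  # aux string, padded to even length
            continue
        t += pending_skip + interval
        pending_skip = 0
        out.append((t, _CODE_TO_SYMBOL.get(code, "?")))
    return out


def _write_annotations(path: Path, annotations: Sequence[tuple[int, str]]) -> None:
    buf = bytearray()
    prev = 0
    for sample, symbol in annotations:
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise AnnotationError(f"no WFDB annotation code for symbol {symbol!r}")
        delta = sample - prev
        if delta < 0:
            raise RecordIntegrityError("annotations must be sorted by sample index")
        if delta > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<H", (delta >> 16) & 0xFFFF)
            buf += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = sample
    buf += struct.pack("<H", 0)
    path.write_bytes(bytes(buf))


# ---------------------------------------------------------------------------
# Record-level API
# ---------------------------------------------------------------------------


def read_record(
    path: str | Path,
    record_id: str,
    channel: int | str = 0,
    annotator: str = "atr",
) -> tuple[EcgRecord, list[BeatAnnotation]]:
    """Read a WFDB record and its beat annotations.

    Parameters
    ----------
    path:
        Directory holding ``<record_id>.hea``, the signal file it names, and
        ``<record_id>.<annotator>``.
    channel:
        Channel index or channel description to select (default: the first
        channel — lead MLII in MIT-BIH).

    Returns
    -------
    (record, annotations):
        The selected channel in millivolts and *all* annotations sorted by
        sample index, non-beat codes flagged via ``aami_class == "non-beat"``.

    Raises
    ------
    FileNotFoundError
        Naming the missing header, signal, or annotation file.
    RecordIntegrityError
        If annotations are out of order or index beyond the signal length.
    """
    path = Path(path)
    record_id = str(record_id)
    hea = path / f"{record_id}.hea"
    if not hea.exists():
        raise FileNotFoundError(f"missing header file: {hea}")
    header = _parse_header(hea)
    if not header.signals:
        raise AnnotationError(f"header {hea} describes no signals")

    if isinstance(channel, str):
        names = [s.description for s in header.signals]
        if channel not in names:
            raise ValueError(f"channel {channel!r} not in record channels {names}")
        ch = names.index(channel)
    else:
        ch = int(channel)
        if not 0 <= ch < header.n_sig:
            raise ValueError(f"channel index {ch} out of range for {header.n_sig} signals")

    dat = path / header.signals[ch].filename
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file: {dat}")
    adc = _read_dat(dat, header.signals[ch].fmt, header.n_sig)
    if header.n_samples > 0:
        adc = adc[: header.n_samples]  # format-212 files pad to an even count
    spec = header.signals[ch]
    signal_mv = (adc[:, ch].astype(float) - spec.baseline) / spec.gain
    record = EcgRecord(record_id, header.fs, signal_mv, spec.description)

    atr = path / f"{record_id}.{annotator}"
    if not atr.exists():
        raise FileNotFoundError(f"missing annotation file: {atr}")
    raw = _read_annotations(atr)
    annotations: list[BeatAnnotation] = []
    prev = -1
    for sample, symbol in raw:
        if sample <= prev:
            raise RecordIntegrityError(
                f"record {record_id}: annotation at sample {sample} not after {prev}"
            )
        if sample >= record.signal.size:
            raise RecordIntegrityError(
                f"record {record_id}: annotation at sample {sample} beyond "
                f"signal length {record.signal.size}"
            )
        try:
            aami = map_symbol_to_aami(symbol)
        except AnnotationError:
            aami = NON_BEAT
        annotations.append(BeatAnnotation(sample, symbol, aami))
        prev = sample
    return record, annotations


def write_record(
    path: str | Path,
    record: EcgRecord,
    annotations: Sequence[BeatAnnotation] | Sequence[tuple[int, str]] = (),
    fmt: int = 16,
    gain: float = 200.0,
    annotator: str = "atr",
) -> None:
    """Write a single-channel WFDB record (header, signal, annotations).

    The signal is quantized with the given ADC gain (units per mV); a
    subsequent :func:`read_record` recovers sample indices and symbols
    exactly and amplitudes to within one ADC step.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rid = record.record_id
    adc = np.round(record.signal * gain).astype(np.int32)
    lim = 2047 if fmt == 212 else 32767
    adc = np.clip(adc, -lim - 1, lim)
    _write_dat(path / f"{rid}.dat", adc.reshape(-1, 1), fmt)
    first = int(adc[0]) if adc.size else 0
    header = (
        f"{rid} 1 {record.sampling_rate:g} {record.signal.size}\n"
        f"{rid}.dat {fmt} {gain:g}(0)/mV {12 if fmt == 212 else 16} 0 "
        f"{first} 0 0 {record.channel_name}\n"
    )
    (path / f"{rid}.hea").write_text(header)
    pairs = [
        (a.sample_index, a.symbol) if isinstance(a, BeatAnnotation) else (int(a[0]), str(a[1]))
        for a in annotations
    ]
    _write_annotations(path / f"{rid}.{annotator}", pairs)


def beat_annotations(annotations: Iterable[BeatAnnotation]) -> list[BeatAnnotation]:
    """Keep only annotations that mark heartbeats (drop rhythm/noise codes)."""
    return [a for a in annotations if a.is_beat]


def beats_to_frame(record_id: str, sampling_rate: float, beats: Iterable[BeatAnnotation]):
    """Beat table as a DataFrame (record_id, sample_index, time_s, symbol, aami_class)."""
    import pandas as pd

    rows = [
        {
            "record_id": record_id,
            "sample_index": b.sample_index,
            "time_s": b.sample_index / sampling_rate,
            "symbol": b.symbol,
            "aami_class": b.aami_class,
        }
        for b in beats
    ]
    return pd.DataFrame(rows, columns=["record_id", "sample_index", "time_s", "symbol", "aami_class"])
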