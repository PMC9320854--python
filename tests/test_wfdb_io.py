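import numpy as np
import pytest

from beatstream.synthetic import gen_rr_dataset, write_synthetic_wfdb
from beatstream.wfdb_io import (
    AAMI_CLASSES,
    NON_BEAT,
    AnnotationError,
    BeatAnnotation,
    EcgRecord,
    RecordIntegrityError,
    beat_annotations,
    exclude_paced,
    map_symbol_to_aami,
    read_record,
    write_record,
)

ALL_BEAT_SYMBOLS = {
    "N": ["N", "L", "R", "e", "j"],
    "SVEB": ["A", "a", "J", "S"],
    "VEB": ["V", "E"],
    "F": ["F"],
    "Q": ["/", "f", "Q"],
}


@pytest.mark.parametrize(
    "symbol,expected",
    [("L", "N"), ("A", "SVEB"), ("/", "Q"), ("V", "VEB"), ("F", "F"),
     ("+", NON_BEAT), ("~", NON_BEAT), ("|", NON_BEAT), ("?", NON_BEAT)],
)
def test_symbol_mapping_examples(symbol, expected):
    assert map_symbol_to_aami(symbol) == expected


def test_mapping_is_total_with_disjoint_preimages():
    """Each of the 15 beat symbols maps to exactly one AAMI class."""
    seen = set()
    for cls, symbols in ALL_BEAT_SYMBOLS.items():
        for s in symbols:
            assert map_symbol_to_aami(s) == cls
            assert s not in seen
            seen.add(s)
    assert len(seen) == 15
    assert set(ALL_BEAT_SYMBOLS) == set(AAMI_CLASSES)


@pytest.mark.parametrize("bad", ["", "NV", 7, None])
def test_malformed_symbols_rejected(bad):
    with pytest.raises(AnnotationError):
        map_symbol_to_aami(bad)


@pytest.mark.parametrize(
    "ids,expected",
    [
        ([100, 102, 104, 106], ["100", "106"]),
        ([], []),
        ([102, 104, 107, 217], []),
        (["100", "217", "100"], ["100", "100"]),
    ],
)
def test_exclude_paced(ids, expected):
    assert exclude_paced(ids) == expected


def _toy_record(n=8000, fs=360.0):
    rng = np.random.default_rng(0)
    return EcgRecord("t1", fs, rng.normal(0, 0.1, n))


def test_roundtrip_identity_on_indices_and_symbols(tmp_path):
    record = _toy_record()
    anns = [
        BeatAnnotation(100, "N", "N"),
        BeatAnnotation(460, "+", NON_BEAT),   # rhythm change, non-beat
        BeatAnnotation(820, "V", "VEB"),
        BeatAnnotation(2900, "A", "SVEB"),    # forces a long-interval encoding
        BeatAnnotation(7500, "/", "Q"),
    ]
    write_record(tmp_path, record, anns)
    back, read_anns = read_record(tmp_path, "t1")
    assert [a.sample_index for a in read_anns] == [a.sample_index for a in anns]
    assert [a.symbol for a in read_anns] == [a.symbol for a in anns]
    assert [a.aami_class for a in read_anns] == [a.aami_class for a in anns]
    assert back.sampling_rate == record.sampling_rate
    # amplitudes recovered to within one ADC step (gain 200/mV)
    assert np.max(np.abs(back.signal - record.signal)) <= 1.0 / 200.0 + 1e-12


@pytest.mark.parametrize("fmt", [16, 212])
def test_signal_formats_roundtrip(tmp_path, fmt):
    record = _toy_record(n=4001)
    write_record(tmp_path / str(fmt), record, [BeatAnnotation(50, "N", "N")], fmt=fmt)
    back, _ = read_record(tmp_path / str(fmt), "t1")
    assert np.max(np.abs(back.signal - record.signal)) <= 1.0 / 200.0 + 1e-12


def test_nonbeat_annotations_flagged_and_filterable(tmp_path):
    """10 annotations, 2 non-beat codes -> 8 beats after filtering."""
    record = _toy_record()
    symbols = ["N", "N", "+", "V", "A", "~", "N", "F", "/", "N"]
    anns = [
        BeatAnnotation(200 + 300 * i, s, map_symbol_to_aami(s)) for i, s in enumerate(symbols)
    ]
    write_record(tmp_path, record, anns)
    _, read_anns = read_record(tmp_path, "t1")
    beats = beat_annotations(read_anns)
    assert len(read_anns) == 10
    assert len(beats) == 8
    assert all(b.aami_class in AAMI_CLASSES for b in beats)


def test_missing_files_error_names_file(tmp_path):
    with pytest.raises(FileNotFoundError, match="nope.hea"):
        read_record(tmp_path, "nope")
    record = _toy_record()
    write_record(tmp_path, record, [BeatAnnotation(10, "N", "N")])
    (tmp_path / "t1.atr").unlink()
    with pytest.raises(FileNotFoundError, match="t1.atr"):
        read_record(tmp_path, "t1")


def test_annotation_beyond_signal_is_integrity_error(tmp_path):
    record = _toy_record(n=1000)
    write_record(tmp_path, record, [BeatAnnotation(100, "N", "N"), BeatAnnotation(5000, "N", "N")])
    with pytest.raises(RecordIntegrityError):
        read_record(tmp_path, "t1")


def test_synthetic_fixture_reads_back_with_correct_labels(tmp_path):
    ds = gen_rr_dataset(n_beats=150, seed=5)
    write_synthetic_wfdb(tmp_path, "s9", ds, seed=5)
    _, anns = read_record(tmp_path, "s9")
    beats = beat_annotations(anns)
    assert len(beats) > 100
    # the i-th interval's closing beat carries label[i]
    got = [b.aami_class for b in beats[1:]]
    assert got == ds.labels[: len(got)]
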