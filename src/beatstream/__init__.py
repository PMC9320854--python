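"""RR-interval heartbeat classification for continuous wearable monitoring.

The package covers the full pipeline from single-lead ECG to per-beat AAMI
class predictions:

* WFDB-dialect record and annotation I/O with AAMI symbol mapping
  (:mod:`beatstream.wfdb_io`),
* Pan-Tompkins R-peak detection and RR-interval derivation
  (:mod:`beatstream.rpeak`),
* the nine RR-interval series features over a trailing 42-interval window
  (:mod:`beatstream.features`),
* class rebalancing by random oversampling, SMOTE or ADASYN
  (:mod:`beatstream.resampling`),
* inter-patient (record-protocol) and intra-patient (random 70/30) splits
  (:mod:`beatstream.splits`),
* the seven reference classifiers (:mod:`beatstream.models`),
* confusion matrices and support-weighted evaluation metrics
  (:mod:`beatstream.metrics`),
* a real-time streaming classification loop emulating a 1 Hz chest-strap
  RR-interval source (:mod:`beatstream.stream`), and
* synthetic ECG / labeled RR-interval generators so the whole pipeline is
  testable without external data (:mod:`beatstream.synthetic`).
"""

from beatstream.wfdb_io import (
    AAMI_CLASSES,
    BeatAnnotation,
    EcgRecord,
    exclude_paced,
    map_symbol_to_aami,
    read_record,
    write_record,
)
from beatstream.rpeak import PanTompkinsParams, PeakList, RRSeries, detect_rpeaks, rr_intervals
from beatstream.features import FEATURE_COLUMNS, RRWindow, build_feature_table, extract_features
from beatstream.resampling import ResamplingSpec, adasyn, random_oversample, smote
from beatstream.splits import SplitSpec, protocol_split, random_split
from beatstream.models import ModelSpec, TrainedModel, predict, train
from beatstream.metrics import ConfusionMatrix, MetricsReport, confusion_matrix, evaluate
from beatstream.stream import StreamEvent, StreamReport, emulate_source, run_stream
from beatstream.synthetic import EcgSynthesisSpec, gen_ecg, gen_rr_dataset

__version__ = "0.1.0"

__all__ = [
    "AAMI_CLASSES",
    "BeatAnnotation",
    "EcgRecord",
    "exclude_paced",
    "map_symbol_to_aami",
    "read_record",
    "write_record",
    "PanTompkinsParams",
    "PeakList",
    "RRSeries",
    "detect_rpeaks",
    "rr_intervals",
    "FEATURE_COLUMNS",
    "RRWindow",
    "build_feature_table",
    "extract_features",
    "ResamplingSpec",
    "adasyn",
    "random_oversample",
    "smote",
    "SplitSpec",
    "protocol_split",
    "random_split",
    "ModelSpec",
    "TrainedModel",
    "predict",
    "train",
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "evaluate",
    "StreamEvent",
    "StreamReport",
    "emulate_source",
    "run_stream",
    "EcgSynthesisSpec",
    "gen_ecg",
    "gen_rr_dataset",
]
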