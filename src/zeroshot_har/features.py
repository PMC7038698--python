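"""ON-count featurization: activity instances -> the fixed-length count matrix.

Each activity instance becomes one row of an ``m x n`` matrix: entry *j*
counts how many activation events (ON for motion sensors, OPEN for door
sensors) sensor *j* emitted during the instance.  OFF/CLOSE transitions and
out-of-vocabulary sensors contribute nothing.  The sensor vocabulary fixes
column order and is built on training data only; an optional per-column
standardizer (fitted on the training matrix only) rescales the counts before
they reach the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np
from sklearn.preprocessing import StandardScaler

from zeroshot_har.casas import ActivityInstance, SensorEvent

__all__ = [
    "SensorVocabulary",
    "FeatureMatrix",
    "build_vocabulary",
    "count_on_events",
    "build_feature_matrix",
    "fit_scaler",
    "write_feature_matrix",
    "read_feature_matrix",
]


@dataclass(frozen=True)
class SensorVocabulary:
    """Ordered, unique sensor ids defining feature-column order."""

    sensor_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sensor_ids)) != len(self.sensor_ids):
            raise ValueError("sensor ids must be unique")

    def __len__(self) -> int:
        return len(self.sensor_ids)

    def __iter__(self):
        return iter(self.sensor_ids)

    def index(self, sensor_id: str) -> int:
        return self.sensor_ids.index(sensor_id)


@dataclass(frozen=True)
class FeatureMatrix:
    """The ``m x n`` per-instance, per-sensor activation-count matrix.

    ``values`` holds non-negative integer counts, or reals after scaling;
    ``row_labels[i]`` is the activity label of instance *i*.
    """

    values: np.ndarray
    row_labels: tuple[str, ...]
    vocabulary: SensorVocabulary

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.row_labels):
            raise ValueError("one row label per matrix row required")
        if self.values.shape[1] != len(self.vocabulary):
            raise ValueError("one column per vocabulary sensor required")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def _numeric_events_exceeding(
    events: Iterable[SensorEvent], threshold: float
) -> set[str]:
    """Sensors whose numeric value jumps by more than ``threshold`` between
    consecutive readings — the optional binarization of environmental sensors."""
    last: dict[str, float] = {}
    hits: set[str] = set()
    for e in events:
        if e.is_categorical:
            continue
        value = e.numeric_value
        if e.sensor_id in last and abs(value - last[e.sensor_id]) > threshold:
            hits.add(e.sensor_id)
        last[e.sensor_id] = value
    return hits


def build_vocabulary(
    instances: Sequence[ActivityInstance],
    *,
    numeric_threshold: float | None = None,
) -> SensorVocabulary:
    """Sorted vocabulary of all sensors emitting categorical binary events.

    Numeric environmental sensors (temperature, light, ...) are excluded by
    default; passing ``numeric_threshold`` admits numeric sensors whose value
    changes by more than the threshold at least once (each such change then
    counts as an activation).
    """
    if not instances:
        raise ValueError("cannot build a vocabulary from zero instances")
    ids: set[str] = set()
    for inst in instances:
        ids.update(e.sensor_id for e in inst.events if e.is_categorical)
    if numeric_threshold is not None:
        for inst in instances:
            ids.update(_numeric_events_exceeding(inst.events, numeric_threshold))
    if not ids:
        raise ValueError(
            "no binary sensors found; pass numeric_threshold= to binarize "
            "numeric environmental sensors"
        )
    return SensorVocabulary(tuple(sorted(ids)))


def count_on_events(
    instance: ActivityInstance,
    vocabulary: SensorVocabulary,
    *,
    numeric_threshold: float | None = None,
) -> np.ndarray:
    """Length-``n`` activation-count vector for one instance.

    Entry *j* is the number of ON/OPEN events of ``vocabulary[j]`` in the
    instance; OFF/CLOSE and out-of-vocabulary sensors contribute zero.  With
    ``numeric_threshold``, a numeric sensor's super-threshold value changes
    count as activations too.
    """
    if len(vocabulary) == 0:
        raise ValueError("vocabulary must be non-empty")
    index = {sid: j for j, sid in enumerate(vocabulary)}
    counts = np.zeros(len(vocabulary), dtype=np.int64)
    last_numeric: dict[str, float] = {}
    for e in instance.events:
        j = index.get(e.sensor_id)
        if e.is_categorical:
            if j is not None and e.is_activation:
                counts[j] += 1
        elif numeric_threshold is not None:
            value = e.numeric_value
            prev = last_numeric.get(e.sensor_id)
            if j is not None and prev is not None and abs(value - prev) > numeric_threshold:
                counts[j] += 1
            last_numeric[e.sensor_id] = value
    return counts


def build_feature_matrix(
    instances: Sequence[ActivityInstance],
    vocabulary: SensorVocabulary,
    *,
    scaler: StandardScaler | None = None,
    numeric_threshold: float | None = None,
) -> FeatureMatrix:
    """Stack per-instance count vectors into a :class:`FeatureMatrix`.

    ``scaler``, when given, must already be fitted (on the training matrix
    only — fitting here would leak test statistics into the features).
    """
    rows = np.array(
        [
            count_on_events(inst, vocabulary, numeric_threshold=numeric_threshold)
            for inst in instances
        ],
        dtype=np.float64,
    ).reshape(len(instances), len(vocabulary))
    if scaler is not None:
        if getattr(scaler, "n_features_in_", len(vocabulary)) != len(vocabulary):
            raise ValueError(
                f"scaler was fitted on {scaler.n_features_in_} columns, "
                f"vocabulary has {len(vocabulary)}"
            )
        rows = scaler.transform(rows)
    else:
        rows = rows.astype(np.int64)
    labels = tuple(inst.label for inst in instances)
    return FeatureMatrix(rows, labels, vocabulary)


def fit_scaler(training_matrix: FeatureMatrix) -> StandardScaler:
    """Per-column standardizer (zero mean, unit variance) fitted on training counts."""
    scaler = StandardScaler()
    scaler.fit(np.asarray(training_matrix.values, dtype=np.float64))
    return scaler


def write_feature_matrix(matrix: FeatureMatrix, sink: TextIO, *, sep: str = "\t") -> None:
    """Persist as delimited text: header names the label column then sensors."""
    sink.write(sep.join(["label", *matrix.vocabulary.sensor_ids]) + "\n")
    integer = np.issubdtype(matrix.values.dtype, np.integer)
    for label, row in zip(matrix.row_labels, matrix.values):
        cells = [str(int(v)) if integer else repr(float(v)) for v in row]
        sink.write(sep.join([label, *cells]) + "\n")


def read_feature_matrix(source: TextIO, *, sep: str = "\t") -> FeatureMatrix:
    header = source.readline().rstrip("\n").split(sep)
    if not header or header[0] != "label":
        raise ValueError("feature-matrix text must start with a 'label' header column")
    vocabulary = SensorVocabulary(tuple(header[1:]))
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in source:
        if not line.strip():
            continue
        cells = line.rstrip("\n").split(sep)
        labels.append(cells[0])
        rows.append([float(c) for c in cells[1:]])
    values = np.array(rows, dtype=np.float64).reshape(len(rows), len(vocabulary))
    if values.size and np.all(values == np.round(values)):
        values = values.astype(np.int64)
    return FeatureMatrix(values, tuple(labels), vocabulary)
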