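"""Shared fixtures: tiny CASAS logs, toy embedding tables, published matrices."""

import io

import numpy as np
import pytest

import zeroshot_har as z

TINY_LOG = """\
2012-07-18 13:47:05.0 M012 ON
2012-07-18 13:47:10.0 D002 OPEN Bathe begin
2012-07-18 13:47:15.0 M012 OFF
2012-07-18 13:47:20.0 T101 21.5
2012-07-18 13:47:25.0 M013 ON
2012-07-18 13:47:30.0 M013 OFF
2012-07-18 13:47:35.0 D002 CLOSE Bathe end
2012-07-18 13:48:00.0 M012 ON
"""

# published zero-shot confusion matrices (rows = truth, columns = predicted)
HH101_S1 = (
    ("Relax", "Sleep", "Toilet"),
    np.array([[84, 0, 0], [7, 79, 0], [0, 97, 352]]),
)
HH101_S2 = (
    ("Cook Lunch", "Eat Lunch", "Personal Hygiene"),
    np.array([[13, 0, 0], [0, 14, 0], [4, 0, 154]]),
)
HH125_S2 = (
    ("Cook Lunch", "Eat Lunch", "Personal Hygiene"),
    np.array([[64, 0, 0], [0, 1, 0], [0, 6, 219]]),
)


def expand_confusion(labels, counts):
    """Truth/predicted label sequences whose tally is exactly ``counts``."""
    truth, predicted = [], []
    for i, row_label in enumerate(labels):
        for j, col_label in enumerate(labels):
            truth.extend([row_label] * int(counts[i, j]))
            predicted.extend([col_label] * int(counts[i, j]))
    return truth, predicted


@pytest.fixture
def tiny_events():
    return z.parse_events(io.StringIO(TINY_LOG))


@pytest.fixture
def tiny_instances(tiny_events):
    return z.segment_instances(tiny_events)


@pytest.fixture(scope="session")
def toy_table():
    vectors = {
        "sleep": np.array([0.1, 0.2, 0.3]),
        "wash": np.array([1.0, 0.0, 0.0]),
        "dinner": np.array([0.0, 1.0, 0.0]),
        "dishes": np.array([0.0, 0.0, 1.0]),
        "toilet": np.array([0.5, -0.5, 0.0]),
    }
    return z.EmbeddingTable(vectors)


@pytest.fixture(scope="session")
def congruent_run():
    """One full synthetic zero-shot experiment, shared across tests (seed 1)."""
    config = z.ScenarioConfig(
        seen_labels=tuple(f"Seen{k}" for k in range(5)),
        unseen_labels=tuple(f"Unseen{u}" for u in range(3)),
        seed=1,
    )
    return z.run_pipeline(config)
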