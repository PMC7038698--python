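"""Word-embedding semantic space: tables, label prototypes, cosine matching.

Activity labels are bridged to the semantic space by tokenizing them
(lowercase; split on spaces, underscores and camel-case boundaries, so
``"WashDinnerDishes"`` -> ``wash``, ``dinner``, ``dishes``), looking each
token up in a word-embedding table, and averaging the vectors.  Unseen
activities are then recognized by maximal cosine similarity between a
predicted semantic vector and the candidate class prototypes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

__all__ = [
    "EmbeddingTable",
    "ClassPrototype",
    "tokenize_label",
    "load_embeddings",
    "write_embeddings",
    "label_to_prototype",
    "cosine_similarity",
    "nearest_prototype",
]

_CAMEL_RE = re.compile(r"(?<=[a-z0-9])(?=[A-Z])|(?<=[A-Z])(?=[A-Z][a-z])")


def tokenize_label(label: str) -> list[str]:
    """Split an activity label into lowercase word tokens.

    Handles the label styles that occur in smart-home datasets: spaced
    ("Wash Dinner Dishes"), underscored ("wash_dinner_dishes") and camel-case
    ("WashDinnerDishes") all tokenize to ``['wash', 'dinner', 'dishes']``.
    """
    parts: list[str] = []
    for chunk in re.split(r"[\s_]+", label.strip()):
        if chunk:
            parts.extend(p for p in _CAMEL_RE.split(chunk) if p)
    return [p.lower() for p in parts]


class EmbeddingTable:
    """Token -> vector store with a fixed dimension ``L`` (300 for Google-News)."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding table must contain at least one token")
        normalized: dict[str, np.ndarray] = {}
        dim: int | None = None
        for token, vec in vectors.items():
            arr = np.asarray(vec, dtype=np.float64).ravel()
            if dim is None:
                dim = arr.size
            elif arr.size != dim:
                raise ValueError(
                    f"token {token!r} has dimension {arr.size}, expected {dim}"
                )
            key = token.lower()
            if key in normalized:
                raise ValueError(f"duplicate token after case-normalization: {key!r}")
            normalized[key] = arr
        self._vectors = normalized
        self.dimension: int = int(dim)  # type: ignore[arg-type]

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self._vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self._vectors[token.lower()]

    @property
    def tokens(self) -> list[str]:
        return list(self._vectors)

    def items(self):
        return self._vectors.items()


def load_embeddings(source: TextIO) -> EmbeddingTable:
    """Read a table in the word2vec text format.

    First line is ``"count dim"``; each following line is a token and ``dim``
    numbers, whitespace-separated.
    """
    header = source.readline().split()
    if len(header) != 2:
        raise ValueError("word2vec text header must be 'count dim'")
    count, dim = int(header[0]), int(header[1])
    vectors: dict[str, np.ndarray] = {}
    for line in source:
        parts = line.split()
        if not parts:
            continue
        token, values = parts[0], parts[1:]
        if len(values) != dim:
            raise ValueError(
                f"token {token!r} has {len(values)} components, header says {dim}"
            )
        vectors[token] = np.array([float(v) for v in values], dtype=np.float64)
    if len(vectors) != count:
        raise ValueError(f"header promised {count} tokens, file holds {len(vectors)}")
    return EmbeddingTable(vectors)


def write_embeddings(table: EmbeddingTable, sink: TextIO) -> None:
    """Write the table in the word2vec text format (full float precision)."""
    sink.write(f"{len(table)} {table.dimension}\n")
    for token, vec in table.items():
        sink.write(token + " " + " ".join(repr(float(v)) for v in vec) + "\n")


@dataclass(frozen=True)
class ClassPrototype:
    """The semantic vector attached to one activity label."""

    label: str
    vector: np.ndarray

    @property
    def unit_vector(self) -> np.ndarray:
        norm = np.linalg.norm(self.vector)
        if norm == 0:
            raise ValueError(f"prototype {self.label!r} has a zero vector")
        return self.vector / norm


def label_to_prototype(label: str, table: EmbeddingTable) -> ClassPrototype:
    """Vectorize an activity label as the mean of its tokens' word vectors.

    Tokens missing from the table are skipped with a warning as long as at
    least one token resolves; otherwise an error lists every attempted token.
    """
    tokens = tokenize_label(label)
    if not tokens:
        raise ValueError(f"label {label!r} produced no tokens")
    found = [table[t] for t in tokens if t in table]
    missing = [t for t in tokens if t not in table]
    if not found:
        raise KeyError(
            f"no token of label {label!r} found in embedding table "
            f"(tried: {', '.join(tokens)})"
        )
    if missing:
        warnings.warn(
            f"label {label!r}: tokens not in embedding table, skipped: "
            f"{', '.join(missing)}",
            stacklevel=2,
        )
    return ClassPrototype(label, np.mean(found, axis=0))


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """``x . y / (||x|| ||y||)`` — in [-1, 1]; errors on zero vectors."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def nearest_prototype(
    query: np.ndarray, prototypes: Sequence[ClassPrototype]
) -> tuple[str, float]:
    """Candidate label with maximal cosine similarity to ``query``.

    Ties break to the lexicographically smallest label, so matching is
    deterministic.
    """
    if not prototypes:
        raise ValueError("at least one prototype is required")
    best: tuple[str, float] | None = None
    for proto in sorted(prototypes, key=lambda p: p.label):
        sim = cosine_similarity(query, proto.vector)
        if best is None or sim > best[1]:
            best = (proto.label, sim)
    return best  # type: ignore[return-value]


def prototypes_for_labels(
    labels: Iterable[str], table: EmbeddingTable
) -> list[ClassPrototype]:
    """Vectorize several labels at once (convenience for scenario setup)."""
    return [label_to_prototype(label, table) for label in labels]
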