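"""Evaluation: confusion matrices, one-vs-rest metrics, correlation, distractors.

Conventions follow the zero-shot activity-recognition literature: the
confusion matrix has rows = ground truth and columns = predicted; per-class
metrics are one-vs-rest, with accuracy reported as a percentage of all
evaluated instances and precision/recall/F on the unit scale.  The
``N (Classified)`` / ``N (Truth)`` accounting of published result tables maps
to the matrix's column and row sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, TextIO

import numpy as np

from zeroshot_har.features import FeatureMatrix
from zeroshot_har.semantic import ClassPrototype, tokenize_label

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion",
    "class_metrics",
    "correlation_matrix",
    "evaluate_with_distractors",
    "write_metrics_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K tally; ``counts[i, j]`` = instances of truth class i predicted j."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def micro_accuracy(self) -> float:
        """Fraction of all instances on the diagonal (overall accuracy)."""
        return float(np.trace(self.counts) / self.total)

    def n_truth(self, label: str) -> int:
        return int(self.counts[self.labels.index(label)].sum())

    def n_classified(self, label: str) -> int:
        return int(self.counts[:, self.labels.index(label)].sum())


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest counts and derived metrics for a single class.

    ``accuracy`` is a percentage; precision, recall and F1 are in [0, 1],
    each defined as 0 when its denominator vanishes.
    """

    label: str
    tp: int
    tn: int
    fp: int
    fn: int
    n_classified: int
    n_truth: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def rounded(self, places: int = 2) -> dict[str, float]:
        return {
            "accuracy": round(self.accuracy, places),
            "precision": round(self.precision, places),
            "recall": round(self.recall, places),
            "f_measure": round(self.f_measure, places),
        }


def confusion(
    truth: Sequence[str],
    predicted: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionMatrix:
    """Tally a confusion matrix over a fixed class order (rows=truth)."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"truth ({len(truth)}) and predicted ({len(predicted)}) differ in length"
        )
    labels = tuple(class_order)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            unknown = t if t not in index else p
            raise ValueError(f"label {unknown!r} not in class order {labels}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels, counts)


def class_metrics(cm: ConfusionMatrix) -> dict[str, ClassMetrics]:
    """One-vs-rest TP/TN/FP/FN and derived metrics for every class."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    out: dict[str, ClassMetrics] = {}
    for i, label in enumerate(cm.labels):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[i].sum()) - tp
        fp = int(cm.counts[:, i].sum()) - tp
        tn = cm.total - tp - fn - fp
        out[label] = ClassMetrics(
            label, tp, tn, fp, fn,
            n_classified=cm.n_classified(label),
            n_truth=cm.n_truth(label),
        )
    return out


def correlation_matrix(
    vectors: Mapping[str, np.ndarray], *, method: str = "pearson"
) -> tuple[tuple[str, ...], np.ndarray]:
    """Pairwise Pearson or cosine coefficients between labeled vectors.

    Used to probe how strongly seen-class signatures (feature centroids or
    word-embedding prototypes) relate to the unseen classes they must infer.
    """
    labels = tuple(vectors)
    if len(labels) < 2:
        raise ValueError("need at least two vectors")
    stack = np.array([np.asarray(vectors[lab], dtype=np.float64).ravel() for lab in labels])
    if len({row.size for row in stack}) > 1:
        raise ValueError("vectors must share one length")
    if method == "pearson":
        if np.any(stack.std(axis=1) == 0):
            constant = [lab for lab, row in zip(labels, stack) if row.std() == 0]
            raise ValueError(f"constant vector(s) under pearson: {constant}")
        matrix = np.corrcoef(stack)
    elif method == "cosine":
        norms = np.linalg.norm(stack, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero vector under cosine")
        unit = stack / norms[:, None]
        matrix = unit @ unit.T
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(matrix, 1.0)
    return labels, matrix


def _distractor_prototypes(
    table,
    unseen_prototypes: Sequence[ClassPrototype],
    mode: str,
    k: int,
    rng: np.random.Generator,
) -> list[ClassPrototype]:
    """Pick k distractor prototypes from an embedding table.

    Tokens that normalize to any true label's tokens are never eligible — a
    distractor must be incorrect by construction.
    """
    true_tokens = set()
    for p in unseen_prototypes:
        true_tokens.update(tokenize_label(p.label))
    eligible = [t for t in table.tokens if t not in true_tokens]
    if mode == "random":
        if k > len(eligible):
            raise ValueError(f"k={k} exceeds eligible vocabulary ({len(eligible)})")
        chosen = list(rng.choice(len(eligible), size=k, replace=False))
        return [ClassPrototype(eligible[i], table[eligible[i]]) for i in chosen]
    if mode == "knn":
        # k nearest eligible tokens of EACH unseen prototype
        out: dict[str, ClassPrototype] = {}
        vectors = np.array([table[t] for t in eligible])
        norms = np.linalg.norm(vectors, axis=1)
        ok = norms > 0
        for proto in unseen_prototypes:
            q = proto.unit_vector
            sims = np.full(len(eligible), -np.inf)
            sims[ok] = (vectors[ok] @ q) / norms[ok]
            if k > int(ok.sum()):
                raise ValueError(f"k={k} exceeds eligible vocabulary ({int(ok.sum())})")
            for i in np.argsort(-sims)[:k]:
                token = eligible[i]
                out[token] = ClassPrototype(token, table[token])
        return list(out.values())
    raise ValueError(f"unknown distractor mode {mode!r}")


def evaluate_with_distractors(
    network,
    xts: FeatureMatrix,
    unseen_prototypes: Sequence[ClassPrototype],
    table,
    *,
    distractor_counts: Sequence[int] = (0, 5, 10, 20),
    mode: str = "random",
    seed: int = 0,
) -> dict[int, float]:
    """Zero-shot accuracy as the candidate set is inflated with distractors.

    The candidate prototypes are the true unseen classes plus ``k`` distractor
    words drawn from the embedding table — uniformly at random (``random``
    mode, seeded) or as each prototype's nearest vocabulary neighbors
    (``knn`` mode, the hard setting).  A robust semantic space keeps accuracy
    nearly flat in random mode.  Returns {distractor count: accuracy}.
    """
    truth = list(xts.row_labels)
    results: dict[int, float] = {}
    for k in distractor_counts:
        rng = np.random.default_rng(seed)
        candidates = list(unseen_prototypes)
        if k:
            candidates += _distractor_prototypes(table, unseen_prototypes, mode, k, rng)
        predicted = network.predict_zero_shot(xts, candidates)
        results[int(k)] = float(np.mean([p == t for p, t in zip(predicted, truth)]))
    return results


def write_metrics_table(
    cm: ConfusionMatrix, sink: TextIO, *, sep: str = "\t", places: int = 2
) -> None:
    """Export per-class metrics as delimited text in the published layout:
    class, N classified, N truth, accuracy, precision, recall, F-measure."""
    header = ["Class", "N (Classified)", "N (Truth)", "Accuracy",
              "Precision", "Recall", "F-Measure"]
    sink.write(sep.join(header) + "\n")
    for label, m in class_metrics(cm).items():
        r = m.rounded(places)
        sink.write(sep.join([
            label, str(m.n_classified), str(m.n_truth),
            f"{r['accuracy']:g}", f"{r['precision']:g}",
            f"{r['recall']:g}", f"{r['f_measure']:g}",
        ]) + "\n")
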