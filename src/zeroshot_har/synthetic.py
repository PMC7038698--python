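"""Synthetic smart-home streams and toy embedding tables for end-to-end tests.

The generator emulates the data regime the method assumes: a home
instrumented with binary sensors, activities whose per-sensor activation
profiles differ, and an annotated event log segmented into labeled
instances.  Per instance, each sensor's ON count is Poisson at the profile's
rate; every ON is paired with a later OFF (which the featurizer must
ignore), timestamps strictly increase, and the instance is wrapped in
begin/end annotations — so synthetic runs exercise the real text I/O paths.

Toy embedding tables mirror the geometry that makes zero-shot transfer
possible: seen-class prototypes are mutually orthogonal unit vectors and
each unseen prototype is a convex combination of seen prototypes (plus
optional isotropic noise).  A *congruent* scenario uses the same mixing
weights for the unseen classes' feature profiles as for their prototypes —
the condition under which nearest-prototype matching can succeed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

from zeroshot_har.casas import ActivityInstance, SensorEvent, format_event
from zeroshot_har.semantic import ClassPrototype, EmbeddingTable

__all__ = [
    "ActivityProfile",
    "SyntheticScenario",
    "generate_stream",
    "make_toy_embeddings",
    "make_congruent_scenario",
]

_EPOCH = datetime(2012, 7, 18, 8, 0, 0)


@dataclass(frozen=True)
class ActivityProfile:
    """Expected per-sensor ON counts for one activity.

    ``rates[j]`` is the Poisson mean of sensor ``sensor_ids[j]``'s activation
    count in a single instance; ``n_instances`` instances are generated;
    ``mean_gap_s`` is the mean spacing between consecutive events (seconds).
    """

    label: str
    sensor_ids: tuple[str, ...]
    rates: tuple[float, ...]
    n_instances: int = 1
    mean_gap_s: float = 5.0

    def __post_init__(self) -> None:
        if len(self.sensor_ids) != len(self.rates):
            raise ValueError("one rate per sensor required")
        rates = np.asarray(self.rates, dtype=float)
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise ValueError("rates must be finite and non-negative")
        if not np.any(rates > 0):
            raise ValueError("at least one positive rate required")


@dataclass(frozen=True)
class SyntheticScenario:
    """A full zero-shot study design: profiles, mixing matrix, geometry, seed."""

    seen_profiles: tuple[ActivityProfile, ...]
    unseen_profiles: tuple[ActivityProfile, ...]
    mixing: np.ndarray  # K_unseen x K_seen, rows convex
    embedding_dim: int = 16
    noise_scale: float = 0.0
    seed: int = 0
    drawn_counts: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        mix = np.asarray(self.mixing, dtype=float)
        if mix.shape != (len(self.unseen_profiles), len(self.seen_profiles)):
            raise ValueError("mixing must be K_unseen x K_seen")
        if np.any(mix < 0) or not np.allclose(mix.sum(axis=1), 1.0):
            raise ValueError("mixing rows must be convex (non-negative, sum 1)")
        seen = {p.label for p in self.seen_profiles}
        unseen = {p.label for p in self.unseen_profiles}
        if seen & unseen:
            raise ValueError(f"seen/unseen labels overlap: {sorted(seen & unseen)}")

    @property
    def seen_labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.seen_profiles)

    @property
    def unseen_labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.unseen_profiles)


def generate_stream(
    profiles: Sequence[ActivityProfile],
    seed: int,
    *,
    start: datetime = _EPOCH,
) -> tuple[str, list[ActivityInstance], dict[tuple[str, int], np.ndarray]]:
    """Simulate an annotated event log.

    Returns ``(log_text, instances, drawn_counts)`` where ``drawn_counts``
    maps ``(label, instance index)`` to the exact Poisson count vector drawn,
    so featurization can be checked for exact count recovery.  Instances are
    emitted profile by profile; within an instance, activations of different
    sensors are interleaved in random order and each ON is followed by its
    OFF.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    clock = start
    events: list[SensorEvent] = []
    instances: list[ActivityInstance] = []
    drawn: dict[tuple[str, int], np.ndarray] = {}

    def tick(mean_gap: float) -> datetime:
        nonlocal clock
        # strictly increasing: exponential gap with a 1 ms floor
        clock = clock + timedelta(seconds=float(rng.exponential(mean_gap)) + 0.001)
        return clock

    for profile in profiles:
        off_state = {"D": "CLOSE"}  # door sensors close, everything else turns OFF
        for i in range(profile.n_instances):
            counts = rng.poisson(profile.rates)
            while counts.sum() == 0:  # an instance needs >=1 event to annotate
                counts = rng.poisson(profile.rates)
            drawn[(profile.label, i)] = counts.copy()
            activations = [
                sid for sid, c in zip(profile.sensor_ids, counts) for _ in range(int(c))
            ]
            order = rng.permutation(len(activations))
            pair_events: list[SensorEvent] = []
            for j in order:
                sid = activations[j]
                on_msg, off_msg = ("OPEN", "CLOSE") if sid[0] in off_state else ("ON", "OFF")
                pair_events.append(SensorEvent(tick(profile.mean_gap_s), sid, on_msg))
                pair_events.append(SensorEvent(tick(profile.mean_gap_s), sid, off_msg))
            first = pair_events[0]
            last = pair_events[-1]
            pair_events[0] = SensorEvent(
                first.timestamp, first.sensor_id, first.message,
                (profile.label, "begin"),
            )
            pair_events[-1] = SensorEvent(
                last.timestamp, last.sensor_id, last.message,
                (profile.label, "end"),
            )
            events.extend(pair_events)
            instances.append(
                ActivityInstance(
                    profile.label, tuple(pair_events),
                    pair_events[0].timestamp, pair_events[-1].timestamp,
                )
            )
            tick(60.0)  # quiet gap between instances

    buf = io.StringIO()
    for e in events:
        buf.write(format_event(e) + "\n")
    return buf.getvalue(), instances, drawn


def make_toy_embeddings(
    scenario: SyntheticScenario,
) -> tuple[EmbeddingTable, list[ClassPrototype], list[ClassPrototype]]:
    """Build a toy word-embedding table realizing the scenario's geometry.

    Seen prototypes are mutually orthogonal unit vectors (a seeded random
    orthonormal frame); unseen prototype *u* is the normalized
    ``mixing[u] @ seen`` combination plus isotropic Gaussian noise of scale
    ``noise_scale``.  Tokens are the lower-cased labels, so
    ``label_to_prototype`` resolves them through the normal lookup path.
    """
    k_seen = len(scenario.seen_profiles)
    d = scenario.embedding_dim
    if d < k_seen:
        raise ValueError(f"embedding dimension {d} < number of seen classes {k_seen}")
    rng = np.random.default_rng(scenario.seed)
    frame, _ = np.linalg.qr(rng.normal(size=(d, d)))
    seen_vecs = frame[:, :k_seen].T  # K_seen orthonormal rows
    mix = np.asarray(scenario.mixing, dtype=float)
    unseen_raw = mix @ seen_vecs
    if scenario.noise_scale > 0:
        unseen_raw = unseen_raw + rng.normal(
            scale=scenario.noise_scale, size=unseen_raw.shape
        )
    unseen_vecs = unseen_raw / np.linalg.norm(unseen_raw, axis=1, keepdims=True)

    vectors: dict[str, np.ndarray] = {}
    seen_protos, unseen_protos = [], []
    for label, vec in zip(scenario.seen_labels, seen_vecs):
        vectors[label.lower()] = vec
        seen_protos.append(ClassPrototype(label, vec))
    for label, vec in zip(scenario.unseen_labels, unseen_vecs):
        vectors[label.lower()] = vec
        unseen_protos.append(ClassPrototype(label, vec))
    # filler tokens give the distractor experiment a vocabulary to draw from
    n_filler = max(4 * (k_seen + len(unseen_protos)), 32)
    filler = rng.normal(size=(n_filler, d))
    filler /= np.linalg.norm(filler, axis=1, keepdims=True)
    for i, vec in enumerate(filler):
        vectors[f"word{i:03d}"] = vec
    return EmbeddingTable(vectors), seen_protos, unseen_protos


def make_congruent_scenario(
    k_seen: int = 5,
    k_unseen: int = 3,
    n_sensors: int = 30,
    *,
    separation: float = 10.0,
    baseline_rate: float = 0.5,
    train_instances_per_class: int = 60,
    test_instances: int = 200,
    embedding_dim: int = 16,
    noise_scale: float = 0.0,
    seed: int = 0,
    permutation: Sequence[int] | None = None,
) -> SyntheticScenario:
    """Design a scenario in which zero-shot transfer should succeed.

    Each seen class dominates a disjoint block of sensors (expected
    ``separation`` ONs per instance there, ``baseline_rate`` elsewhere).
    Unseen class *u*'s feature profile is the convex combination
    ``mixing[u] @ seen_profiles`` with the SAME weights that build its
    prototype from the seen prototypes — feature-space and semantic-space
    geometry are congruent.  Mixing rows pair consecutive seen classes with
    weights (2/3, 1/3), which keeps unseen classes well separated from one
    another.

    ``permutation`` (a reordering of the unseen rows) misaligns the feature
    mixing from the prototype mixing and serves as the negative control: the
    congruence is broken, so accuracy collapses toward or below chance.
    """
    if k_seen < 2 or k_unseen < 1:
        raise ValueError("need k_seen >= 2 and k_unseen >= 1")
    if n_sensors < k_seen:
        raise ValueError(f"n_sensors ({n_sensors}) must be >= k_seen ({k_seen})")
    sensor_ids = tuple(f"M{j:03d}" for j in range(1, n_sensors + 1))
    block = n_sensors // k_seen
    seen_rates = np.full((k_seen, n_sensors), baseline_rate)
    for k in range(k_seen):
        lo = k * block
        hi = (k + 1) * block if k < k_seen - 1 else n_sensors
        seen_rates[k, lo:hi] = separation

    mixing = np.zeros((k_unseen, k_seen))
    for u in range(k_unseen):
        mixing[u, u % k_seen] = 2 / 3
        mixing[u, (u + 1) % k_seen] = 1 / 3

    feature_mixing = mixing
    if permutation is not None:
        perm = list(permutation)
        if sorted(perm) != list(range(k_unseen)):
            raise ValueError("permutation must reorder range(k_unseen)")
        feature_mixing = mixing[perm]
    unseen_rates = feature_mixing @ seen_rates

    per_unseen = [test_instances // k_unseen] * k_unseen
    for u in range(test_instances % k_unseen):
        per_unseen[u] += 1

    seen_profiles = tuple(
        ActivityProfile(
            f"Seen{k}", sensor_ids, tuple(seen_rates[k]), train_instances_per_class
        )
        for k in range(k_seen)
    )
    unseen_profiles = tuple(
        ActivityProfile(f"Unseen{u}", sensor_ids, tuple(unseen_rates[u]), per_unseen[u])
        for u in range(k_unseen)
    )
    return SyntheticScenario(
        seen_profiles, unseen_profiles, mixing,
        embedding_dim=embedding_dim, noise_scale=noise_scale, seed=seed,
    )
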