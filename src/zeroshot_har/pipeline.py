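"""End-to-end orchestration: config validation, staging, reproducible runs.

A scenario declares disjoint seen (training) and unseen (zero-shot) activity
label sets, the data source (a CASAS log on disk or the synthetic
generator), and the embedding source (a word2vec text file or the toy
table).  ``run_pipeline`` executes parse -> segment -> featurize (vocabulary
and scaler fitted on seen data only) -> build/train -> zero-shot predict ->
evaluate, and writes every artifact plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from zeroshot_har import casas, features, semantic, synthetic
from zeroshot_har.evaluation import (
    ConfusionMatrix,
    class_metrics,
    confusion,
    correlation_matrix,
    write_metrics_table,
)
from zeroshot_har.network import NetworkConfig, ZeroShotNetwork

logger = logging.getLogger("zeroshot_har")

__all__ = ["ScenarioConfig", "PipelineResult", "run_pipeline"]


class ConfigError(ValueError):
    """The scenario configuration is invalid (caught before any compute)."""


@dataclass
class ScenarioConfig:
    """Declarative description of one zero-shot experiment."""

    seen_labels: tuple[str, ...]
    unseen_labels: tuple[str, ...]
    dataset_path: str | None = None  # CASAS log; None -> synthetic
    embedding_path: str | None = None  # word2vec text; None -> toy table
    simulate: dict = field(default_factory=dict)  # make_congruent_scenario kwargs
    network: dict = field(default_factory=dict)  # NetworkConfig overrides
    standardize: bool = True
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        overlap = set(self.seen_labels) & set(self.unseen_labels)
        if overlap:
            raise ConfigError(
                f"seen and unseen label sets must be disjoint; both contain "
                f"{sorted(overlap)}"
            )
        if not self.seen_labels or not self.unseen_labels:
            raise ConfigError("both seen and unseen label sets must be non-empty")
        if self.dataset_path is not None and not Path(self.dataset_path).exists():
            raise ConfigError(f"dataset not found: {self.dataset_path}")
        if self.embedding_path is not None and not Path(self.embedding_path).exists():
            raise ConfigError(f"embedding table not found: {self.embedding_path}")

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        raw["seen_labels"] = tuple(raw.get("seen_labels", ()))
        raw["unseen_labels"] = tuple(raw.get("unseen_labels", ()))
        return cls(**raw)

    def manifest(self) -> dict:
        body = {
            "seen_labels": list(self.seen_labels),
            "unseen_labels": list(self.unseen_labels),
            "dataset_path": self.dataset_path,
            "embedding_path": self.embedding_path,
            "simulate": self.simulate,
            "network": self.network,
            "standardize": self.standardize,
            "seed": self.seed,
        }
        digest = hashlib.sha256(
            json.dumps(body, sort_keys=True).encode()
        ).hexdigest()
        return {**body, "config_sha256": digest}


@dataclass
class PipelineResult:
    """Everything ``run_pipeline`` computes, ready for inspection or export."""

    confusion: ConfusionMatrix
    metrics: dict
    zero_shot_accuracy: float
    training_report: object
    network: ZeroShotNetwork
    seen_feature_correlation: tuple
    prototype_correlation: tuple
    manifest: dict


def _load_instances(config: ScenarioConfig):
    """Instances + (optionally) a toy embedding table from file or simulation."""
    if config.dataset_path is not None:
        with open(config.dataset_path) as fh:
            events = casas.parse_events(fh)
        instances = casas.segment_instances(events)
        return instances, None, None
    sim = dict(config.simulate)
    sim.setdefault("seed", config.seed)
    scenario = synthetic.make_congruent_scenario(**sim)
    stream, instances, _ = synthetic.generate_stream(
        scenario.seen_profiles + scenario.unseen_profiles, scenario.seed
    )
    # run the generated text through the real parser — the I/O path is the test
    instances = casas.segment_instances(casas.parse_events(io.StringIO(stream)))
    table, seen_protos, unseen_protos = synthetic.make_toy_embeddings(scenario)
    return instances, scenario, table


def run_pipeline(config: ScenarioConfig) -> PipelineResult:
    """Execute one full zero-shot experiment; see the module docstring."""
    config.validate()
    instances, scenario, toy_table = _load_instances(config)

    seen_set, unseen_set = set(config.seen_labels), set(config.unseen_labels)
    train_instances = [i for i in instances if i.label in seen_set]
    test_instances = [i for i in instances if i.label in unseen_set]
    if not train_instances:
        raise ConfigError("no instances carry a seen label")
    if not test_instances:
        raise ConfigError("no instances carry an unseen label")
    logger.info(
        "segmented %d instances: %d train (%d seen classes), %d test (%d unseen)",
        len(instances), len(train_instances), len(seen_set),
        len(test_instances), len(unseen_set),
    )

    # featurize — vocabulary and scaler from seen data only
    vocabulary = features.build_vocabulary(train_instances)
    raw_train = features.build_feature_matrix(train_instances, vocabulary)
    scaler = features.fit_scaler(raw_train) if config.standardize else None
    xtr = features.build_feature_matrix(train_instances, vocabulary, scaler=scaler)
    xts = features.build_feature_matrix(test_instances, vocabulary, scaler=scaler)
    logger.info("feature matrix: %d sensors; train %dx%d, test %dx%d",
                len(vocabulary), xtr.m, xtr.n, xts.m, xts.n)

    # semantic prototypes
    if config.embedding_path is not None:
        with open(config.embedding_path) as fh:
            table = semantic.load_embeddings(fh)
    elif toy_table is not None:
        table = toy_table
    else:
        raise ConfigError("a dataset run needs embedding_path")
    try:
        seen_protos = semantic.prototypes_for_labels(config.seen_labels, table)
        unseen_protos = semantic.prototypes_for_labels(config.unseen_labels, table)
    except KeyError as exc:
        raise ConfigError(str(exc)) from exc

    net_kwargs = dict(config.network)
    net_kwargs.setdefault("input_dim", xtr.n)
    net_kwargs.setdefault("hidden2", table.dimension)
    net_kwargs.setdefault("seed", config.seed)
    net_config = NetworkConfig(**net_kwargs)
    network = ZeroShotNetwork(net_config, seen_protos)
    report = network.train(xtr)
    logger.info("trained %d epochs; final seen-class accuracy %.3f",
                len(report.epoch_losses), report.final_train_accuracy)

    predicted = network.predict_zero_shot(xts, unseen_protos)
    cm = confusion(list(xts.row_labels), predicted, list(config.unseen_labels))
    metrics = class_metrics(cm)
    accuracy = cm.micro_accuracy
    logger.info("zero-shot accuracy %.3f over %d instances", accuracy, cm.total)

    # correlation analyses: seen/unseen feature centroids and prototypes
    centroids = {}
    for label in [*config.seen_labels, *config.unseen_labels]:
        rows = [r for r, lab in zip(np.asarray(raw_train.values), raw_train.row_labels)
                if lab == label]
        rows += [
            features.count_on_events(i, vocabulary)
            for i in test_instances if i.label == label
        ]
        if rows:
            centroids[label] = np.mean(rows, axis=0)
    feat_corr = correlation_matrix(centroids, method="pearson")
    proto_corr = correlation_matrix(
        {p.label: p.vector for p in [*seen_protos, *unseen_protos]}, method="cosine"
    )

    result = PipelineResult(
        confusion=cm,
        metrics=metrics,
        zero_shot_accuracy=accuracy,
        training_report=report,
        network=network,
        seen_feature_correlation=feat_corr,
        prototype_correlation=proto_corr,
        manifest=config.manifest(),
    )
    if config.output_dir is not None:
        _write_artifacts(result, cm, scaler, Path(config.output_dir))
    return result


def _write_artifacts(result: PipelineResult, cm: ConfusionMatrix, scaler, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    with open(out / "confusion.tsv", "w") as fh:
        fh.write("\t".join(["truth\\predicted", *cm.labels]) + "\n")
        for label, row in zip(cm.labels, cm.counts):
            fh.write("\t".join([label, *map(str, row)]) + "\n")
    with open(out / "metrics.tsv", "w") as fh:
        write_metrics_table(cm, fh)
    with open(out / "model.json", "w") as fh:
        result.network.save(fh, scaler=scaler)
    for name, (labels, matrix) in (
        ("correlation_features.tsv", result.seen_feature_correlation),
        ("correlation_prototypes.tsv", result.prototype_correlation),
    ):
        with open(out / name, "w") as fh:
            fh.write("\t".join(["", *labels]) + "\n")
            for label, row in zip(labels, matrix):
                fh.write("\t".join([label, *(f"{v:.6f}" for v in row)]) + "\n")
    logger.info("artifacts written to %s", out)
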