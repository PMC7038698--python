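"""The shallow zero-shot network with a frozen word-embedding output layer.

Architecture (four layers): input (n sensor counts) -> dense 128, SELU ->
dense 300, SELU -> fixed multiplication by the matrix ``W`` whose columns are
the L2-normalized word-embedding prototypes of the *seen* classes -> softmax
over the seen classes.  ``W`` is initialized from the seen-class word vectors
and is never trainable: the layer is a plain matrix product, so the 300-unit
activation feeding it is the network's image of an input in the semantic word
space.  Training minimizes categorical cross-entropy with Adam; optional
batch normalization follows each hidden layer.

Zero-shot recognition takes the 300-dim embedding of a test instance and
assigns the unseen class whose prototype is nearest in cosine similarity.

Implemented directly on numpy: the model is a pair of dense layers plus a
frozen matmul, small enough that explicit forward/backward passes are clearer
(and easier to verify against hand-computed oracles) than a framework graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence, TextIO

import numpy as np

from zeroshot_har.features import FeatureMatrix
from zeroshot_har.semantic import ClassPrototype, nearest_prototype

__all__ = ["NetworkConfig", "TrainingReport", "ZeroShotNetwork", "grid_search"]

# SELU constants (self-normalizing networks); selu(x) = scale*(x>0 ? x : alpha*(e^x-1))
_SELU_ALPHA = 1.6732632423543772848170429916717
_SELU_SCALE = 1.0507009873554804934193349852946

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def _selu(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * (np.exp(z) - 1.0))


def _selu_grad(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the shallow network.

    ``hidden2`` must equal the embedding dimension ``L`` (300 for the
    Google-News vectors) — it is the layer whose activation lives in the
    semantic space.  Defaults: Adam at 1e-3, batch size 32, 200 epochs,
    batch normalization after each hidden layer.
    """

    input_dim: int
    hidden1: int = 128
    hidden2: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 200
    batch_norm: bool = True
    loss: str = "softmax"  # or "regression": MSE straight to the prototype
    class_weighting: bool = False  # inverse-frequency loss weights
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if self.epochs < 1:
            raise ValueError("epoch count must be >= 1")
        if self.loss not in ("softmax", "regression"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainingReport:
    """Per-epoch mean loss and the final accuracy on the seen classes."""

    epoch_losses: list[float] = field(default_factory=list)
    final_train_accuracy: float = float("nan")


class _BatchNorm:
    """Per-feature batch normalization with running inference statistics."""

    def __init__(self, width: int):
        self.gamma = np.ones(width)
        self.beta = np.zeros(width)
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self._cache: tuple[np.ndarray, np.ndarray] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mean
            self.running_var = _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        assert self._cache is not None, "backward before forward(training=True)"
        xhat, inv_std = self._cache
        b = dy.shape[0]
        dgamma = (dy * xhat).sum(axis=0)
        dbeta = dy.sum(axis=0)
        dx = (self.gamma * inv_std / b) * (b * dy - dbeta - xhat * dgamma)
        return dx, dgamma, dbeta


class _Adam:
    """Adam with bias correction, one slot per named parameter."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, g in grads.items():
            m = self.m.setdefault(name, np.zeros_like(g))
            v = self.v.setdefault(name, np.zeros_like(g))
            m[:] = self.beta1 * m + (1 - self.beta1) * g
            v[:] = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ZeroShotNetwork:
    """Shallow semantic-output network; see the module docstring."""

    def __init__(self, config: NetworkConfig, seen_prototypes: Sequence[ClassPrototype]):
        if len(seen_prototypes) < 2:
            raise ValueError("need at least two seen classes")
        dims = {p.vector.size for p in seen_prototypes}
        if dims != {config.hidden2}:
            raise ValueError(
                f"hidden2 ({config.hidden2}) must equal prototype dimension {dims}"
            )
        labels = [p.label for p in seen_prototypes]
        if len(set(labels)) != len(labels):
            raise ValueError("seen-class labels must be unique")
        self.config = config
        self.seen_labels: tuple[str, ...] = tuple(labels)
        # frozen output layer: columns are unit-norm seen prototypes (L x K)
        self.W_out = np.column_stack([p.unit_vector for p in seen_prototypes])
        self.W_out.setflags(write=False)

        rng = np.random.default_rng(config.seed)
        n, h1, h2 = config.input_dim, config.hidden1, config.hidden2
        # LeCun-normal initialization, the convention paired with SELU
        self.params: dict[str, np.ndarray] = {
            "W1": rng.normal(0.0, 1.0 / np.sqrt(n), size=(n, h1)),
            "b1": np.zeros(h1),
            "W2": rng.normal(0.0, 1.0 / np.sqrt(h1), size=(h1, h2)),
            "b2": np.zeros(h2),
        }
        self.bn1 = _BatchNorm(h1) if config.batch_norm else None
        self.bn2 = _BatchNorm(h2) if config.batch_norm else None
        self._rng = rng

    # ------------------------------------------------------------------ forward

    def _forward(self, x: np.ndarray, training: bool) -> dict[str, np.ndarray]:
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input must be (batch, {self.config.input_dim}), got {x.shape}"
            )
        p = self.params
        z1 = x @ p["W1"] + p["b1"]
        a1 = _selu(z1)
        h1 = self.bn1.forward(a1, training) if self.bn1 else a1
        z2 = h1 @ p["W2"] + p["b2"]
        a2 = _selu(z2)
        emb = self.bn2.forward(a2, training) if self.bn2 else a2
        logits = emb @ self.W_out
        return {"x": x, "z1": z1, "h1": h1, "z2": z2, "emb": emb, "logits": logits}

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Map feature vectors into the semantic word space.

        Returns the activation of the 300-unit layer — the representation
        immediately before the frozen prototype multiplication.  Accepts a
        single vector (returns shape ``(L,)``) or a batch (``(B, L)``).
        Inference mode: batch normalization uses running statistics, so the
        result is deterministic and batch-independent.
        """
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        emb = self._forward(x, training=False)["emb"]
        return emb[0] if single else emb

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax distribution over the *seen* classes (inference mode)."""
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        probs = _softmax(self._forward(x, training=False)["logits"])
        return probs[0] if single else probs

    # ------------------------------------------------------------------- train

    def train(self, xtr: FeatureMatrix, seen_labels: Sequence[str] | None = None) -> TrainingReport:
        """Fit the trainable layers on seen-class data; ``W_out`` stays frozen.

        Every row label of ``xtr`` must belong to the seen-class set declared
        at construction (a leakage guard: zero-shot classes may never appear
        here).  Deterministic for a fixed config seed.
        """
        allowed = set(self.seen_labels if seen_labels is None else seen_labels)
        if not allowed.issubset(self.seen_labels):
            raise ValueError("seen_labels must be a subset of the network's classes")
        stray = [lab for lab in xtr.row_labels if lab not in allowed]
        if stray:
            raise ValueError(
                f"training rows carry non-seen labels (leakage?): {sorted(set(stray))}"
            )
        x = np.asarray(xtr.values, dtype=np.float64)
        label_index = {lab: k for k, lab in enumerate(self.seen_labels)}
        y_idx = np.array([label_index[lab] for lab in xtr.row_labels])
        k = len(self.seen_labels)
        y_onehot = np.eye(k)[y_idx]
        targets = self.W_out.T[y_idx]  # per-row prototype, for the regression loss

        weights = np.ones(len(y_idx))
        if self.config.class_weighting:
            counts = np.bincount(y_idx, minlength=k).astype(float)
            counts[counts == 0] = 1.0
            per_class = counts.sum() / (k * counts)
            weights = per_class[y_idx]

        adam = _Adam(self.config.learning_rate)
        report = TrainingReport()
        m = x.shape[0]
        batch = min(self.config.batch_size, m)
        for _ in range(self.config.epochs):
            order = self._rng.permutation(m)
            epoch_loss = 0.0
            for start in range(0, m, batch):
                idx = order[start : start + batch]
                cache = self._forward(x[idx], training=True)
                w = weights[idx][:, None]
                if self.config.loss == "softmax":
                    probs = _softmax(cache["logits"])
                    eps = 1e-12
                    loss = float(
                        -(w.ravel() * np.log(probs[np.arange(len(idx)), y_idx[idx]] + eps)).sum()
                    )
                    dlogits = w * (probs - y_onehot[idx]) / len(idx)
                    demb = dlogits @ self.W_out.T
                else:  # regression straight to the seen prototype
                    diff = cache["emb"] - targets[idx]
                    loss = float((w * diff * diff).sum())
                    demb = 2.0 * w * diff / len(idx)
                epoch_loss += loss
                grads = self._backward(cache, demb)
                adam.step(self.params, grads["dense"])
                if self.bn1 is not None:
                    adam.step(
                        {
                            "bn1.gamma": self.bn1.gamma,
                            "bn1.beta": self.bn1.beta,
                            "bn2.gamma": self.bn2.gamma,
                            "bn2.beta": self.bn2.beta,
                        },
                        {
                            "bn1.gamma": grads["bn1"][0],
                            "bn1.beta": grads["bn1"][1],
                            "bn2.gamma": grads["bn2"][0],
                            "bn2.beta": grads["bn2"][1],
                        },
                    )
            report.epoch_losses.append(epoch_loss / m)
        predicted = self.predict_proba(x).argmax(axis=1)
        report.final_train_accuracy = float((predicted == y_idx).mean())
        return report

    def _backward(
        self, cache: dict[str, np.ndarray], demb: np.ndarray
    ) -> dict[str, object]:
        p = self.params
        grads: dict[str, object] = {}
        if self.bn2 is not None:
            da2, dg2, db2_ = self.bn2.backward(demb)
            grads["bn2"] = (dg2, db2_)
        else:
            da2 = demb
        dz2 = da2 * _selu_grad(cache["z2"])
        dW2 = cache["h1"].T @ dz2
        db2 = dz2.sum(axis=0)
        dh1 = dz2 @ p["W2"].T
        if self.bn1 is not None:
            da1, dg1, db1_ = self.bn1.backward(dh1)
            grads["bn1"] = (dg1, db1_)
        else:
            da1 = dh1
        dz1 = da1 * _selu_grad(cache["z1"])
        dW1 = cache["x"].T @ dz1
        db1 = dz1.sum(axis=0)
        grads["dense"] = {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}
        return grads

    # ------------------------------------------------------------ zero-shot use

    def predict_zero_shot(
        self, xts: FeatureMatrix, unseen_prototypes: Sequence[ClassPrototype]
    ) -> list[str]:
        """Label each test row with its nearest unseen prototype in cosine space.

        Equivalent to :meth:`embed` followed by
        :func:`~zeroshot_har.semantic.nearest_prototype`, row by row.  The
        unseen label set must be disjoint from the seen classes.
        """
        if not unseen_prototypes:
            raise ValueError("unseen prototype set must be non-empty")
        overlap = {p.label for p in unseen_prototypes} & set(self.seen_labels)
        if overlap:
            raise ValueError(f"unseen labels overlap seen classes: {sorted(overlap)}")
        embeddings = self.embed(np.asarray(xts.values, dtype=np.float64))
        return [nearest_prototype(e, unseen_prototypes)[0] for e in embeddings]

    # ---------------------------------------------------------------- persist

    def save(self, sink: TextIO, *, scaler=None) -> None:
        """Write a JSON checkpoint: config, weights, frozen matrix, label order.

        ``scaler`` (a fitted per-column standardizer) is stored alongside so a
        reloaded model featurizes exactly as the trained one.  JSON float
        serialization round-trips IEEE doubles, so reload is bit-exact.
        """
        state = {
            "config": asdict(self.config),
            "seen_labels": list(self.seen_labels),
            "W_out": self.W_out.tolist(),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        for name, bn in (("bn1", self.bn1), ("bn2", self.bn2)):
            if bn is not None:
                state[name] = {
                    "gamma": bn.gamma.tolist(),
                    "beta": bn.beta.tolist(),
                    "running_mean": bn.running_mean.tolist(),
                    "running_var": bn.running_var.tolist(),
                }
        if scaler is not None:
            state["scaler"] = {
                "mean": np.asarray(scaler.mean_).tolist(),
                "scale": np.asarray(scaler.scale_).tolist(),
            }
        json.dump(state, sink)

    @classmethod
    def load(cls, source: TextIO) -> tuple["ZeroShotNetwork", object | None]:
        """Reload a checkpoint; returns ``(network, scaler_or_None)``."""
        from sklearn.preprocessing import StandardScaler

        state = json.load(source)
        config = NetworkConfig(**state["config"])
        w_out = np.array(state["W_out"], dtype=np.float64)
        protos = [
            ClassPrototype(label, w_out[:, k])
            for k, label in enumerate(state["seen_labels"])
        ]
        net = cls(config, protos)
        for k, v in state["params"].items():
            net.params[k] = np.array(v, dtype=np.float64)
        for name, bn in (("bn1", net.bn1), ("bn2", net.bn2)):
            if bn is not None and name in state:
                bn.gamma = np.array(state[name]["gamma"])
                bn.beta = np.array(state[name]["beta"])
                bn.running_mean = np.array(state[name]["running_mean"])
                bn.running_var = np.array(state[name]["running_var"])
        scaler = None
        if "scaler" in state:
            scaler = StandardScaler()
            scaler.mean_ = np.array(state["scaler"]["mean"])
            scaler.scale_ = np.array(state["scaler"]["scale"])
            scaler.var_ = scaler.scale_**2
            scaler.n_features_in_ = scaler.mean_.size
            scaler.with_mean = scaler.with_std = True
        return net, scaler


def grid_search(
    grid: dict[str, list],
    xtr: FeatureMatrix,
    seen_prototypes: Sequence[ClassPrototype],
    *,
    validation_fraction: float = 0.25,
    seed: int = 0,
    base_config: dict | None = None,
) -> tuple[NetworkConfig, list[tuple[NetworkConfig, float]]]:
    """Small hyperparameter search scored by held-out seen-class accuracy.

    ``grid`` maps :class:`NetworkConfig` field names to candidate values; all
    combinations are tried on a seeded train/validation split of the seen
    data.  Returns the best config and every (config, accuracy) pair.
    """
    from sklearn.model_selection import ParameterGrid, train_test_split

    base = dict(base_config or {})
    base.setdefault("input_dim", xtr.n)
    idx = np.arange(xtr.m)
    labels = np.array(xtr.row_labels)
    train_idx, val_idx = train_test_split(
        idx, test_size=validation_fraction, random_state=seed, stratify=labels
    )
    results: list[tuple[NetworkConfig, float]] = []
    for point in ParameterGrid(grid):
        config = NetworkConfig(**{**base, **point, "seed": seed})
        net = ZeroShotNetwork(config, seen_prototypes)
        sub = FeatureMatrix(
            xtr.values[train_idx], tuple(labels[train_idx]), xtr.vocabulary
        )
        net.train(sub)
        probs = net.predict_proba(np.asarray(xtr.values[val_idx], dtype=np.float64))
        predicted = [net.seen_labels[k] for k in probs.argmax(axis=1)]
        accuracy = float(np.mean([p == t for p, t in zip(predicted, labels[val_idx])]))
        results.append((config, accuracy))
    best = max(results, key=lambda item: item[1])[0]
    return best, results
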