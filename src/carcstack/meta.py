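"""The neural meta-classifier over model-level representations.

A three-layer network maps a compound's vector of base-classifier
probabilities to a carcinogenicity probability:

    input (n selected classifiers)
      -> dense (10 units) -> batch norm -> ReLU -> dropout (0.5)
      -> dense (1 unit) -> sigmoid

trained with plain stochastic gradient descent (momentum) on binary
cross-entropy. The network is implemented directly in NumPy: it is tiny, and
owning the forward/backward pass keeps training bit-reproducible under a
seed. Batch normalization keeps exponential running moments for inference;
dropout is inverted (activations rescaled at train time) and inactive at
prediction time, so inference is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np

from .base_ensemble import ModelLevelRepresentation

_EPS = 1e-5


@dataclass
class MetaNetworkConfig:
    """Architecture and optimization settings for the meta network.

    Only ``input_dim`` is data-dependent; the remaining defaults are
    conventional small-network settings and are all recorded with the model.
    """

    input_dim: int
    hidden_units: int = 10
    dropout_rate: float = 0.5
    batch_norm: bool = True
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 32
    patience: int = 20  # early stopping on training loss; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class MetaClassifier:
    """Fitted meta network: weights, batch-norm running moments, config."""

    config: MetaNetworkConfig
    w1: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    w2: np.ndarray
    b2: float
    classifier_ids: list[str] = field(default_factory=list)
    history: list[float] = field(default_factory=list)

    def predict_proba(self, x: np.ndarray | ModelLevelRepresentation) -> np.ndarray:
        """Carcinogenicity probability per row; deterministic (no dropout)."""
        if isinstance(x, ModelLevelRepresentation):
            if self.classifier_ids and x.classifier_ids != self.classifier_ids:
                raise ValueError(
                    "model-level representation columns do not match the "
                    "classifier ids this meta-model was trained on"
                )
            x = x.probabilities
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected {self.config.input_dim} input columns, got {x.shape[1]}"
            )
        z1 = x @ self.w1
        if self.config.batch_norm:
            z1 = (z1 - self.running_mean) / np.sqrt(self.running_var + _EPS)
            z1 = self.gamma * z1 + self.beta
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.w2 + self.b2
        return 1.0 / (1.0 + np.exp(-z2[:, 0]))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"), w1=self.w1, gamma=self.gamma, beta=self.beta,
            running_mean=self.running_mean, running_var=self.running_var,
            w2=self.w2, b2=np.array([self.b2]),
        )
        path.with_suffix(".json").write_text(json.dumps({
            "config": asdict(self.config),
            "classifier_ids": self.classifier_ids,
            "history": self.history,
        }, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MetaClassifier":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            config=MetaNetworkConfig(**meta["config"]),
            w1=arrays["w1"], gamma=arrays["gamma"], beta=arrays["beta"],
            running_mean=arrays["running_mean"], running_var=arrays["running_var"],
            w2=arrays["w2"], b2=float(arrays["b2"][0]),
            classifier_ids=meta["classifier_ids"], history=meta["history"],
        )


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train_meta(
    config: MetaNetworkConfig,
    mlr_dev: ModelLevelRepresentation | np.ndarray,
    dev_labels,
) -> MetaClassifier:
    """Fit the meta network on development-set model-level representations.

    Mini-batch SGD with momentum on binary cross-entropy; batch-norm moments
    are tracked with momentum 0.9. Training stops early when the epoch loss
    has not improved for ``config.patience`` epochs, restoring the best
    weights. Fully reproducible under ``config.seed``.
    """
    classifier_ids: list[str] = []
    if isinstance(mlr_dev, ModelLevelRepresentation):
        classifier_ids = list(mlr_dev.classifier_ids)
        x = mlr_dev.probabilities
    else:
        x = np.asarray(mlr_dev, dtype=float)
    y = np.asarray(dev_labels, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("labels must align with representation rows")
    if x.shape[1] != config.input_dim:
        raise ValueError(f"input_dim {config.input_dim} != matrix width {x.shape[1]}")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(config.seed)
    h = config.hidden_units
    # He initialization for the ReLU layer, Glorot-ish for the output
    w1 = rng.standard_normal((config.input_dim, h)) * np.sqrt(2.0 / config.input_dim)
    gamma = np.ones(h)
    beta = np.zeros(h)
    running_mean = np.zeros(h)
    running_var = np.ones(h)
    w2 = rng.standard_normal((h, 1)) * np.sqrt(1.0 / h)
    b2 = 0.0

    vel = {k: 0.0 for k in ("w1", "gamma", "beta", "w2", "b2")}
    params = {"w1": w1, "gamma": gamma, "beta": beta, "w2": w2}
    bn_momentum = 0.9
    keep = 1.0 - config.dropout_rate

    history: list[float] = []
    best_loss = np.inf
    best_state = None
    stall = 0
    n = x.shape[0]

    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2 and config.batch_norm:
                continue  # batch statistics are undefined on one sample
            xb, yb = x[idx], y[idx]
            m = len(idx)

            # forward
            z1 = xb @ params["w1"]
            if config.batch_norm:
                mu = z1.mean(axis=0)
                var = z1.var(axis=0)
                z1_hat = (z1 - mu) / np.sqrt(var + _EPS)
                z1_bn = params["gamma"] * z1_hat + params["beta"]
                running_mean = bn_momentum * running_mean + (1 - bn_momentum) * mu
                running_var = bn_momentum * running_var + (1 - bn_momentum) * var
            else:
                z1_bn = z1
            a1 = np.maximum(z1_bn, 0.0)
            if config.dropout_rate > 0:
                mask = (rng.random(a1.shape) < keep) / keep
                a1_drop = a1 * mask
            else:
                mask = None
                a1_drop = a1
            z2 = a1_drop @ params["w2"] + b2
            p = 1.0 / (1.0 + np.exp(-z2[:, 0]))

            # backward (BCE + sigmoid collapses to p - y)
            dz2 = ((p - yb) / m)[:, None]
            dw2 = a1_drop.T @ dz2
            db2 = float(dz2.sum())
            da1 = dz2 @ params["w2"].T
            if mask is not None:
                da1 = da1 * mask
            dz1_bn = da1 * (z1_bn > 0)
            if config.batch_norm:
                dgamma = (dz1_bn * z1_hat).sum(axis=0)
                dbeta = dz1_bn.sum(axis=0)
                inv_std = 1.0 / np.sqrt(var + _EPS)
                dz1_hat = dz1_bn * params["gamma"]
                dz1 = (inv_std / m) * (
                    m * dz1_hat
                    - dz1_hat.sum(axis=0)
                    - z1_hat * (dz1_hat * z1_hat).sum(axis=0)
                )
            else:
                dgamma = dbeta = 0.0
                dz1 = dz1_bn
            dw1 = xb.T @ dz1

            grads = {"w1": dw1, "gamma": dgamma, "beta": dbeta, "w2": dw2, "b2": db2}
            for k in ("w1", "gamma", "beta", "w2"):
                vel[k] = config.momentum * vel[k] - config.learning_rate * grads[k]
                params[k] = params[k] + vel[k]
            vel["b2"] = config.momentum * vel["b2"] - config.learning_rate * db2
            b2 = b2 + vel["b2"]

        # epoch loss with the current weights, inference mode
        snapshot = MetaClassifier(
            config, params["w1"], params["gamma"], params["beta"],
            running_mean.copy(), running_var.copy(), params["w2"], b2,
        )
        loss = _bce(y, snapshot.predict_proba(x))
        history.append(loss)
        if loss < best_loss - 1e-9:
            best_loss = loss
            best_state = snapshot
            stall = 0
        else:
            stall += 1
            if config.patience and stall >= config.patience:
                break

    model = best_state if best_state is not None else snapshot
    model.classifier_ids = classifier_ids
    model.history = history
    return model


def predict_meta(
    model: MetaClassifier, mlr: ModelLevelRepresentation | np.ndarray
) -> np.ndarray:
    """Probability vector for a model-level representation (column-checked)."""
    return model.predict_proba(mlr)
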