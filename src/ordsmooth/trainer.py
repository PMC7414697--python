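"""A small trainable classifier harness for soft-target experiments.

Fits a linear softmax model or a small multilayer perceptron by plain
mini-batch stochastic gradient descent on the soft cross-entropy, with the
label scheme (hard / uniform / gaussian smoothing) applied to the NOISY
training annotations only; the validation monitor and all test evaluation
use hard labels — smoothing regularizes optimization, never assessment.
Training stops early when the validation monitor has not improved for
``patience`` consecutive epochs, and the parameters from the best epoch are
returned.

Models are plain NumPy: parameters are lists of arrays, gradients are
written out by hand (the softmax/soft-CE gradient w.r.t. the logits is
``p * sum(q) - q``, which correctly handles unnormalized Gaussian-smoothed
targets).  Image inputs are downsampled by fixed average pooling before the
dense stages.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .label_schemes import GradeScale, SmoothingConfig, encode_batch
from .losses import LOG_EPS
from .metrics import ScoreTable

__all__ = [
    "TrainConfig",
    "MLPModel",
    "FittedModel",
    "build_model",
    "train",
    "predict_scores",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 8
    max_epochs: int = 200
    patience: int = 5
    monitor: str = "val_loss"
    label_scheme: SmoothingConfig = field(
        default_factory=lambda: SmoothingConfig(scheme="hard")
    )
    model_kind: str = "linear"
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if not 0 <= self.patience <= self.max_epochs:
            raise ValueError("patience must lie in [0, max_epochs]")
        if self.model_kind not in ("linear", "small_net"):
            raise ValueError(f"unsupported model_kind {self.model_kind!r}")


class MLPModel:
    """Affine stack with tanh nonlinearities; no hidden layers = linear.

    Image inputs (n, S, S) are average-pooled by ``pool`` and flattened
    before the first affine stage.
    """

    def __init__(
        self,
        input_shape: tuple[int, ...],
        K: int,
        hidden: Sequence[int] = (),
        pool: int = 1,
        seed: int = 0,
    ):
        if K < 2:
            raise ValueError("K must be >= 2")
        self.input_shape = tuple(input_shape)
        self.K = int(K)
        self.pool = int(pool)
        if len(self.input_shape) == 1:
            d = self.input_shape[0]
        elif len(self.input_shape) == 2:
            s = self.input_shape[0] // self.pool
            d = s * (self.input_shape[1] // self.pool)
        else:
            raise ValueError(f"unsupported input shape {input_shape}")
        sizes = [d, *hidden, K]
        rng = np.random.Generator(np.random.PCG64(seed))
        self.weights = [
            rng.normal(0.0, 1.0 / np.sqrt(a), size=(a, b))
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.biases = [np.zeros(b) for b in sizes[1:]]

    # -- parameter plumbing -------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n_w = len(self.weights)
        self.weights = [p.copy() for p in params[:n_w]]
        self.biases = [p.copy() for p in params[n_w:]]

    # -- forward / backward -------------------------------------------------
    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == len(self.input_shape):  # single sample
            X = X[None]
        if X.ndim == 3:  # images: fixed average pooling then flatten
            if self.pool > 1:
                n, h, w = X.shape
                h2, w2 = h // self.pool, w // self.pool
                X = X[:, : h2 * self.pool, : w2 * self.pool]
                X = X.reshape(n, h2, self.pool, w2, self.pool).mean(axis=(2, 4))
            X = X.reshape(X.shape[0], -1)
        return X

    def logits(self, X: np.ndarray) -> np.ndarray:
        a, _ = self._forward(self._prepare(X))
        return a[-1]

    def _forward(self, X: np.ndarray):
        activations = [X]
        pre = []
        h = X
        last = len(self.weights) - 1
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            pre.append(z)
            h = z if layer == last else np.tanh(z)
            activations.append(h)
        return activations, pre

    def backward(
        self, X: np.ndarray, dlogits: np.ndarray
    ) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters, given dL/dlogits."""
        X = self._prepare(X)
        activations, pre = self._forward(X)
        grads_w = [np.zeros_like(W) for W in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        delta = dlogits
        for layer in reversed(range(len(self.weights))):
            grads_w[layer] = activations[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (
                    1.0 - np.tanh(pre[layer - 1]) ** 2
                )
        return [*grads_w, *grads_b]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(X))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(
    model_kind: str,
    input_shape: tuple[int, ...] | int,
    K: int,
    seed: int = 0,
) -> MLPModel:
    """Construct a scorer: ``linear`` (affine map) or ``small_net`` (MLP).

    For image inputs the small net prepends a fixed 4x4 average-pooling
    downsample; the linear model consumes flattened raw pixels.
    """
    if isinstance(input_shape, (int, np.integer)):
        input_shape = (int(input_shape),)
    if model_kind == "linear":
        return MLPModel(input_shape, K, hidden=(), pool=1, seed=seed)
    if model_kind == "small_net":
        pool = 4 if len(input_shape) == 2 else 1
        return MLPModel(input_shape, K, hidden=(32,), pool=pool, seed=seed)
    raise ValueError(f"unsupported model_kind {model_kind!r}")


@dataclass
class FittedModel:
    model: MLPModel
    history: dict[str, list[float]]
    best_epoch: int  # 0-based epoch whose parameters are kept
    stopped_epoch: int  # last epoch that actually ran

    @property
    def best_monitor(self) -> float:
        return self.history["val_loss"][self.best_epoch]


def _soft_ce_from_logits(logits: np.ndarray, q: np.ndarray) -> float:
    p = np.clip(_softmax(logits), LOG_EPS, None)
    return float(-(q * np.log(p)).sum(axis=1).mean())


def train(
    model: MLPModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> FittedModel:
    """Mini-batch SGD on the soft cross-entropy with early stopping.

    ``y_train`` are the (possibly noisy) annotator grades, encoded with the
    configured label scheme; ``y_val`` is monitored with hard labels.
    Returns the model with the best-epoch parameters restored.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("train and validation splits must be non-empty")
    scale = GradeScale(model.K)
    Q_train = encode_batch(y_train, scale, config.label_scheme)
    Q_val = encode_batch(y_val, scale, SmoothingConfig(scheme="hard"))

    rng = np.random.Generator(np.random.PCG64(config.seed))
    n = len(X_train)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_epoch = 0
    best_params = model.copy_parameters()
    velocity = [np.zeros_like(p) for p in model.parameters]
    epochs_bad = 0
    epoch = -1

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, qb = X_train[idx], Q_train[idx]
            logits = model.logits(Xb)
            p = _softmax(logits)
            batch_ce = _soft_ce_from_logits(logits, qb)
            if not np.isfinite(batch_ce):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            epoch_loss += batch_ce * len(idx)
            # d(mean soft-CE)/dlogits; q may be unnormalized (sum <= 1)
            dlogits = (p * qb.sum(axis=1, keepdims=True) - qb) / len(idx)
            grads = model.backward(Xb, dlogits)
            params = model.parameters
            for v, p_arr, g in zip(velocity, params, grads):
                v *= config.momentum
                v -= config.learning_rate * g
                p_arr += v
        history["train_loss"].append(epoch_loss / n)

        val_loss = _soft_ce_from_logits(model.logits(X_val), Q_val)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = model.copy_parameters()
            epochs_bad = 0
        else:
            epochs_bad += 1
            if epochs_bad > config.patience:
                break

    model.set_parameters(best_params)
    return FittedModel(
        model=model, history=history, best_epoch=best_epoch, stopped_epoch=epoch
    )


def predict_scores(
    model: MLPModel,
    features: np.ndarray,
    ids: np.ndarray,
    y_true: np.ndarray,
) -> ScoreTable:
    """Probability-normalized scores for a feature batch, as a ScoreTable."""
    features = np.asarray(features, dtype=float)
    if len(features) == 0:
        return ScoreTable(
            ids=np.asarray(ids),
            y_true=np.asarray(y_true, dtype=int),
            scores=np.empty((0, model.K)),
        )
    return ScoreTable(ids=ids, y_true=y_true, scores=model.predict_proba(features))
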