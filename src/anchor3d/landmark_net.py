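"""Multilayer-perceptron landmark regressor.

The network maps the 9216 normalized pixel intensities of a 96x96
illustration to the 68 interleaved (x, y) coordinates of its 34 landmark
points: 9216 -> 512 -> 128 hidden units with ReLU activations and a linear
68-unit output, trained with mini-batch stochastic gradient descent using
Nesterov momentum on a mean-squared-error loss.

Inputs are scaled to [0, 1] by dividing by 255; target coordinates are scaled
to [0, 1) by dividing by the 96-pixel canvas size, which keeps the loss on a
comparable scale to the inputs and makes a learning rate of 0.01 workable.

Accuracy is reported as the within-tolerance landmark hit rate: the fraction
of (record, landmark) pairs whose predicted point lies within a Euclidean
distance of ``tolerance_px`` (default 3 px) of the annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .anchor_shapes import CANVAS_SIZE, N_POINTS

LAYER_SIZES = (9216, 512, 128, 68)

_SERIAL_VERSION = 1


@dataclass
class MLPConfig:
    """Hyperparameters of the regressor and its training run."""

    layer_sizes: tuple[int, ...] = LAYER_SIZES
    epochs: int = 200
    batch_size: int = 20
    learning_rate: float = 0.01
    momentum: float = 0.9
    decay: float = 0.0
    nesterov: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


@dataclass
class MLPModel:
    """Weights and biases of the three layer transitions, plus config echo."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MLPConfig

    def copy(self) -> "MLPModel":
        return MLPModel(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.config,
        )


@dataclass
class TrainingLog:
    """Per-epoch training/validation MSE plus final hit-rate accuracies."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    train_accuracy: float | None = None
    val_accuracy: float | None = None
    test_accuracy: float | None = None

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("epoch,train_mse,val_mse\n")
            for i, (tr, va) in enumerate(zip(self.train_mse, self.val_mse), start=1):
                fh.write(f"{i},{tr:.10g},{va:.10g}\n")


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive train/validation/test index lists."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def split_dataset(n: int, seed: int) -> DatasetSplit:
    """Randomly partition ``n`` records into train/validation/test.

    20% of all samples (rounded) are held out as the test set; 30% of the
    remainder becomes the validation set; the rest trains the model.  For
    n = 5000 this gives 2800 / 1200 / 1000.
    """
    if n < 10:
        raise ValueError("need at least 10 records to split")
    n_test = round(0.20 * n)
    n_val = round(0.30 * (n - n_test))
    n_train = n - n_test - n_val
    if min(n_test, n_val, n_train) < 1:
        raise ValueError(f"n={n} leaves an empty split partition")
    perm = np.random.default_rng(np.random.SeedSequence([int(seed), 7])).permutation(n)
    return DatasetSplit(
        train=perm[:n_train],
        validation=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
    )


# ---------------------------------------------------------------------------
# normalization


def normalize_inputs(pixels: np.ndarray) -> np.ndarray:
    """Scale 0..255 intensities to [0, 1]."""
    px = np.asarray(pixels)
    if px.min() < 0 or px.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return px / 255.0


def normalize_targets(coords: np.ndarray) -> np.ndarray:
    """Scale pixel coordinates in [0, 96) to [0, 1)."""
    c = np.asarray(coords, dtype=float)
    if c.min() < 0 or c.max() >= CANVAS_SIZE:
        raise ValueError(f"coordinates must lie in [0, {CANVAS_SIZE})")
    return c / CANVAS_SIZE


def denormalize_targets(values: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`normalize_targets`."""
    return np.asarray(values, dtype=float) * CANVAS_SIZE


# ---------------------------------------------------------------------------
# model


def init_model(config: MLPConfig) -> MLPModel:
    """Draw initial parameters: zero-mean weights at std 1/sqrt(fan_in), zero
    biases; deterministic under ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    dtype = np.dtype(config.dtype)
    weights, biases = [], []
    for fan_in, fan_out in zip(config.layer_sizes[:-1], config.layer_sizes[1:]):
        w = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))
        weights.append(w.astype(dtype))
        biases.append(np.zeros(fan_out, dtype=dtype))
    return MLPModel(weights, biases, config)


def forward(model: MLPModel, inputs: np.ndarray) -> np.ndarray:
    """Forward pass: ReLU hidden layers, identity output."""
    x = np.asarray(inputs)
    if x.ndim != 2 or x.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"expected inputs of shape (n, {model.weights[0].shape[0]}), got {x.shape}"
        )
    h = x.astype(model.weights[0].dtype, copy=False)
    last = len(model.weights) - 1
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        h = h @ w + b
        if i < last:
            np.maximum(h, 0.0, out=h)
    return h


def _forward_cached(model: MLPModel, x: np.ndarray):
    """Forward pass keeping per-layer activations for backprop."""
    acts = [x]
    last = len(model.weights) - 1
    h = x
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        h = h @ w + b
        if i < last:
            np.maximum(h, 0.0, out=h)
        acts.append(h)
    return acts


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def gradients(model: MLPModel, x: np.ndarray, y: np.ndarray):
    """Analytic gradients of the batch MSE w.r.t. every weight and bias.

    Returns ``(loss, grad_w, grad_b)`` with gradients in layer order.
    """
    acts = _forward_cached(model, x)
    pred = acts[-1]
    n = pred.size
    delta = (2.0 / n) * (pred - y).astype(pred.dtype)
    grad_w = [None] * len(model.weights)
    grad_b = [None] * len(model.biases)
    for i in range(len(model.weights) - 1, -1, -1):
        grad_w[i] = acts[i].T @ delta
        grad_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * (acts[i] > 0)
    return mse_loss(pred, y), grad_w, grad_b


try:  # single-pass fused kernel; the pure-numpy path is semantically identical
    import numba

    @numba.njit(cache=False, fastmath=False)
    def _sgd_update_kernel(theta, vel, grad, mu, eta, nesterov):
        # velocities of dead gradient components decay geometrically into the
        # subnormal range, where x86 arithmetic is pathologically slow; flush
        # them to zero far below any numerically meaningful magnitude
        tiny = 1e-30
        for k in range(theta.size):
            v = mu * vel[k] - eta * grad[k]
            if -tiny < v < tiny:
                v = 0.0
            vel[k] = v
            if nesterov:
                theta[k] += mu * v - eta * grad[k]
            else:
                theta[k] += v

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _sgd_update(theta, vel, grad, mu, eta, nesterov: bool) -> None:
    """One (Nesterov) momentum step, fused in place.

    ``v <- mu*v - eta*g`` then ``theta <- theta + mu*v - eta*g`` (Nesterov)
    or ``theta <- theta + v`` (classical momentum).  ``grad`` is consumed as
    scratch space.
    """
    if _HAVE_NUMBA:
        _sgd_update_kernel(
            theta.reshape(-1), vel.reshape(-1), grad.reshape(-1),
            theta.dtype.type(mu), theta.dtype.type(eta), nesterov,
        )
        return
    grad *= eta  # grad now holds eta*g
    vel *= mu
    vel -= grad
    vel[np.abs(vel) < 1e-30] = 0.0  # keep decayed velocities out of subnormals
    if nesterov:
        theta -= grad
        np.multiply(vel, mu, out=grad)  # grad reused as the mu*v buffer
        theta += grad
    else:
        theta += vel


def train(
    model: MLPModel,
    X: np.ndarray,
    Y: np.ndarray,
    split: DatasetSplit,
    config: MLPConfig | None = None,
) -> tuple[MLPModel, TrainingLog]:
    """Mini-batch SGD with Nesterov momentum on normalized data.

    ``X`` and ``Y`` must already be normalized (pixels in [0, 1], coordinates
    in [0, 1)).  Each epoch reshuffles the training batches under the run
    seed; the update per parameter is ``v <- mu*v - eta*g`` followed by
    ``theta <- theta + mu*v - eta*g``.  Validation MSE is computed after
    every epoch; there is no early stopping and no weight decay.
    """
    config = config or model.config
    dtype = model.weights[0].dtype
    Xtr = np.ascontiguousarray(X[split.train], dtype=dtype)
    Ytr = np.ascontiguousarray(Y[split.train], dtype=dtype)
    Xva = np.ascontiguousarray(X[split.validation], dtype=dtype)
    Yva = np.ascontiguousarray(Y[split.validation], dtype=dtype)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 13]))
    mu = dtype.type(config.momentum)
    eta = dtype.type(config.learning_rate)
    vel_w = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    log = TrainingLog()
    n_train = len(Xtr)
    for _ in range(config.epochs):
        order = rng.permutation(n_train)
        batch_losses = []
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, gw, gb = gradients(model, Xtr[idx], Ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {len(log.train_mse) + 1}"
                )
            batch_losses.append(loss)
            for i in range(len(model.weights)):
                _sgd_update(
                    model.weights[i], vel_w[i], gw[i], mu, eta, config.nesterov
                )
                _sgd_update(
                    model.biases[i], vel_b[i], gb[i], mu, eta, config.nesterov
                )
        log.train_mse.append(float(np.mean(batch_losses)))
        log.val_mse.append(mse_loss(forward(model, Xva), Yva))
    return model, log


# ---------------------------------------------------------------------------
# prediction and evaluation


def predict_landmarks(model: MLPModel, pixels: np.ndarray) -> np.ndarray:
    """Predict the 34 (x, y) landmark pairs for one raw pixel array."""
    x = normalize_inputs(np.asarray(pixels).reshape(1, -1))
    out = denormalize_targets(forward(model, x)[0])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite landmark prediction")
    return out.reshape(N_POINTS, 2)


def predict_batch(model: MLPModel, X_raw: np.ndarray) -> np.ndarray:
    """Predict landmarks for n raw pixel rows; returns (n, 34, 2)."""
    out = denormalize_targets(forward(model, normalize_inputs(X_raw)))
    return out.reshape(-1, N_POINTS, 2)


def landmark_accuracy(model: MLPModel, records, tolerance_px: float = 3.0) -> float:
    """Within-tolerance hit rate over all (record, landmark) pairs.

    ``records`` may be a list of :class:`~anchor3d.augmentation.SyntheticRecord`
    or a tuple ``(X_raw, Y_px)`` of raw pixel rows and per-row interleaved
    pixel coordinates.
    """
    if tolerance_px <= 0:
        raise ValueError("tolerance_px must be > 0")
    if isinstance(records, tuple):
        X_raw, Y_px = records
        truth = np.asarray(Y_px, dtype=float).reshape(-1, N_POINTS, 2)
    else:
        records = list(records)
        if not records:
            raise ValueError("records must be non-empty")
        X_raw = np.stack([np.asarray(r.pixels) for r in records])
        truth = np.stack(
            [np.column_stack([r.coordinate_x, r.coordinate_y]) for r in records]
        )
    if len(X_raw) == 0:
        raise ValueError("records must be non-empty")
    pred = predict_batch(model, X_raw)
    dist = np.linalg.norm(pred - truth, axis=2)
    return float((dist <= tolerance_px).mean())


# ---------------------------------------------------------------------------
# serialization


def save_model(model: MLPModel, path) -> None:
    """Write a self-describing model container (config echo + arrays)."""
    arrays = {}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    meta = json.dumps({"version": _SERIAL_VERSION, "config": asdict(model.config)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> MLPModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != _SERIAL_VERSION:
            raise ValueError(f"unsupported model container version: {meta.get('version')}")
        cfg_dict = meta["config"]
        cfg_dict["layer_sizes"] = tuple(cfg_dict["layer_sizes"])
        config = MLPConfig(**cfg_dict)
        n_layers = len(config.layer_sizes) - 1
        weights = [data[f"w{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
    return MLPModel(weights, biases, config)
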