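"""Feed-forward sigmoid multilayer perceptron with momentum backprop.

The canonical site-prediction network has 90 input neurons (the encoded
window), one hidden layer, and 2 output neurons, one per class in the
order (positive, negative).  Input neurons are pass-through; every other
neuron computes a sigmoid of the weighted sum of its inputs.  Training
minimizes the sum of squared errors by per-sample (stochastic) gradient
descent with a momentum term:

    dw(t) = -eta * dE/dw + delta * dw(t-1),    E = 1/2 sum (y - t)^2

where eta is the learning rate and delta the momentum ("acceleration")
factor, both 0.8 by default.  The half factor is the classical
backprop convention (the output delta is (y - t) * sigmoid'), under
which these learning-rate values behave well; reported SSE traces are
the plain sum of squared errors.  A prediction carries a confidence equal to
the winning output response normalized by the sum of responses, so the
two class confidences always sum to one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

SCHEMA = "ptmnet-mlp/1"


class TrainingDivergedError(RuntimeError):
    """Weights became non-finite during training."""


class ModelFormatError(ValueError):
    """A saved model file is malformed or inconsistent."""


def sigmoid(z: np.ndarray) -> np.ndarray:
    # Clipping keeps exp() finite; responses stay strictly inside (0, 1).
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class MLPModel:
    """Layer sizes, weights and biases of a sigmoid MLP.

    ``weights[l]`` has shape (layer_sizes[l], layer_sizes[l+1]);
    ``biases[l]`` has shape (layer_sizes[l+1],).  ``metadata`` carries
    encoder settings, PTM type, optimization criterion and training
    seed for a trained predictor.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("an MLP needs at least input and output layers")
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError(f"layer sizes must be positive: {self.layer_sizes}")
        if len(self.weights) != len(self.layer_sizes) - 1 or len(self.biases) != len(
            self.weights
        ):
            raise ValueError("one weight matrix and bias vector per layer gap required")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            expect = (self.layer_sizes[l], self.layer_sizes[l + 1])
            if w.shape != expect or b.shape != (expect[1],):
                raise ValueError(
                    f"layer {l}: weight shape {w.shape} / bias shape {b.shape} "
                    f"inconsistent with sizes {self.layer_sizes}"
                )
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError(f"layer {l}: non-finite parameters")

    @property
    def input_size(self) -> int:
        return self.layer_sizes[0]

    @property
    def output_size(self) -> int:
        return self.layer_sizes[-1]

    def copy(self) -> "MLPModel":
        return MLPModel(
            list(self.layer_sizes),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            dict(self.metadata),
        )


@dataclass
class TrainConfig:
    """Backprop hyperparameters.

    eta : learning rate (> 0), default 0.8.
    delta : momentum factor in [0, 1), default 0.8.
    epochs : fixed epoch budget (checkpoint selection happens per epoch
        in the training harness), default 500.
    seed : drives weight initialization and per-epoch shuffling.
    init_range : weights drawn uniformly from [-init_range, init_range].
    shuffle : reshuffle the sample order each epoch.
    """

    eta: float = 0.8
    delta: float = 0.8
    epochs: int = 500
    seed: int = 0
    init_range: float = 0.5
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.eta <= 0 and self.eta != 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if not 0 <= self.delta < 1:
            raise ValueError(f"delta must be in [0, 1), got {self.delta}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")


def init_network(
    layer_sizes: Sequence[int], seed: int = 0, init_range: float = 0.5
) -> MLPModel:
    """A fresh network with uniform random parameters; reproducible by seed."""
    sizes = list(layer_sizes)
    rng = np.random.default_rng(seed)
    weights = []
    biases = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(-init_range, init_range, size=(n_in, n_out)))
        biases.append(rng.uniform(-init_range, init_range, size=n_out))
    return MLPModel(sizes, weights, biases)


def forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Output responses for one input vector; each response lies in (0, 1)."""
    a = np.asarray(x, float)
    if a.shape != (model.input_size,):
        raise ValueError(
            f"input has shape {a.shape}, model expects ({model.input_size},)"
        )
    for w, b in zip(model.weights, model.biases):
        a = sigmoid(a @ w + b)
    return a


def forward_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Responses for an (n, input_size) matrix of inputs."""
    a = np.asarray(X, float)
    if a.ndim != 2 or a.shape[1] != model.input_size:
        raise ValueError(
            f"input has shape {a.shape}, model expects (n, {model.input_size})"
        )
    for w, b in zip(model.weights, model.biases):
        a = sigmoid(a @ w + b)
    return a


def confidence(responses: np.ndarray) -> np.ndarray:
    """Normalized output responses C_j = R_j / sum(R); they sum to one."""
    r = np.asarray(responses, float)
    if not np.isfinite(r).all():
        raise ValueError(f"non-finite responses: {r}")
    if (r <= 0).any():
        raise ValueError(f"responses must be positive (sigmoid outputs): {r}")
    return r / r.sum()


def predict(model: MLPModel, x: np.ndarray) -> tuple[int, float]:
    """Binary decision and confidence of the winning class.

    Output neuron 0 is the positive (modified) class, neuron 1 the
    negative class.  Decision 1 requires the positive response to be
    strictly larger; ties classify negative (conservative for a
    screening tool).  The confidence is the winning class's normalized
    response.
    """
    r = forward(model, x)
    c = confidence(r)
    decision = 1 if r[0] > r[1] else 0
    return decision, float(c[0] if decision == 1 else c[1])


def predict_batch(model: MLPModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized predict: (decisions, winning confidences, positive confidences)."""
    r = forward_batch(model, X)
    c = r / r.sum(axis=1, keepdims=True)
    decisions = (r[:, 0] > r[:, 1]).astype(int)
    winning = np.where(decisions == 1, c[:, 0], c[:, 1])
    return decisions, winning, c[:, 0]


def sse(model: MLPModel, X: np.ndarray, T: np.ndarray) -> float:
    """Sum of squared errors over samples (the objective is half of this)."""
    y = forward_batch(model, np.atleast_2d(X))
    return float(((y - np.atleast_2d(T)) ** 2).sum())


def gradient(
    model: MLPModel, x: np.ndarray, t: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Analytic per-sample gradient of E = 1/2 ||y - t||^2 w.r.t. parameters."""
    activations = [np.asarray(x, float)]
    a = activations[0]
    for w, b in zip(model.weights, model.biases):
        a = sigmoid(a @ w + b)
        activations.append(a)
    # dE/dz at the output; sigmoid' = a (1 - a).
    delta = (activations[-1] - t) * activations[-1] * (1.0 - activations[-1])
    gw: list[np.ndarray] = [None] * len(model.weights)  # type: ignore[list-item]
    gb: list[np.ndarray] = [None] * len(model.biases)  # type: ignore[list-item]
    for l in range(len(model.weights) - 1, -1, -1):
        gw[l] = np.outer(activations[l], delta)
        gb[l] = delta
        if l > 0:
            delta = (model.weights[l] @ delta) * activations[l] * (1.0 - activations[l])
    return gw, gb


def train_backprop(
    model: MLPModel,
    X: np.ndarray,
    T: np.ndarray,
    config: TrainConfig,
    on_epoch: Callable[[int, MLPModel, float], None] | None = None,
) -> tuple[MLPModel, list[float]]:
    """Train in place by per-sample backprop with momentum.

    Samples are visited in a per-epoch shuffled order (seeded).  After
    every epoch the SSE over the training set is appended to the trace
    and ``on_epoch(epoch, model, sse)`` is invoked, which is where the
    harness snapshots checkpoint weights.  Raises
    :class:`TrainingDivergedError` if parameters become non-finite.
    """
    X = np.asarray(X, float)
    T = np.asarray(T, float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty (n, input_size) matrix")
    if T.shape != (X.shape[0], model.output_size):
        raise ValueError(f"targets must have shape (n, {model.output_size})")
    if X.shape[1] != model.input_size:
        raise ValueError(
            f"inputs have {X.shape[1]} columns, model expects {model.input_size}"
        )
    rng = np.random.default_rng(config.seed)
    vel_w = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    n = X.shape[0]
    order = np.arange(n)
    trace: list[float] = []
    n_layers = len(model.weights)
    eta, delta_m = config.eta, config.delta
    for epoch in range(config.epochs):
        if config.shuffle:
            rng.shuffle(order)
        epoch_sse = 0.0
        for i in order:
            # forward pass, keeping activations
            acts = [X[i]]
            a = acts[0]
            for w, b in zip(model.weights, model.biases):
                a = sigmoid(a @ w + b)
                acts.append(a)
            err = acts[-1] - T[i]
            epoch_sse += float(err @ err)
            d = err * acts[-1] * (1.0 - acts[-1])
            for l in range(n_layers - 1, -1, -1):
                gw = np.outer(acts[l], d)
                if l > 0:
                    d_next = (model.weights[l] @ d) * acts[l] * (1.0 - acts[l])
                vel_w[l] *= delta_m
                vel_w[l] -= eta * gw
                vel_b[l] *= delta_m
                vel_b[l] -= eta * d
                model.weights[l] += vel_w[l]
                model.biases[l] += vel_b[l]
                if l > 0:
                    d = d_next
        if not all(np.isfinite(w).all() for w in model.weights):
            raise TrainingDivergedError(
                f"non-finite weights after epoch {epoch} (eta={eta}, delta={delta_m})"
            )
        if not math.isfinite(epoch_sse):
            raise TrainingDivergedError(f"non-finite SSE after epoch {epoch}")
        trace.append(epoch_sse)
        if on_epoch is not None:
            on_epoch(epoch, model, epoch_sse)
    return model, trace


def one_hot_targets(labels: Sequence[int]) -> np.ndarray:
    """Targets over the (positive, negative) output pair: 1 -> (1,0), 0 -> (0,1)."""
    labels = np.asarray(labels, int)
    T = np.zeros((len(labels), 2))
    T[labels == 1, 0] = 1.0
    T[labels == 0, 1] = 1.0
    return T


def save_model(model: MLPModel, path: str | Path) -> None:
    """Persist a model as versioned JSON (weights row-major, plus metadata)."""
    doc = {
        "schema": SCHEMA,
        "layer_sizes": model.layer_sizes,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> MLPModel:
    """Load a saved model; forward outputs are bit-identical to pre-save."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("schema") != SCHEMA:
        raise ModelFormatError(
            f"{path}: unsupported schema {doc.get('schema')!r}, expected {SCHEMA}"
        )
    try:
        model = MLPModel(
            [int(s) for s in doc["layer_sizes"]],
            [np.array(w, float) for w in doc["weights"]],
            [np.array(b, float) for b in doc["biases"]],
            doc.get("metadata", {}),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    return model
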