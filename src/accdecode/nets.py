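"""Small feedforward networks trained with mini-batch SGD.

The position decoder is a fixed architecture: input (one unit per recorded
neuron) -> 100 rectified-linear -> 50 rectified-linear -> 25 tanh -> 2 linear
outputs (the x, y coordinate).  The feeder classifier reuses the same trunk
with a 3-way softmax output.  Training uses mini-batch gradient descent with
momentum and weight decay; forward and backward passes are plain numpy, which
keeps training bit-reproducible for a given seed.

The regression loss is MSE with the conventional 1/2 factor,
``(1/2N) * sum ||pred - target||^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rand import rng_from

__all__ = ["TrainConfig", "MLP", "train_mlp"]

HIDDEN = (100, 50, 25)


class DivergenceError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    batch_size: int = 100
    epochs: int = 100
    learning_rate: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    hidden: tuple[int, ...] = HIDDEN


@dataclass
class MLP:
    """Weights plus the activation plan: relu, relu, tanh, then linear/softmax."""
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    task: str                       # "regression" | "classification"
    config: TrainConfig
    seed: int | None = None
    # target standardization (regression): predictions are mapped back to cm
    y_mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    y_scale: np.ndarray = field(default_factory=lambda: np.ones(2))

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """All layer activations; X is samples x units."""
        acts = [X]
        h = X
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden):
            z = h @ self.weights[i] + self.biases[i]
            h = np.tanh(z) if i == n_hidden - 1 else np.maximum(z, 0.0)
            acts.append(h)
        z = h @ self.weights[-1] + self.biases[-1]
        if self.task == "classification":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            z = e / e.sum(axis=1, keepdims=True)
        acts.append(z)
        return acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Regression: positions in cm.  Classification: class probabilities."""
        X = np.asarray(X, float)
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"input has {X.shape[1]} units, model expects {self.n_inputs}"
            )
        out = self._forward(X)[-1]
        if self.task == "regression":
            out = out * self.y_scale + self.y_mean
        return out

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        """Activation of the last hidden (tanh) layer, one row per sample."""
        return self._forward(np.asarray(X, float))[-2]


def _init(n_in: int, n_out: int, rng) -> np.ndarray:
    # He-style scaling, suitable for the rectified-linear trunk
    return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    task: str = "regression",
    config: TrainConfig | None = None,
    seed=None,
) -> MLP:
    """Train the decoder/classifier network.

    For regression, ``y`` is samples x 2 positions in cm; they are z-scaled
    internally (the scaling is stored on the model and inverted at prediction
    time) so that the fixed learning rate is well-conditioned regardless of
    track size.  For classification, ``y`` is integer class labels.
    """
    config = config or TrainConfig()
    rng = rng_from(seed)
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, d = X.shape

    if task == "regression":
        y = np.asarray(y, float)
        y_mean = y.mean(axis=0)
        y_scale = np.where(y.std(axis=0) > 1e-8, y.std(axis=0), 1.0)
        t = (y - y_mean) / y_scale
        n_out = t.shape[1]
    elif task == "classification":
        n_out = int(y.max()) + 1
        t = np.zeros((n, n_out))
        t[np.arange(n), y.astype(int)] = 1.0
        y_mean, y_scale = np.zeros(n_out), np.ones(n_out)
    else:
        raise ValueError(f"unknown task {task!r}")

    dims = [d, *config.hidden, n_out]
    W = [_init(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
    b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
    model = MLP(weights=W, biases=b, task=task, config=config,
                seed=seed, y_mean=y_mean, y_scale=y_scale)

    vW = [np.zeros_like(w) for w in W]
    vb = [np.zeros_like(x) for x in b]
    lr, mom, wd = config.learning_rate, config.momentum, config.weight_decay
    n_hidden = len(W) - 1

    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            acts = model._forward(X[sel])
            out = acts[-1]
            m = len(sel)
            # dL/dz at the output: identical form for 1/2-MSE (linear output)
            # and cross-entropy (softmax output)
            delta = (out - t[sel]) / m
            if not np.all(np.isfinite(delta)):
                raise DivergenceError(
                    "training loss diverged; try a lower learning rate"
                )
            for i in range(len(W) - 1, -1, -1):
                gW = acts[i].T @ delta + wd * W[i]
                gb = delta.sum(axis=0)
                if i > 0:
                    back = delta @ W[i].T
                    h = acts[i]
                    if i - 1 == n_hidden - 1:      # tanh layer
                        delta = back * (1.0 - h * h)
                    else:                          # relu layers
                        delta = back * (h > 0)
                vW[i] = mom * vW[i] - lr * gW
                vb[i] = mom * vb[i] - lr * gb
                W[i] += vW[i]
                b[i] += vb[i]
    return model
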