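"""Single-hidden-layer perceptron trained by full-batch backpropagation.

The network is deliberately minimal, mirroring the classic connectionist
recipe: inputs scaled to [0, 1], one sigmoid hidden layer (three units by
default), a sigmoid output in (0, 1), weights initialized uniformly in
(-0.05, 0.05), learning rate 0.1, and plain gradient descent in which the
per-example weight changes of an epoch are accumulated and applied once at
the epoch's end.  Training stops when the training-set mean squared error
drops below 0.045 (targets live on the [0, 1] scale) or a maximum epoch count
is reached, in which case the best weights seen so far are kept and a
non-convergence warning is issued.

Per-example loss is (1/2)(y - t)^2, so the epoch update is
``w <- w - lr * sum_i grad_i``; the reported/stopping metric is the plain mean
of (y - t)^2 over the training examples.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TrainingConfig",
    "NetworkWeights",
    "TrainingTrace",
    "NetworkModel",
    "init_network",
    "forward",
    "gradients",
    "backprop_epoch",
    "train",
    "rmse",
]


@dataclass
class TrainingConfig:
    learning_rate: float = 0.1
    target_mse: float = 0.045
    max_epochs: int = 50000
    init_half_range: float = 0.05
    use_bias: bool = True
    n_hidden: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.init_half_range <= 0:
            raise ValueError("learning_rate and init_half_range must be positive")
        if not 0 < self.target_mse < 1:
            raise ValueError("target_mse must lie in (0, 1)")
        if self.max_epochs < 0 or self.n_hidden < 1:
            raise ValueError("max_epochs must be >= 0 and n_hidden >= 1")


@dataclass
class NetworkWeights:
    """W_hi maps inputs to hidden units; W_oh maps hidden units to the output."""

    w_hi: np.ndarray          # (n_hidden, n_in)
    w_oh: np.ndarray          # (n_hidden,)
    b_h: np.ndarray | None    # (n_hidden,) or None when bias-free
    b_o: float | None

    @property
    def n_in(self) -> int:
        return self.w_hi.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w_hi.shape[0]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.w_hi.copy(), self.w_oh.copy(),
                              None if self.b_h is None else self.b_h.copy(),
                              self.b_o)


@dataclass
class TrainingTrace:
    mse: list[float] = field(default_factory=list)
    converged: bool = False
    epochs_run: int = 0


@dataclass
class NetworkModel:
    """Trained weights plus the metadata needed to apply them to new rows."""

    weights: NetworkWeights
    feature_names: list[str]
    dimension: str
    trace: TrainingTrace
    config: TrainingConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        return forward(self.weights, X)

    def to_dict(self) -> dict:
        w = self.weights
        return {
            "feature_names": self.feature_names,
            "dimension": self.dimension,
            "w_hi": w.w_hi.tolist(),
            "w_oh": w.w_oh.tolist(),
            "b_h": None if w.b_h is None else w.b_h.tolist(),
            "b_o": w.b_o,
            "config": {
                "learning_rate": self.config.learning_rate,
                "target_mse": self.config.target_mse,
                "max_epochs": self.config.max_epochs,
                "init_half_range": self.config.init_half_range,
                "use_bias": self.config.use_bias,
                "n_hidden": self.config.n_hidden,
                "seed": self.config.seed,
            },
            "trace": {"converged": self.trace.converged,
                      "epochs_run": self.trace.epochs_run,
                      "final_mse": self.trace.mse[-1] if self.trace.mse else None},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        weights = NetworkWeights(
            w_hi=np.asarray(d["w_hi"], dtype=float),
            w_oh=np.asarray(d["w_oh"], dtype=float),
            b_h=None if d["b_h"] is None else np.asarray(d["b_h"], dtype=float),
            b_o=d["b_o"],
        )
        trace = TrainingTrace(mse=[], converged=d["trace"]["converged"],
                              epochs_run=d["trace"]["epochs_run"])
        if d["trace"]["final_mse"] is not None:
            trace.mse = [d["trace"]["final_mse"]]
        return cls(weights=weights, feature_names=list(d["feature_names"]),
                   dimension=d["dimension"], trace=trace,
                   config=TrainingConfig(**d["config"]))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def init_network(n_in: int, n_hidden: int, config: TrainingConfig,
                 rng: np.random.Generator | None = None) -> NetworkWeights:
    """Uniform(-r, r) initialization of all connection weights (and biases)."""
    if n_in < 1 or n_hidden < 1:
        raise ValueError("n_in and n_hidden must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    r = config.init_half_range
    w_hi = rng.uniform(-r, r, size=(n_hidden, n_in))
    w_oh = rng.uniform(-r, r, size=n_hidden)
    if config.use_bias:
        b_h = rng.uniform(-r, r, size=n_hidden)
        b_o = float(rng.uniform(-r, r))
    else:
        b_h, b_o = None, None
    return NetworkWeights(w_hi=w_hi, w_oh=w_oh, b_h=b_h, b_o=b_o)


def forward(net: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Sigmoid-hidden, sigmoid-output forward pass; rows of X are examples."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.n_in:
        raise ValueError(f"input has {X.shape[1]} features, network expects {net.n_in}")
    pre_h = X @ net.w_hi.T
    if net.b_h is not None:
        pre_h = pre_h + net.b_h
    H = _sigmoid(pre_h)
    pre_o = H @ net.w_oh
    if net.b_o is not None:
        pre_o = pre_o + net.b_o
    return _sigmoid(pre_o)


def gradients(net: NetworkWeights, X: np.ndarray, Y: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, float | None, np.ndarray]:
    """Summed per-example gradients of (1/2)(y - t)^2 and the outputs.

    Returns (gW_hi, gW_oh, gb_h, gb_o, outputs); bias gradients are None for
    bias-free networks.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).ravel()
    pre_h = X @ net.w_hi.T
    if net.b_h is not None:
        pre_h = pre_h + net.b_h
    H = _sigmoid(pre_h)
    pre_o = H @ net.w_oh
    if net.b_o is not None:
        pre_o = pre_o + net.b_o
    y = _sigmoid(pre_o)
    d_o = (y - Y) * y * (1.0 - y)                    # (n,)
    g_w_oh = d_o @ H                                 # (n_hidden,)
    d_h = (d_o[:, None] * net.w_oh[None, :]) * H * (1.0 - H)
    g_w_hi = d_h.T @ X                               # (n_hidden, n_in)
    g_b_h = d_h.sum(axis=0) if net.b_h is not None else None
    g_b_o = float(d_o.sum()) if net.b_o is not None else None
    return g_w_hi, g_w_oh, g_b_h, g_b_o, y


def backprop_epoch(net: NetworkWeights, X: np.ndarray, Y: np.ndarray,
                   config: TrainingConfig, rng: np.random.Generator | None = None
                   ) -> tuple[NetworkWeights, float]:
    """One full-batch epoch: accumulate per-example deltas, update once.

    Examples are presented in a randomized order each epoch; because the
    update is the sum of per-example gradients applied at the epoch's end, the
    order is mathematically inert but retained for procedural fidelity.
    Returns the updated weights and the epoch MSE (pre-update weights).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).ravel()
    if len(X) != len(Y):
        raise ValueError("X and Y lengths differ")
    order = rng.permutation(len(X)) if rng is not None else np.arange(len(X))
    g_w_hi, g_w_oh, g_b_h, g_b_o, y = gradients(net, X[order], Y[order])
    if not (np.isfinite(g_w_hi).all() and np.isfinite(g_w_oh).all()):
        raise FloatingPointError("non-finite gradient encountered during backprop")
    mse = float(np.mean((y - Y[order]) ** 2))
    lr = config.learning_rate
    new = net.copy()
    new.w_hi -= lr * g_w_hi
    new.w_oh -= lr * g_w_oh
    if new.b_h is not None:
        new.b_h -= lr * g_b_h
        new.b_o -= lr * g_b_o
    return new, mse


def train(X: np.ndarray, Y: np.ndarray, config: TrainingConfig,
          feature_names: list[str] | None = None, dimension: str = "",
          net: NetworkWeights | None = None,
          rng: np.random.Generator | None = None) -> NetworkModel:
    """Train until MSE < target_mse or max_epochs; keep best-so-far weights."""
    config.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).ravel()
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if net is None:
        net = init_network(X.shape[1], config.n_hidden, config, rng=rng)
    trace = TrainingTrace()
    best = net.copy()
    best_mse = float(np.mean((forward(net, X) - Y) ** 2))
    converged = best_mse < config.target_mse
    for _ in range(config.max_epochs):
        if converged:
            break
        net, mse = backprop_epoch(net, X, Y, config, rng=rng)
        trace.mse.append(mse)
        trace.epochs_run += 1
        if mse < best_mse:
            best_mse = mse
            best = net.copy()
        if mse < config.target_mse:
            converged = True
    trace.converged = converged
    if not converged:
        warnings.warn(
            f"network did not reach MSE < {config.target_mse} in "
            f"{config.max_epochs} epochs (best {best_mse:.4f}); keeping best weights")
    final = best if not converged else net
    return NetworkModel(weights=final, feature_names=list(feature_names or []),
                        dimension=dimension, trace=trace, config=copy.copy(config))


def rmse(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Root mean squared error."""
    p = np.asarray(predictions, dtype=float).ravel()
    t = np.asarray(targets, dtype=float).ravel()
    if len(p) == 0 or len(p) != len(t):
        raise ValueError("predictions and targets must be non-empty, equal-length")
    return float(np.sqrt(np.mean((p - t) ** 2)))
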