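"""Perceptron learning-speed assay for pattern separation.

A single-layer network of sigmoidal output units (one per class, one-hot
0/1 targets) is trained online with the delta rule at a small fixed learning
rate. Each epoch presents all patterns once in a fresh random order; after
each epoch the RMSE over all patterns and outputs is evaluated with frozen
weights. ``N_E`` is the first epoch at which the RMSE reaches the criterion
(0.2 by default) and the learning speed is ``1 / N_E`` (0 if the criterion
is never reached within the epoch budget).

The per-pattern update loop is numba-compiled; the post-epoch RMSE pass
uses BLAS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np

__all__ = [
    "PerceptronConfig",
    "LearningResult",
    "assign_classes",
    "train_classifier",
    "learning_speed_ratio",
]


@dataclass(frozen=True)
class PerceptronConfig:
    """Training protocol: 640 patterns / 10 classes sized tasks by default."""

    learning_rate: float = 0.01
    max_epochs: int = 5000
    rmse_threshold: float = 0.2
    # small init keeps the sigmoid outputs away from saturation at the start
    # of training even for integer spike-count inputs with large norms;
    # binary/real inputs learn identically to a 0.1-scale init
    weight_init_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 < self.rmse_threshold < 1.0:
            raise ValueError("rmse_threshold must lie in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class LearningResult:
    """Epochs-to-criterion and speed; ``n_epochs`` is None when unmet."""

    n_epochs: int | None
    speed: float
    rmse_curve: np.ndarray = field(repr=False)

    @property
    def final_rmse(self) -> float:
        return float(self.rmse_curve[-1]) if self.rmse_curve.size else float("nan")


def assign_classes(n_patterns: int, n_classes: int, seed=None) -> np.ndarray:
    """Assign each pattern to a uniformly random class in [0, n_classes).

    Random class assignment maximizes overlap between patterns that must be
    separated, making the task a generic pattern-separation probe.
    """
    if n_classes <= 0:
        raise ValueError("n_classes must be >= 1")
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    if n_classes > n_patterns:
        warnings.warn("more classes than patterns: some classes will be empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.integers(0, n_classes, size=n_patterns)


@numba.njit(cache=False)
def _epoch_update(X, T, order, W, b, lr):  # pragma: no cover - compiled
    P, N = X.shape
    K = W.shape[0]
    for ii in range(P):
        p = order[ii]
        for k in range(K):
            s = b[k]
            for j in range(N):
                xj = X[p, j]
                if xj != 0.0:
                    s += W[k, j] * xj
            y = 1.0 / (1.0 + np.exp(-s))
            g = lr * (T[p, k] - y) * y * (1.0 - y)
            if g != 0.0:
                for j in range(N):
                    xj = X[p, j]
                    if xj != 0.0:
                        W[k, j] += g * xj
                b[k] += g


def _rmse(X: np.ndarray, T: np.ndarray, W: np.ndarray, b: np.ndarray) -> float:
    Y = 1.0 / (1.0 + np.exp(-(X @ W.T + b)))
    return float(np.sqrt(np.mean((Y - T) ** 2)))


def train_classifier(
    X,
    labels: np.ndarray,
    cfg: PerceptronConfig = PerceptronConfig(),
    seed=None,
) -> LearningResult:
    """Train to the RMSE criterion and report epochs-to-criterion and speed.

    Parameters
    ----------
    X : ensemble or ndarray (n_patterns, n_inputs)
        Raw activity patterns (binary MF, real GC, or integer spike counts).
    labels : ndarray of int
        One class per pattern.
    seed : int or Generator
        Controls weight initialization and presentation order.
    """
    from .containers import as_matrix

    M = np.ascontiguousarray(as_matrix(X), dtype=np.float64)
    labels = np.asarray(labels)
    if labels.shape[0] != M.shape[0]:
        raise ValueError("labels length must match the number of patterns")
    if not np.isfinite(M).all():
        raise ValueError("non-finite values in the input patterns")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    P, N = M.shape
    K = int(labels.max()) + 1
    T = np.zeros((P, K))
    T[np.arange(P), labels] = 1.0

    W = rng.uniform(-cfg.weight_init_scale, cfg.weight_init_scale, size=(K, N))
    b = rng.uniform(-cfg.weight_init_scale, cfg.weight_init_scale, size=K)

    rmse_curve = np.empty(cfg.max_epochs)
    n_epochs: int | None = None
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(P)
        _epoch_update(M, T, order, W, b, cfg.learning_rate)
        rmse_curve[epoch] = _rmse(M, T, W, b)
        if rmse_curve[epoch] <= cfg.rmse_threshold:
            n_epochs = epoch + 1
            break
    done = n_epochs if n_epochs is not None else cfg.max_epochs
    speed = 1.0 / n_epochs if n_epochs is not None else 0.0
    return LearningResult(n_epochs=n_epochs, speed=speed, rmse_curve=rmse_curve[:done].copy())


def learning_speed_ratio(numerator: LearningResult, denominator: LearningResult) -> float:
    """Speed ratio, e.g. GC/MF (normalized learning speed) or GC/shuffled-GC."""
    if denominator.speed == 0.0:
        raise ZeroDivisionError(
            "speed ratio undefined: reference classifier never reached criterion"
        )
    return numerator.speed / denominator.speed
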