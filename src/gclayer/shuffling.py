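"""Partial shuffling of activity patterns to a target population correlation.

Each shuffling move permutes a neuron's values across patterns, so every
per-neuron marginal statistic (mean, variance, histogram) is exactly
preserved — only the co-variation across neurons changes:

* decreasing direction: exchange a neuron's values between two random
  patterns (a random within-neuron transposition);
* increasing direction: for a random pair of patterns, reorder every
  neuron's two values so the lower value goes to the first pattern and the
  higher to the second, making the population more co-active.

Moves are applied in batches whose size adapts to the remaining distance
from the target population correlation; a batch is kept only if it moves
the ensemble toward the target (otherwise it is reverted and the batch size
halved). Iteration stops when the population correlation is within
``tolerance`` of the target, or fails with a convergence error reporting the
best value achieved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import PatternEnsemble, as_matrix
from .popstats import population_correlation

__all__ = ["ShuffleConfig", "ShuffleConvergenceError", "ShuffleReport",
           "shuffle_to_target", "verify_shuffle"]


@dataclass(frozen=True)
class ShuffleConfig:
    """Target population correlation and convergence controls."""

    target_pc: float
    # population correlations of these ensembles live at the few-percent
    # scale; the clamp tolerance must resolve GC-vs-MF gaps of ~0.01-0.03
    tolerance: float = 0.005
    max_iterations: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_pc <= 1.0:
            raise ValueError("target_pc must lie in [0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class ShuffleConvergenceError(RuntimeError):
    def __init__(self, target: float, best_pc: float, iterations: int):
        self.target = target
        self.best_pc = best_pc
        self.iterations = iterations
        super().__init__(
            f"shuffle did not reach target PC {target:.4f} within {iterations} "
            f"iterations (best achieved {best_pc:.4f})"
        )


def _swap_down(X: np.ndarray, n_pairs_per_neuron: int, rng) -> None:
    """Disjoint random within-neuron transpositions, vectorized over neurons."""
    P, N = X.shape
    m = min(n_pairs_per_neuron, P // 2)
    # per neuron: 2m distinct random patterns via argsort of random keys
    order = np.argsort(rng.random((N, P)), axis=1)[:, : 2 * m]
    p, q = order[:, :m], order[:, m:]
    cols = np.arange(N)[:, None]
    Xp = X[p, cols].copy()
    X[p, cols] = X[q, cols]
    X[q, cols] = Xp


def _swap_up(X: np.ndarray, n_pattern_pairs: int, rng) -> None:
    """For disjoint random pattern pairs, sort each neuron's two values."""
    P, _ = X.shape
    m = min(n_pattern_pairs, P // 2)
    pats = rng.choice(P, size=2 * m, replace=False)
    p, q = pats[:m], pats[m:]
    lo = np.minimum(X[p], X[q])
    hi = np.maximum(X[p], X[q])
    X[p] = lo
    X[q] = hi


def shuffle_to_target(X, cfg: ShuffleConfig) -> PatternEnsemble:
    """Shuffle an ensemble to a prescribed population correlation.

    Returns a new ensemble whose metadata records the target, the achieved
    population correlation and the number of accepted/attempted batches.
    Raises :class:`ShuffleConvergenceError` if the target is unreachable
    within ``cfg.max_iterations`` batches.
    """
    M = as_matrix(X).astype(float)
    P, N = M.shape
    if P < 2:
        raise ValueError("need at least 2 patterns to shuffle")
    rng = np.random.default_rng(cfg.seed)

    pc = population_correlation(M)
    best = pc
    intensity = max(1, P // 8)  # pairs per neuron (down) / pattern pairs (up)
    accepted = 0
    for it in range(1, cfg.max_iterations + 1):
        if abs(pc - cfg.target_pc) <= cfg.tolerance:
            break
        backup = M.copy()
        if pc > cfg.target_pc:
            _swap_down(M, intensity, rng)
        else:
            _swap_up(M, intensity, rng)
        new_pc = population_correlation(M)
        if abs(new_pc - cfg.target_pc) < abs(pc - cfg.target_pc):
            pc = new_pc
            accepted += 1
            if abs(pc - cfg.target_pc) < abs(best - cfg.target_pc):
                best = pc
            # grow cautiously while far from target
            intensity = min(max(intensity, int(intensity * 1.3)), P // 2)
        else:
            M = backup
            intensity = max(1, intensity // 2)
    else:
        raise ShuffleConvergenceError(cfg.target_pc, best, cfg.max_iterations)

    meta = dict(getattr(X, "meta", {}))
    meta.update({
        "kind": "shuffled",
        "shuffle_target_pc": cfg.target_pc,
        "shuffle_achieved_pc": pc,
        "shuffle_batches": it,
        "shuffle_accepted_batches": accepted,
        "shuffle_seed": cfg.seed,
    })
    out = M
    src = as_matrix(X)
    if np.issubdtype(src.dtype, np.integer) or np.isin(src, (0, 1)).all():
        # permutations of integer/binary values stay exact; keep source dtype
        out = M.astype(src.dtype)
    return PatternEnsemble(X=out, meta=meta)


@dataclass(frozen=True)
class ShuffleReport:
    marginals_preserved: bool
    max_mean_error: float
    max_var_error: float
    total_variance_error: float
    sparseness_original: float
    sparseness_shuffled: float

    @property
    def ok(self) -> bool:
        return self.marginals_preserved


def verify_shuffle(original, shuffled) -> ShuffleReport:
    """Assert the exact invariants of a valid partial shuffle.

    Each neuron's multiset of values must be exactly preserved (hence its
    mean, variance and the ensemble total variance). Population sparseness
    is reported for both ensembles (near-equal but not exactly invariant).
    Raises AssertionError on any exact-invariant violation.
    """
    from .popstats import population_sparseness, total_variance

    A = as_matrix(original)
    B = as_matrix(shuffled)
    if A.shape != B.shape:
        raise ValueError("original and shuffled ensembles must have matching shapes")
    multiset_ok = bool(np.array_equal(np.sort(A, axis=0), np.sort(B, axis=0)))
    if not multiset_ok:
        raise AssertionError("shuffle violated per-neuron marginal preservation")
    report = ShuffleReport(
        marginals_preserved=True,
        max_mean_error=float(np.abs(A.mean(axis=0) - B.mean(axis=0)).max()),
        max_var_error=float(np.abs(A.var(axis=0, ddof=1) - B.var(axis=0, ddof=1)).max()),
        total_variance_error=abs(total_variance(A) - total_variance(B)),
        sparseness_original=population_sparseness(A),
        sparseness_shuffled=population_sparseness(B),
    )
    return report
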