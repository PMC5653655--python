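"""Population-level statistics of activity-pattern ensembles.

Three statistics summarize an ensemble ``X`` of shape (n_patterns, n_neurons):

* population sparseness (Treves-Rolls style), per pattern
  ``(N - (sum x)^2 / sum x^2) / (N - 1)`` averaged over patterns — 1 when a
  single neuron is active, 0 for perfectly uniform activity;
* total variance ``sum_i var(x_i)`` — the size of the coding space;
* population correlation, an eigenvalue-based elongation measure of the
  activity distribution:
  ``N/(N-1) * (max_i sqrt(lambda_i) / sum_i sqrt(lambda_i) - 1/N)`` where
  ``lambda_i`` are the eigenvalues of the covariance matrix — 0 for an
  uncorrelated homogeneous Gaussian, 1 when all neurons are identical.

GC-vs-MF comparisons use normalized (output/input) ratios of these
quantities, and "robustness" is the fraction of a parameter grid where the
normalized value exceeds 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PatternEnsemble, as_matrix

__all__ = [
    "PopulationStats",
    "DegenerateCovarianceError",
    "population_sparseness",
    "total_variance",
    "population_correlation",
    "population_correlation_hetero",
    "mean_pairwise_pearson",
    "fraction_inactive",
    "subsample_curve",
    "normalized_metric",
    "robustness",
    "compute_stats",
]

logger = logging.getLogger(__name__)


class DegenerateCovarianceError(ValueError):
    """Raised when the population correlation is undefined (zero covariance)."""


@dataclass(frozen=True)
class PopulationStats:
    sparseness: float
    total_variance: float
    population_correlation: float
    mean_pearson: float
    fraction_inactive: float
    n_neurons: int
    n_patterns: int


def population_sparseness(X) -> float:
    """Mean per-pattern population sparseness in [0, 1].

    All-zero patterns are counted as maximally sparse (value 1) and logged;
    this keeps the average defined at very high thresholds.
    """
    X = as_matrix(X).astype(float)
    P, N = X.shape
    if N < 2:
        raise ValueError("population sparseness needs at least 2 neurons")
    s1 = X.sum(axis=1) ** 2
    s2 = (X**2).sum(axis=1)
    zero = s2 == 0.0
    if zero.any():
        logger.info("population_sparseness: %d all-zero patterns treated as sparseness 1",
                    int(zero.sum()))
    vals = np.ones(P)
    nz = ~zero
    vals[nz] = (N - s1[nz] / s2[nz]) / (N - 1)
    return float(vals.mean())


def total_variance(X, ddof: int = 1) -> float:
    """Sum over neurons of the across-pattern activity variance."""
    X = as_matrix(X).astype(float)
    if X.shape[0] < 2:
        raise ValueError("total variance needs at least 2 patterns")
    return float(X.var(axis=0, ddof=ddof).sum())


def _pc_from_eigenvalues(lam: np.ndarray) -> float:
    lam = np.clip(np.asarray(lam, dtype=float), 0.0, None)
    total = np.sqrt(lam).sum()
    if total == 0.0:
        raise DegenerateCovarianceError(
            "population correlation undefined: covariance is identically zero"
        )
    n = lam.size
    return float(n / (n - 1) * (np.sqrt(lam).max() / total - 1.0 / n))


def population_correlation(X=None, *, cov: np.ndarray | None = None) -> float:
    """Eigenvalue-based population correlation in [0, 1].

    Either an ensemble ``X`` (sample covariance, unbiased normalization) or a
    covariance matrix may be supplied. Tiny negative eigenvalues from
    numerical error are clipped at zero.
    """
    if cov is None:
        X = as_matrix(X).astype(float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 patterns to estimate covariance")
        if X.shape[1] < 2:
            raise ValueError("population correlation needs at least 2 neurons")
        Xc = X - X.mean(axis=0)
        # eigenvalues of the covariance via singular values: avoids forming NxN
        sv = np.linalg.svd(Xc, compute_uv=False)
        # constant-to-rounding ensembles are degenerate, not rank-deficient noise
        tol = X.shape[0] * np.finfo(float).eps * max(1.0, float(np.abs(X).max()))
        if sv.max(initial=0.0) <= tol:
            raise DegenerateCovarianceError(
                "population correlation undefined: covariance is identically zero"
            )
        lam = np.zeros(X.shape[1])
        lam[: sv.size] = sv**2 / (X.shape[0] - 1)
    else:
        cov = np.asarray(cov, dtype=float)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1] or cov.shape[0] < 2:
            raise ValueError("cov must be a square matrix of size >= 2")
        lam = np.linalg.eigvalsh(cov)
    return _pc_from_eigenvalues(lam)


def population_correlation_hetero(X=None, *, cov: np.ndarray | None = None) -> float:
    """Population correlation on the correlation matrix (variance-normalized).

    Controls for heterogeneous per-neuron variances; zero-variance neurons
    are dropped with a warning.
    """
    if cov is None:
        X = as_matrix(X).astype(float)
        cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    v = np.diag(cov).copy()
    keep = v > 0
    if not keep.all():
        logger.warning("population_correlation_hetero: dropping %d zero-variance neurons",
                       int((~keep).sum()))
    cov = cov[np.ix_(keep, keep)]
    if cov.shape[0] < 2:
        raise DegenerateCovarianceError("fewer than 2 neurons with nonzero variance")
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    return _pc_from_eigenvalues(np.linalg.eigvalsh(corr))


def mean_pairwise_pearson(X) -> float:
    """Average off-diagonal Pearson coefficient; zero-variance neurons excluded."""
    X = as_matrix(X).astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 patterns")
    keep = X.var(axis=0) > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 neurons with nonzero variance")
    corr = np.corrcoef(X[:, keep], rowvar=False)
    n = corr.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(corr[iu].mean())


def fraction_inactive(X) -> float:
    """Mean over patterns of the fraction of exactly-silent neurons."""
    X = as_matrix(X)
    return float((X == 0).mean())


def normalized_metric(gc_value: float, mf_value: float, log10: bool = False) -> float:
    """Output/input ratio of a statistic (optionally log10, for correlation maps)."""
    if mf_value == 0:
        raise ZeroDivisionError("normalization undefined: input-population value is 0")
    ratio = gc_value / mf_value
    return float(np.log10(ratio)) if log10 else float(ratio)


def robustness(normalized_values) -> float:
    """Fraction of grid points where the normalized value exceeds 1."""
    vals = np.asarray(list(normalized_values), dtype=float)
    if vals.size == 0:
        raise ValueError("robustness needs a non-empty grid")
    return float((vals > 1.0).mean())


def subsample_curve(
    X_out,
    X_in,
    fractions,
    n_resamples: int = 10,
    seed=None,
) -> pd.DataFrame:
    """Normalized population correlation for random subpopulations.

    For each fraction f, draws ``n_resamples`` random neuron subsets of size
    ``round(f * N)`` from the output and input populations independently and
    computes the output/input population-correlation ratio per draw.

    Returns a DataFrame with columns fraction, size_out, size_in, mean, sd.
    """
    X_out = as_matrix(X_out).astype(float)
    X_in = as_matrix(X_in).astype(float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        k_out = int(round(frac * X_out.shape[1]))
        k_in = int(round(frac * X_in.shape[1]))
        if min(k_out, k_in) < 2:
            logger.warning("subsample_curve: skipping fraction %.3g (subset < 2 neurons)", frac)
            continue
        full = k_out == X_out.shape[1] and k_in == X_in.shape[1]
        vals = []
        for _ in range(1 if full else n_resamples):
            so = rng.choice(X_out.shape[1], size=k_out, replace=False)
            si = rng.choice(X_in.shape[1], size=k_in, replace=False)
            vals.append(
                population_correlation(X_out[:, so]) / population_correlation(X_in[:, si])
            )
        vals = np.asarray(vals)
        rows.append({
            "fraction": float(frac), "size_out": k_out, "size_in": k_in,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=0)) if vals.size > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def compute_stats(X) -> PopulationStats:
    """All scalar statistics of one ensemble in a single record."""
    M = as_matrix(X)
    return PopulationStats(
        sparseness=population_sparseness(M),
        total_variance=total_variance(M),
        population_correlation=population_correlation(M),
        mean_pearson=mean_pairwise_pearson(M),
        fraction_inactive=fraction_inactive(M),
        n_neurons=M.shape[1],
        n_patterns=M.shape[0],
    )
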