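"""Spatially correlated binary mossy-fiber activity patterns.

Ensembles of binary MF patterns are drawn from a dichotomized Gaussian (DG)
model: a latent multivariate normal is thresholded so that each MF is active
with probability ``f_mf`` and each MF pair attains a specified binary
(Pearson) correlation. The target pairwise correlation decays with
inter-rosette distance ``d`` as a Gaussian kernel ``exp(-d^2 / (2 sigma^2))``
with correlation radius ``sigma``.

Fitting the latent correlation ``lambda_ij`` for a target binary correlation
``r_ij`` requires the equal-threshold bivariate-normal orthant probability

    P(Z1 > t, Z2 > t; lambda) = 1 - 2 Phi(t) + Phi2(t, t; lambda),

which this module evaluates in closed form through Owen's T function,

    Phi2(t, t; rho) = Phi(t) - 2 T(t, sqrt((1 - rho) / (1 + rho))),

so the per-pair root-finding vectorizes over all MF pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .containers import PatternEnsemble, as_matrix

__all__ = [
    "CorrelationSpec",
    "DGModel",
    "target_binary_correlation",
    "fit_dichotomized_gaussian",
    "sample_patterns",
    "patterns_to_rates",
    "make_correlated_patterns",
]

logger = logging.getLogger(__name__)

_RHO_BOUND = 0.9999
_FIT_TOL = 1e-8


@dataclass(frozen=True)
class CorrelationSpec:
    """Mean MF activity ``f_mf`` and spatial correlation radius ``sigma`` (um)."""

    f_mf: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_mf <= 1.0:
            raise ValueError(f"f_mf must lie in [0, 1], got {self.f_mf}")
        if self.sigma < 0.0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def target_binary_correlation(mf_positions: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian distance-dependent target correlation matrix.

    ``R_ij = exp(-d_ij^2 / (2 sigma^2))`` for ``i != j`` and ``R_ii = 1``.
    ``sigma = 0`` is the independent limit (identity matrix).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    pos = np.atleast_2d(np.asarray(mf_positions, dtype=float))
    n = pos.shape[0]
    if sigma == 0.0:
        return np.eye(n)
    d2 = pdist(pos, metric="sqeuclidean")
    R = squareform(np.exp(-d2 / (2.0 * sigma**2)))
    np.fill_diagonal(R, 1.0)
    return R


def _phi2_equal(t: float, rho: np.ndarray) -> np.ndarray:
    """Bivariate standard-normal CDF at the equal point (t, t), via Owen's T."""
    rho = np.clip(rho, -_RHO_BOUND, _RHO_BOUND)
    a = np.sqrt((1.0 - rho) / (1.0 + rho))
    return norm.cdf(t) - 2.0 * special.owens_t(t, a)


def joint_active_probability(t: float, rho: np.ndarray) -> np.ndarray:
    """P(Z1 > t and Z2 > t) for standard bivariate normals with correlation rho."""
    return 1.0 - 2.0 * norm.cdf(t) + _phi2_equal(t, rho)


@dataclass
class DGModel:
    """Fitted dichotomized-Gaussian sampler state.

    ``threshold`` is the upper-tail latent cut: an MF is active when its
    latent Gaussian exceeds it, so ``P(active) = 1 - Phi(threshold) = f_mf``.
    ``latent_corr`` is the (possibly PSD-repaired) latent correlation matrix,
    ``target_corr`` the requested binary correlation matrix.
    """

    f_mf: float
    threshold: float
    latent_corr: np.ndarray
    target_corr: np.ndarray
    psd_distortion: float = 0.0
    _factor: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.latent_corr.shape[0]

    def factor(self) -> np.ndarray:
        """Square-root factor L with L L^T = latent_corr (eigendecomposition)."""
        if self._factor is None:
            w, V = np.linalg.eigh(self.latent_corr)
            self._factor = V * np.sqrt(np.clip(w, 0.0, None))
        return self._factor


def _fit_latent_correlations(t: float, p11_target: np.ndarray) -> np.ndarray:
    """Vectorized bisection for lambda with P(Z1>t, Z2>t; lambda) = p11_target.

    Monotone in lambda (Slepian), so plain bisection on [-bound, bound].
    """
    lo = np.full_like(p11_target, -_RHO_BOUND)
    hi = np.full_like(p11_target, _RHO_BOUND)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = joint_active_probability(t, mid) < p11_target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.max(hi - lo) < _FIT_TOL:
            break
    return 0.5 * (lo + hi)


def _nearest_psd_correlation(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    w, V = np.linalg.eigh(A)
    if w.min() >= -1e-10:
        return A, 0.0
    B = (V * np.clip(w, 0.0, None)) @ V.T
    d = np.sqrt(np.diag(B))
    B = B / np.outer(d, d)
    np.fill_diagonal(B, 1.0)
    distortion = float(np.linalg.norm(B - A))
    return B, distortion


def fit_dichotomized_gaussian(f_mf: float, R: np.ndarray) -> DGModel:
    """Fit latent threshold and correlation matrix for binary targets.

    Parameters
    ----------
    f_mf : float
        Desired mean activity, strictly inside (0, 1).
    R : ndarray (N, N)
        Target binary correlation matrix (unit diagonal).

    Notes
    -----
    Target correlations outside the range attainable by Bernoulli(f_mf)
    marginals are clamped to the feasible interval with a logged warning.
    If eigenvalue clipping is needed to make the latent matrix a valid
    correlation matrix, the Frobenius distortion is recorded on the model.
    """
    if not 0.0 < f_mf < 1.0:
        raise ValueError(f"f_mf must lie strictly in (0, 1), got {f_mf}")
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be a square matrix")
    t = norm.ppf(1.0 - f_mf)  # upper-tail threshold: P(Z > t) = f_mf

    iu = np.triu_indices(R.shape[0], k=1)
    r = R[iu]
    # feasible binary correlation range for equal Bernoulli(f) marginals
    r_lo = max(-f_mf / (1 - f_mf), -(1 - f_mf) / f_mf) + 1e-12
    r_clamped = np.clip(r, r_lo, _RHO_BOUND)
    n_clamped = int(np.count_nonzero(r_clamped != r))
    if n_clamped:
        logger.warning(
            "clamped %d infeasible target correlations into [%.4f, %.4f]",
            n_clamped, r_lo, _RHO_BOUND,
        )

    p11 = f_mf**2 + r_clamped * f_mf * (1.0 - f_mf)
    lam_flat = _fit_latent_correlations(t, p11)
    lam = np.eye(R.shape[0])
    lam[iu] = lam_flat
    lam.T[iu] = lam_flat

    lam, distortion = _nearest_psd_correlation(lam)
    if distortion:
        logger.info("latent correlation PSD repair, Frobenius distortion %.3g", distortion)
    return DGModel(
        f_mf=float(f_mf),
        threshold=float(t),
        latent_corr=lam,
        target_corr=R,
        psd_distortion=distortion,
    )


def sample_patterns(dg: DGModel, n_patterns: int, seed=None) -> PatternEnsemble:
    """Draw binary MF patterns from a fitted dichotomized-Gaussian model."""
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = rng.standard_normal((n_patterns, dg.n)) @ dg.factor().T
    X = (Z > dg.threshold).astype(np.uint8)
    return PatternEnsemble(
        X=X,
        meta={
            "kind": "mf_binary",
            "f_mf": dg.f_mf,
            "n_patterns": int(n_patterns),
            "seed": seed if isinstance(seed, int) else None,
            "psd_distortion": dg.psd_distortion,
        },
    )


def make_correlated_patterns(
    mf_positions: np.ndarray,
    f_mf: float,
    sigma: float,
    n_patterns: int,
    seed=None,
) -> PatternEnsemble:
    """Convenience front-end: kernel -> DG fit -> sampling in one call."""
    R = target_binary_correlation(mf_positions, sigma)
    dg = fit_dichotomized_gaussian(f_mf, R)
    ens = sample_patterns(dg, n_patterns, seed=seed)
    ens.meta["sigma"] = float(sigma)
    return ens


def patterns_to_rates(
    ensemble: PatternEnsemble | np.ndarray,
    active_rate: float = 50.0,
    inactive_rate: float = 0.0,
) -> np.ndarray:
    """Map binary patterns to firing rates (Hz): 1 -> active, 0 -> silent."""
    X = as_matrix(ensemble)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("patterns_to_rates requires a binary ensemble")
    return np.where(X == 1, float(active_rate), float(inactive_rate))
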