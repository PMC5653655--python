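"""Simplified granule-cell layer models.

The core transform is a thresholded rectified-linear unit applied to the
summed, weight-normalized mossy-fiber drive:

    x_i^GC = f+( sum_j (4 / N_syn) C_ij x_j^MF - theta ),   f+(u) = max(0, u)

with threshold ``theta = 3`` by default (about three concurrently active MFs
are needed to fire a granule cell). Variants: ``linear`` drops the threshold
entirely (isolates the effect of network structure), ``adaptive`` raises the
threshold with the fraction of active MFs in each pattern (a minimal model
of feedforward Golgi-cell inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import Connectivity
from .containers import PatternEnsemble, as_matrix

__all__ = ["TransferConfig", "gc_response", "gc_response_adaptive", "threshold_sweep"]

_MODES = ("rectified", "linear", "adaptive")


@dataclass(frozen=True)
class TransferConfig:
    """Granule-cell transfer function parameters.

    theta : threshold in units of "active unit-weight inputs" (default 3).
    mode : "rectified", "linear" or "adaptive".
    adaptive_gain : slope of the per-pattern threshold increment with the
        active-MF fraction; the default 2.5 spans +-1 threshold unit as the
        active fraction moves across [0.1, 0.9].
    f_mf_reference : reference active fraction for the adaptive increment;
        ``None`` uses the ensemble mean.
    """

    theta: float = 3.0
    mode: str = "rectified"
    adaptive_gain: float = 2.5
    f_mf_reference: float | None = None

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")


def _drive(X_mf: np.ndarray, conn: Connectivity) -> np.ndarray:
    if X_mf.shape[1] != conn.n_mf:
        raise ValueError(
            f"pattern width {X_mf.shape[1]} does not match connectivity n_mf={conn.n_mf}"
        )
    w = 4.0 / conn.n_syn
    return w * (X_mf.astype(float) @ conn.C.T.astype(float))


def gc_response(
    X_mf: PatternEnsemble | np.ndarray,
    conn: Connectivity,
    cfg: TransferConfig = TransferConfig(),
) -> PatternEnsemble:
    """Granule-cell responses for every MF pattern.

    Dispatches on ``cfg.mode``; adaptive mode is delegated to
    :func:`gc_response_adaptive`.
    """
    if cfg.mode == "adaptive":
        return gc_response_adaptive(X_mf, conn, cfg)
    X = as_matrix(X_mf)
    drive = _drive(X, conn)
    if cfg.mode == "rectified":
        out = np.maximum(drive - cfg.theta, 0.0)
    else:  # linear: no threshold
        out = drive
    meta = dict(getattr(X_mf, "meta", {}))
    meta.update({"kind": "gc_simplified", "mode": cfg.mode, "theta": cfg.theta,
                 "n_syn": conn.n_syn})
    return PatternEnsemble(X=out, meta=meta)


def gc_response_adaptive(
    X_mf: PatternEnsemble | np.ndarray,
    conn: Connectivity,
    cfg: TransferConfig,
) -> PatternEnsemble:
    """Rectified response with a per-pattern, activity-dependent threshold.

    theta_eff(pattern) = theta + gain * (active fraction - reference), so
    patterns with unusually many active MFs see a higher effective threshold,
    mimicking feedforward inhibition that tracks overall network drive.
    """
    if cfg.mode != "adaptive":
        raise ValueError("gc_response_adaptive requires cfg.mode == 'adaptive'")
    X = as_matrix(X_mf)
    frac_active = X.mean(axis=1)
    ref = cfg.f_mf_reference
    if ref is None:
        ref = float(frac_active.mean())
    theta_eff = cfg.theta + cfg.adaptive_gain * (frac_active - ref)
    drive = _drive(X, conn)
    out = np.maximum(drive - theta_eff[:, None], 0.0)
    meta = dict(getattr(X_mf, "meta", {}))
    meta.update({"kind": "gc_simplified", "mode": "adaptive", "theta": cfg.theta,
                 "adaptive_gain": cfg.adaptive_gain, "n_syn": conn.n_syn})
    return PatternEnsemble(X=out, meta=meta)


def threshold_sweep(
    X_mf: PatternEnsemble | np.ndarray,
    conn: Connectivity,
    theta_grid,
    mode: str = "rectified",
) -> dict[float, PatternEnsemble]:
    """One GC ensemble per threshold value (downstream metrics via popstats)."""
    theta_grid = list(theta_grid)
    if not theta_grid:
        raise ValueError("theta_grid must be non-empty")
    return {
        float(theta): gc_response(X_mf, conn, TransferConfig(theta=float(theta), mode=mode))
        for theta in theta_grid
    }
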