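"""Experiment orchestration: parameter sweeps and normalized-metric maps.

A "condition" is one parameter cell (N_syn, f_MF, sigma, model). Running it
composes the stages: anatomy -> correlated MF patterns -> GC transform
(simplified / linear / adaptive / spiking) -> population statistics for both
populations -> perceptron learning on both populations, all seed-logged.
Sweeps reuse the MF-side work (patterns, statistics, training) across
N_syn values, since the input side does not depend on the wiring.

Seeds are managed with ``numpy.random.SeedSequence``: a base seed plus a
stage-specific child index gives every stage its own reproducible stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from . import anatomy, gc_models, gc_spiking, learning, mf_patterns, popstats, shuffling

__all__ = [
    "SweepSpec",
    "run_condition",
    "run_sweep",
    "run_shuffle_experiment",
    "summarize_sweep",
]

logger = logging.getLogger(__name__)

_MODELS = ("simplified", "linear", "adaptive", "spiking")

# child indices for per-stage seed derivation
_STAGE = {"geometry": 0, "wiring": 1, "patterns": 2, "task": 3,
          "train_mf": 4, "train_gc": 5, "spiking": 6, "shuffle": 7,
          "train_shuffled": 8}


def stage_rng(base_seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Independent reproducible stream for one pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence(base_seed, spawn_key=(_STAGE[stage], *extra))
    )


@dataclass(frozen=True)
class SweepSpec:
    """Grid definition and shared protocol parameters for one sweep."""

    n_syn_grid: tuple = (1, 2, 3, 4, 6, 8, 12, 16)
    f_mf_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    sigma: float = 20.0
    model: str = "simplified"
    theta: float = 3.0
    n_patterns: int = 640
    n_classes: int = 10
    n_seeds: int = 3
    n_mf: int = anatomy.DEFAULT_N_MF
    n_gc: int = anatomy.DEFAULT_N_GC
    radius: float = anatomy.DEFAULT_RADIUS_UM
    base_seed: int = 0
    perceptron: learning.PerceptronConfig = field(default_factory=learning.PerceptronConfig)
    spiking: gc_spiking.SpikingConfig = field(default_factory=gc_spiking.SpikingConfig)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if not self.n_syn_grid or not self.f_mf_grid:
            raise ValueError("grids must be non-empty")


def _build_network(spec: SweepSpec, n_syn: int, seed_idx: int):
    geom = anatomy.place_cells(
        spec.radius, spec.n_mf, spec.n_gc,
        seed=stage_rng(spec.base_seed, "geometry", seed_idx),
    )
    conn = anatomy.wire_network(
        geom, n_syn, seed=stage_rng(spec.base_seed, "wiring", seed_idx, n_syn)
    )
    return geom, conn


def _mf_side(spec: SweepSpec, geom, f_mf: float, seed_idx: int):
    """MF ensemble, statistics, task labels and MF training (N_syn-independent)."""
    ens = mf_patterns.make_correlated_patterns(
        geom.mf_positions, f_mf, spec.sigma, spec.n_patterns,
        seed=stage_rng(spec.base_seed, "patterns", seed_idx, int(round(1000 * f_mf))),
    )
    labels = learning.assign_classes(
        spec.n_patterns, spec.n_classes,
        seed=stage_rng(spec.base_seed, "task", seed_idx, int(round(1000 * f_mf))),
    )
    X_train = ens
    if spec.model == "spiking":
        # MF side of the spiking comparison is computed together with the GC
        # side (shared Poisson draws), so training happens in run_condition.
        return ens, labels, None, None
    stats = popstats.compute_stats(ens)
    res = learning.train_classifier(
        X_train, labels, spec.perceptron,
        seed=stage_rng(spec.base_seed, "train_mf", seed_idx, int(round(1000 * f_mf))),
    )
    return ens, labels, stats, res


def _gc_ensemble(spec: SweepSpec, conn, mf_ens, f_mf: float, seed_idx: int):
    if spec.model == "spiking":
        gc_counts, mf_counts = gc_spiking.run_spiking_condition(
            mf_ens, conn, spec.spiking,
            seed=stage_rng(spec.base_seed, "spiking", seed_idx, conn.n_syn,
                           int(round(1000 * f_mf))),
        )
        return gc_counts, mf_counts
    mode = {"simplified": "rectified", "linear": "linear", "adaptive": "adaptive"}[spec.model]
    cfg = gc_models.TransferConfig(theta=spec.theta, mode=mode, f_mf_reference=f_mf)
    return gc_models.gc_response(mf_ens, conn, cfg), None


def run_condition(
    spec: SweepSpec,
    n_syn: int,
    f_mf: float,
    seed_idx: int = 0,
    _mf_cache: dict | None = None,
) -> dict[str, Any]:
    """All metrics for one (N_syn, f_MF, sigma, model) cell.

    Returns a flat record with raw and normalized sparseness, total
    variance, population correlation and learning speed for the MF input
    and GC output populations.
    """
    geom, conn = _build_network(spec, n_syn, seed_idx)
    key = (f_mf, seed_idx)
    if _mf_cache is not None and key in _mf_cache:
        mf_ens, labels, mf_stats, mf_res = _mf_cache[key]
    else:
        mf_ens, labels, mf_stats, mf_res = _mf_side(spec, geom, f_mf, seed_idx)
        if _mf_cache is not None:
            _mf_cache[key] = (mf_ens, labels, mf_stats, mf_res)

    gc_ens, mf_override = _gc_ensemble(spec, conn, mf_ens, f_mf, seed_idx)
    if mf_override is not None:  # spiking model: MF side = spike counts
        mf_stats = popstats.compute_stats(mf_override)
        mf_res = learning.train_classifier(
            mf_override, labels, spec.perceptron,
            seed=stage_rng(spec.base_seed, "train_mf", seed_idx, int(round(1000 * f_mf))),
        )
    gc_stats = popstats.compute_stats(gc_ens)
    gc_res = learning.train_classifier(
        gc_ens, labels, spec.perceptron,
        seed=stage_rng(spec.base_seed, "train_gc", seed_idx, n_syn,
                       int(round(1000 * f_mf))),
    )

    rec: dict[str, Any] = {
        "model": spec.model, "n_syn": n_syn, "f_mf": f_mf, "sigma": spec.sigma,
        "theta": spec.theta, "seed_idx": seed_idx, "base_seed": spec.base_seed,
        "mf_sparseness": mf_stats.sparseness,
        "gc_sparseness": gc_stats.sparseness,
        "mf_total_variance": mf_stats.total_variance,
        "gc_total_variance": gc_stats.total_variance,
        "mf_population_correlation": mf_stats.population_correlation,
        "gc_population_correlation": gc_stats.population_correlation,
        "mf_speed": mf_res.speed, "gc_speed": gc_res.speed,
        "mf_epochs": mf_res.n_epochs, "gc_epochs": gc_res.n_epochs,
        "gc_fraction_inactive": gc_stats.fraction_inactive,
    }
    for name in ("sparseness", "total_variance", "population_correlation"):
        mf_v, gc_v = rec[f"mf_{name}"], rec[f"gc_{name}"]
        rec[f"norm_{name}"] = gc_v / mf_v if mf_v else np.nan
    rec["norm_speed"] = rec["gc_speed"] / rec["mf_speed"] if rec["mf_speed"] else np.nan
    return rec


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run every (N_syn, f_MF, seed) cell of the sweep; one row per cell."""
    rows = []
    for seed_idx in range(spec.n_seeds):
        mf_cache: dict = {}
        for f_mf in spec.f_mf_grid:
            for n_syn in spec.n_syn_grid:
                rows.append(run_condition(spec, n_syn, f_mf, seed_idx, mf_cache))
                logger.info("cell model=%s n_syn=%d f_mf=%.2f seed=%d done",
                            spec.model, n_syn, f_mf, seed_idx)
    return pd.DataFrame(rows)


def run_shuffle_experiment(
    spec: SweepSpec,
    n_syn: int,
    f_mf: float,
    seed_idx: int = 0,
    tolerance: float = 0.005,
    max_iterations: int = 500,
) -> dict[str, Any]:
    """GC vs shuffled-GC learning with the GC correlation clamped to the MF value.

    The GC ensemble is shuffled until its population correlation matches the
    MF population correlation (preserving every per-neuron marginal), then
    the classifier is trained on the true and the shuffled patterns. The
    speed ratio isolates what correlations (not expansion or sparsening)
    contribute to learning.
    """
    geom, conn = _build_network(spec, n_syn, seed_idx)
    mf_ens, labels, mf_stats, _ = _mf_side(spec, geom, f_mf, seed_idx)
    if spec.model == "spiking":
        gc_ens, mf_counts = _gc_ensemble(spec, conn, mf_ens, f_mf, seed_idx)
        mf_stats = popstats.compute_stats(mf_counts)
    else:
        gc_ens, _ = _gc_ensemble(spec, conn, mf_ens, f_mf, seed_idx)
    target_pc = mf_stats.population_correlation

    shuffle_seed = int(
        stage_rng(spec.base_seed, "shuffle", seed_idx, n_syn,
                  int(round(1000 * f_mf))).integers(2**31)
    )
    cfg = shuffling.ShuffleConfig(target_pc=target_pc, tolerance=tolerance,
                                  max_iterations=max_iterations, seed=shuffle_seed)
    shuffled = shuffling.shuffle_to_target(gc_ens, cfg)
    report = shuffling.verify_shuffle(gc_ens, shuffled)

    gc_res = learning.train_classifier(
        gc_ens, labels, spec.perceptron,
        seed=stage_rng(spec.base_seed, "train_gc", seed_idx, n_syn,
                       int(round(1000 * f_mf))),
    )
    sh_res = learning.train_classifier(
        shuffled, labels, spec.perceptron,
        seed=stage_rng(spec.base_seed, "train_shuffled", seed_idx, n_syn,
                       int(round(1000 * f_mf))),
    )
    ratio = (gc_res.speed / sh_res.speed) if sh_res.speed else np.nan
    return {
        "model": spec.model, "n_syn": n_syn, "f_mf": f_mf, "sigma": spec.sigma,
        "seed_idx": seed_idx,
        "target_pc": target_pc,
        "achieved_pc": shuffled.meta["shuffle_achieved_pc"],
        "gc_pc": popstats.population_correlation(gc_ens.X),
        "gc_speed": gc_res.speed, "shuffled_speed": sh_res.speed,
        "speed_ratio_gc_over_shuffled": ratio,
        "marginals_preserved": report.marginals_preserved,
        "total_variance_error": report.total_variance_error,
    }


def summarize_sweep(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Medians over f_MF and robustness per (model, sigma, n_syn).

    Seed replicates are averaged first; the median is then taken over the
    f_MF grid, and robustness is the fraction of f_MF cells whose normalized
    value exceeds 1.
    """
    metrics = ["norm_speed", "norm_sparseness", "norm_total_variance",
               "norm_population_correlation"]
    cell = (df.groupby(["model", "sigma", "n_syn", "f_mf"], as_index=False)[metrics]
              .mean())
    med = (cell.groupby(["model", "sigma", "n_syn"], as_index=False)[metrics]
               .median()
               .rename(columns={m: f"median_{m}" for m in metrics}))
    rob = (cell.groupby(["model", "sigma", "n_syn"], as_index=False)[metrics]
               .agg(lambda v: float((np.asarray(v) > 1.0).mean()))
               .rename(columns={m: f"robustness_{m}" for m in metrics}))
    return {"cells": cell, "medians": med, "robustness": rob}
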