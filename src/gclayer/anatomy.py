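"""Anatomically constrained local network of the cerebellar input layer.

Mossy-fiber (MF) rosettes and granule cells (GCs) are placed uniformly at
random inside an 80 um diameter ball (~180 rosettes, ~480 GCs in the default
local volume). Each GC is wired to ``n_syn`` distinct MFs chosen at random
under the constraint that the MF-GC distance is as close as possible to the
mean dendritic length of 15 um.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkGeometry",
    "Connectivity",
    "place_cells",
    "wire_network",
    "save_network",
    "load_network",
]

DEFAULT_RADIUS_UM = 40.0
DEFAULT_N_MF = 180
DEFAULT_N_GC = 480
DEFAULT_TARGET_LENGTH_UM = 15.0
DEFAULT_TOLERANCE_SCALE_UM = 5.0


@dataclass
class NetworkGeometry:
    """3-D positions (um, Cartesian, ball centred at the origin)."""

    radius: float
    mf_positions: np.ndarray  # (n_mf, 3)
    gc_positions: np.ndarray  # (n_gc, 3)
    seed: int | None = None

    @property
    def n_mf(self) -> int:
        return self.mf_positions.shape[0]

    @property
    def n_gc(self) -> int:
        return self.gc_positions.shape[0]

    @property
    def expansion_ratio(self) -> float:
        """Realized GC:MF count ratio (reported, never forced)."""
        return self.n_gc / self.n_mf if self.n_mf else np.nan


@dataclass
class Connectivity:
    """Binary MF->GC wiring with fixed in-degree.

    ``C`` is (n_gc, n_mf) with exactly ``n_syn`` ones per row;
    ``mf_indices[i]`` lists the ``n_syn`` distinct MFs of GC ``i`` and
    ``dendrite_lengths[i]`` the corresponding Euclidean MF-GC distances.
    """

    C: np.ndarray
    n_syn: int
    mf_indices: np.ndarray  # (n_gc, n_syn) int
    dendrite_lengths: np.ndarray  # (n_gc, n_syn) um

    @property
    def n_gc(self) -> int:
        return self.C.shape[0]

    @property
    def n_mf(self) -> int:
        return self.C.shape[1]

    @property
    def mean_dendrite_length(self) -> float:
        return float(self.dendrite_lengths.mean())


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def place_cells(
    radius: float = DEFAULT_RADIUS_UM,
    n_mf: int = DEFAULT_N_MF,
    n_gc: int = DEFAULT_N_GC,
    seed=None,
) -> NetworkGeometry:
    """Place MF rosettes and GCs uniformly at random inside a ball.

    Parameters
    ----------
    radius : float
        Ball radius in um (default 40, i.e. the 80 um diameter local volume).
    n_mf, n_gc : int
        Number of MF rosettes and GCs to place.
    seed : int, Generator or None
        Reproducibility handle.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if n_mf < 0 or n_gc < 0:
        raise ValueError("cell counts must be non-negative")
    rng = _as_rng(seed)

    def _ball(n: int) -> np.ndarray:
        # rejection sampling from the enclosing cube; acceptance ~0.52
        out = np.empty((n, 3))
        have = 0
        while have < n:
            cand = rng.uniform(-radius, radius, size=(max(2 * (n - have), 16), 3))
            keep = cand[np.einsum("ij,ij->i", cand, cand) <= radius**2]
            take = min(len(keep), n - have)
            out[have : have + take] = keep[:take]
            have += take
        return out

    return NetworkGeometry(
        radius=float(radius),
        mf_positions=_ball(n_mf),
        gc_positions=_ball(n_gc),
        seed=seed if isinstance(seed, int) else None,
    )


def wire_network(
    geom: NetworkGeometry,
    n_syn: int,
    target_length: float = DEFAULT_TARGET_LENGTH_UM,
    length_tolerance_scale: float = DEFAULT_TOLERANCE_SCALE_UM,
    seed=None,
    mode: str = "weighted",
) -> Connectivity:
    """Wire each GC to ``n_syn`` distinct MFs with dendrites near 15 um.

    The selection rule is random-but-constrained: candidate MFs are drawn
    without replacement with weight ``exp(-(d - target)^2 / (2 s^2)) / d^2``
    where ``d`` is the MF-GC distance and ``s = length_tolerance_scale``.
    The ``1/d^2`` factor cancels the radial growth of the number of
    candidate MFs at distance ``d`` in a uniform 3-D volume, so realized
    dendritic lengths are distributed around the target (mean ~15 um)
    rather than biased upward. As ``s -> 0`` the rule converges to the
    deterministic choice of the ``n_syn`` MFs whose distances are nearest
    the target, which is also available directly as ``mode="nearest"``.
    """
    if n_syn < 1:
        raise ValueError("n_syn must be >= 1")
    if geom.n_mf == 0 or geom.n_gc == 0:
        raise ValueError("geometry must contain at least one MF and one GC")
    if n_syn > geom.n_mf:
        raise ValueError(
            f"infeasible wiring: n_syn={n_syn} exceeds number of MFs ({geom.n_mf})"
        )
    if mode not in ("weighted", "nearest"):
        raise ValueError(f"unknown wiring mode {mode!r}")
    rng = _as_rng(seed)

    # (n_gc, n_mf) distances
    diff = geom.gc_positions[:, None, :] - geom.mf_positions[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    dev = np.abs(dist - target_length)

    if mode == "nearest":
        idx = np.argsort(dev, axis=1, kind="stable")[:, :n_syn]
    else:
        # Gumbel top-k = weighted sampling without replacement;
        # -2 log d corrects for the r^2 radial density of candidates
        logw = -((dist - target_length) ** 2) / (2.0 * length_tolerance_scale**2)
        logw -= 2.0 * np.log(np.maximum(dist, 1e-9))
        gumbel = rng.gumbel(size=dist.shape)
        idx = np.argpartition(-(logw + gumbel), n_syn - 1, axis=1)[:, :n_syn]

    idx = np.sort(idx, axis=1)
    C = np.zeros((geom.n_gc, geom.n_mf), dtype=np.uint8)
    np.put_along_axis(C, idx, 1, axis=1)
    lengths = np.take_along_axis(dist, idx, axis=1)
    return Connectivity(C=C, n_syn=int(n_syn), mf_indices=idx, dendrite_lengths=lengths)


def save_network(geom: NetworkGeometry, conn: Connectivity, path_prefix: str | Path) -> None:
    """Serialize geometry to JSON and wiring arrays to ``.npz``; exact round-trip."""
    prefix = Path(path_prefix)
    doc = {
        "radius_um": geom.radius,
        "seed": geom.seed,
        "n_syn": conn.n_syn,
        "mf_positions_um": geom.mf_positions.tolist(),
        "gc_positions_um": geom.gc_positions.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(doc))
    np.savez_compressed(
        prefix.with_suffix(".npz"),
        C=conn.C,
        mf_indices=conn.mf_indices,
        dendrite_lengths=conn.dendrite_lengths,
    )


def load_network(path_prefix: str | Path) -> tuple[NetworkGeometry, Connectivity]:
    prefix = Path(path_prefix)
    doc = json.loads(prefix.with_suffix(".json").read_text())
    geom = NetworkGeometry(
        radius=doc["radius_um"],
        mf_positions=np.asarray(doc["mf_positions_um"], dtype=float).reshape(-1, 3),
        gc_positions=np.asarray(doc["gc_positions_um"], dtype=float).reshape(-1, 3),
        seed=doc.get("seed"),
    )
    with np.load(prefix.with_suffix(".npz")) as npz:
        conn = Connectivity(
            C=npz["C"],
            n_syn=int(doc["n_syn"]),
            mf_indices=npz["mf_indices"],
            dendrite_lengths=npz["dendrite_lengths"],
        )
    return geom, conn
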