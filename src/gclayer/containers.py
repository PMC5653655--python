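"""Shared in-memory container for population activity patterns.

A :class:`PatternEnsemble` is a ``(n_patterns, n_neurons)`` matrix of
activity values — 0/1 for mossy-fiber (MF) patterns, non-negative reals for
simplified granule-cell (GC) responses, integer spike counts for the spiking
model — plus provenance metadata (mean input activity ``f_mf``, correlation
radius ``sigma``, seeds, generator stage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["PatternEnsemble"]


@dataclass
class PatternEnsemble:
    """Activity patterns of one neural population.

    Parameters
    ----------
    X : ndarray, shape (n_patterns, n_neurons)
        One activity pattern per row.
    meta : dict
        Provenance (f_mf, sigma, seed, stage, ...). Stored as-is.
    labels : ndarray or None
        Optional per-pattern class labels for the learning assay.
    """

    X: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n_patterns, n_neurons)")
        if self.X.shape[0] < 1:
            raise ValueError("ensemble needs at least one pattern")

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.X.shape[1]

    def is_binary(self) -> bool:
        return bool(np.isin(self.X, (0, 1)).all())

    def save(self, path: str | Path) -> None:
        """Write arrays to ``<path>.npz`` and metadata to ``<path>.json``."""
        path = Path(path)
        arrays = {"X": self.X}
        if self.labels is not None:
            arrays["labels"] = self.labels
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=1, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "PatternEnsemble":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as npz:
            X = npz["X"]
            labels = npz["labels"] if "labels" in npz.files else None
        meta_path = path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(X=X, meta=meta, labels=labels)


def as_matrix(x: "PatternEnsemble | np.ndarray") -> np.ndarray:
    """Accept either an ensemble or a bare (P, N) array."""
    if isinstance(x, PatternEnsemble):
        return x.X
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (n_patterns, n_neurons) array")
    return x
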