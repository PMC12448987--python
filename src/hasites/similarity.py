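"""Inter-protein distance from HA-site attention trajectories, plus pooled
embedding baselines.

A residue's *trajectory* is its normalized attention across all L layers —
one column of the heatmap.  A protein is represented by the set of
trajectories of its HA sites; the distance between two proteins is the mean
cosine distance over all cross pairs of their trajectory sets.  Trajectory
vectors have length L regardless of sequence length, so the distance is
independent of protein length.

The three conventional whole-protein baselines (CLS token, mean pooling,
max pooling of the per-residue embedding matrix) are provided for
comparison; all four measures plug into the same evaluation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .attention_store import EmbeddingMatrix
from .layer_profile import AttentionHeatmap

__all__ = [
    "HATrajectory",
    "HATrajectorySet",
    "EmptyTrajectorySetError",
    "ha_trajectories",
    "cosine_distance",
    "protein_distance",
    "pooled_vector",
    "distance_matrix",
    "write_distance_matrix",
]

POOL_MODES = ("cls", "mean", "max")


class EmptyTrajectorySetError(ValueError):
    """A protein without HA sites cannot enter the trajectory distance."""


@dataclass
class HATrajectory:
    """Normalized attention of one residue across layers (length L)."""

    protein_id: str
    position: int  # 1-based residue position
    t: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)


@dataclass
class HATrajectorySet:
    protein_id: str
    trajectories: list[HATrajectory]

    def __len__(self) -> int:
        return len(self.trajectories)

    def as_matrix(self) -> np.ndarray:
        return np.vstack([tr.t for tr in self.trajectories])


def ha_trajectories(
    heatmap: AttentionHeatmap, ha_positions: list[int]
) -> HATrajectorySet:
    """Read the heatmap column of each HA position (1-based)."""
    trajs = []
    for pos in ha_positions:
        if not 1 <= pos <= heatmap.n:
            raise IndexError(
                f"{heatmap.protein_id}: position {pos} outside 1..{heatmap.n}"
            )
        trajs.append(HATrajectory(heatmap.protein_id, pos, heatmap.matrix[:, pos - 1]))
    return HATrajectorySet(heatmap.protein_id, trajs)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 − cos(u, v); in [0, 1] for non-negative vectors, [0, 2] in general."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def protein_distance(a: HATrajectorySet, b: HATrajectorySet) -> float:
    """Mean cosine distance over all |a| × |b| trajectory cross pairs.

    Symmetric and zero on identical sets; no bipartite matching is
    attempted.  Raises :class:`EmptyTrajectorySetError` if either protein
    has no HA sites, so the caller can distinguish exclusion from failure.
    """
    if len(a) == 0 or len(b) == 0:
        empty = a.protein_id if len(a) == 0 else b.protein_id
        raise EmptyTrajectorySetError(f"{empty} has no HA sites")
    A = a.as_matrix()
    B = b.as_matrix()
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("cosine distance undefined for a zero trajectory")
    sims = (A @ B.T) / np.outer(na, nb)
    return float(np.mean(1.0 - sims))


def pooled_vector(embeddings: EmbeddingMatrix, mode: str) -> np.ndarray:
    """Whole-protein vector by CLS token, per-dimension mean, or max."""
    if mode not in POOL_MODES:
        raise ValueError(f"mode must be one of {POOL_MODES}; got {mode!r}")
    if mode == "cls":
        if embeddings.cls_vector is None:
            raise ValueError(
                f"{embeddings.protein_id}: no CLS vector stored in archive"
            )
        return embeddings.cls_vector.copy()
    if mode == "mean":
        return embeddings.vectors.mean(axis=0)
    return embeddings.vectors.max(axis=0)


def distance_matrix(
    sets: list[HATrajectorySet] | list[np.ndarray],
    ids: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Symmetric pairwise distance matrix over trajectory sets or vectors."""
    k = len(sets)
    if ids is None:
        ids = [
            s.protein_id if isinstance(s, HATrajectorySet) else str(i)
            for i, s in enumerate(sets)
        ]
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if isinstance(sets[i], HATrajectorySet):
                d = protein_distance(sets[i], sets[j])
            else:
                d = cosine_distance(sets[i], sets[j])
            D[i, j] = D[j, i] = d
    return D, ids


def write_distance_matrix(
    D: np.ndarray, ids: list[str], path: str | Path
) -> None:
    pd.DataFrame(D, index=ids, columns=ids).to_csv(path, sep="\t")
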