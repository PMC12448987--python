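"""Per-layer attention summarization: head pooling, column importance, and
the normalized L × n heatmap.

For one protein of length ``n``, each transformer layer yields ``H`` head
attention matrices.  Heads are mean-pooled into a single n × n matrix per
layer; a column-wise sum then measures how much total attention each
residue *receives* across all query positions (summing rows would instead
measure how much it distributes, which is not a notion of importance).
Each layer's column-sum vector ``s_l`` is divided by its maximum to give a
normalized profile ``v_l`` in [0, 1], and the per-layer profiles are
stacked into an L × n heatmap whose rows trace the progression of residue
importance through the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .attention_store import AttentionTensor

__all__ = [
    "LayerProfile",
    "AttentionHeatmap",
    "pool_heads",
    "column_importance",
    "normalize_profile",
    "build_heatmap",
]


class DegenerateLayerError(ValueError):
    """An all-zero attention layer: impossible for softmax output."""


@dataclass
class LayerProfile:
    """Raw and max-normalized column importance for one layer."""

    layer: int
    raw_sums: np.ndarray
    normalized: np.ndarray


@dataclass
class AttentionHeatmap:
    """L × n matrix; row ``l`` is the normalized profile of layer ``l``."""

    protein_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("heatmap must be a 2-d (L, n) array")

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Export with layer rows and 1-based residue position columns."""
        df = pd.DataFrame(
            self.matrix,
            index=pd.Index(range(self.L), name="layer"),
            columns=[str(p) for p in range(1, self.n + 1)],
        )
        df.to_csv(path, sep="\t")


def pool_heads(tensor: AttentionTensor, layer: int) -> np.ndarray:
    """Mean-pool the attention heads of one layer into an n × n matrix."""
    if not 0 <= layer < tensor.L:
        raise IndexError(f"layer {layer} out of range [0, {tensor.L})")
    return tensor.values[layer].mean(axis=0)


def column_importance(pooled: np.ndarray) -> np.ndarray:
    """Sum each column of a pooled attention matrix.

    Entry ``j`` is the total attention allocated to residue ``j`` over all
    query positions.  For a row-stochastic matrix the entries sum to n.
    """
    pooled = np.asarray(pooled, dtype=np.float64)
    if pooled.ndim != 2 or pooled.shape[0] != pooled.shape[1]:
        raise ValueError(f"pooled attention must be square; got {pooled.shape}")
    return pooled.sum(axis=0)


def normalize_profile(raw: np.ndarray) -> np.ndarray:
    """Divide by the maximum so the profile lies in [0, 1] with max exactly 1.

    Ties for the maximum are left untouched (several entries may equal 1).
    An all-zero vector signals a malformed layer and raises
    :class:`DegenerateLayerError`.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.min() < 0:
        raise ValueError("column importances must be non-negative")
    peak = raw.max()
    if peak <= 0:
        raise DegenerateLayerError("all-zero importance vector (degenerate layer)")
    return raw / peak


def build_heatmap(tensor: AttentionTensor) -> AttentionHeatmap:
    """Assemble the L × n heatmap of normalized per-layer profiles."""
    rows = []
    for layer in range(tensor.L):
        try:
            rows.append(normalize_profile(column_importance(pool_heads(tensor, layer))))
        except DegenerateLayerError as exc:
            raise DegenerateLayerError(f"layer {layer}: {exc}") from exc
    return AttentionHeatmap(tensor.protein_id, np.vstack(rows))
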