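"""Synthetic attention tensors, families, embeddings, contact maps and CA
traces with planted ground truth.

The generator emulates the three-phase attention dynamics observed in
protein language models: near-uniform attention in early layers, sharply
concentrated attention on a small planted residue set around a mid-network
convergence layer, and locally banded attention in late layers, with the
residual planted-site mass decaying to zero by the last layer.  Rows of
every head are exactly row-stochastic.

Within the convergence window the planted sites receive geometrically
decreasing shares of the concentrated mass (strongest heterogeneity at the
convergence layer itself, relaxing over the following two layers).  Real
sorted attention profiles decay steeply over the top residues rather than
forming a flat plateau, and it is this spread that gives the two-segment
fit its near-vertical left segment; making the planted shares heterogeneous
reproduces that geometry and makes the convergence layer the unique angle
optimum rather than a three-way coin flip among the window layers.

Embeddings are generated as a large shared offset plus per-position
background vectors common to all proteins, a small family direction, and
per-member noise.  Pooled vectors are therefore dominated by components
that carry no family information — mirroring the tendency of whole-protein
pooling to wash out residue-level family signal — while HA trajectories
remain family-specific.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .attention_store import AttentionTensor, ContactMap, EmbeddingMatrix, ProteinRecord
from .structure_eval import ResidueCoordinates

__all__ = [
    "SyntheticSpec",
    "make_attention_tensor",
    "make_family",
    "make_structure",
    "contact_map_from_structure",
    "make_embeddings",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: embedding-generator constants: dimension, shared-offset scale, family
#: direction scale, per-member noise, per-position background scale
EMB_DIM = 32
EMB_OFFSET_SCALE = 3.0
EMB_FAMILY_SCALE = 0.15
EMB_NOISE_SCALE = 0.5
EMB_BACKGROUND_SCALE = 1.0
_BACKGROUND_SEED = 987654321  # fixed: the background is a generator constant

CA_SPACING_A = 3.8


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic attention tensor.

    ``concentration`` is the fraction of each row's mass directed at the
    planted sites in the convergence window; ``site_decay`` the geometric
    ratio between successive planted-site shares at the convergence layer;
    ``noise_sigma`` the log-normal sigma of elementwise multiplicative
    noise (rows are renormalized afterwards); ``band_width`` the half-width
    of the late-layer circular attention band.
    """

    n: int = 120
    L: int = 33
    H: int = 4
    planted_sites: tuple[int, ...] = (30, 60, 90)  # 1-based
    conv_layer: int = 10
    concentration: float = 0.6
    site_decay: float = 0.75
    noise_sigma: float = 0.05
    band_width: int = 3
    seed: int = 0
    contact_map: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not all(1 <= p <= self.n for p in self.planted_sites):
            raise ValueError(f"planted sites must lie in 1..{self.n}")
        if len(set(self.planted_sites)) != len(self.planted_sites):
            raise ValueError("planted sites must be distinct")
        if not 0 <= self.conv_layer < self.L:
            raise ValueError("conv_layer outside 0..L-1")
        if not 0 < self.concentration <= 1:
            raise ValueError("concentration must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")


def _site_weights(n_sites: int, ratio: float) -> np.ndarray:
    w = ratio ** np.arange(n_sites)
    return w / w.sum()


def _band_row(n: int, i: int, width: int) -> np.ndarray:
    """Circular band: uniform mass on positions within ``width`` of i,
    wrapping at the ends so every column receives the same total."""
    row = np.zeros(n)
    offs = np.arange(-width, width + 1)
    row[(i + offs) % n] = 1.0 / (2 * width + 1)
    return row


def _base_layer(spec: SyntheticSpec, layer: int) -> np.ndarray:
    """Noise-free n × n row allocation for one layer."""
    n, c = spec.n, spec.concentration
    planted = np.asarray(spec.planted_sites, dtype=int) - 1
    window_end = min(spec.conv_layer + 2, spec.L - 1)
    base = np.full((n, n), 1.0 / n)
    if layer < spec.conv_layer:
        return base
    if spec.contact_map is not None and layer == spec.L - 1:
        # tiny floor only to guard against all-zero rows; anything larger
        # would scramble the rank order of weak contacts
        cm = np.asarray(spec.contact_map, dtype=np.float64) + 1e-9
        return cm / cm.sum(axis=1, keepdims=True)
    if layer <= window_end:
        ratio = min(spec.site_decay + 0.1 * (layer - spec.conv_layer), 0.95)
        w = _site_weights(len(planted), ratio)
        base *= 1 - c
        base[:, planted] += c * w
        return base
    # late layers: banded locality plus linearly decaying planted residue
    span = max(spec.L - 1 - window_end, 1)
    residual = c * (spec.L - 1 - layer) / span
    w = _site_weights(len(planted), 0.95)
    base *= 1 - c
    base[:, planted] += residual * w
    band = np.vstack([_band_row(n, i, spec.band_width) for i in range(n)])
    base += (c - residual) * band
    return base


def make_attention_tensor(spec: SyntheticSpec) -> AttentionTensor:
    """Generate a row-stochastic (L, H, n, n) tensor per the spec.

    Multiplicative log-normal noise is applied elementwise per head before
    each row is renormalized to sum exactly 1, so the one hard invariant of
    softmax attention is preserved at any noise level.  Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(spec.seed)
    values = np.empty((spec.L, spec.H, spec.n, spec.n))
    for layer in range(spec.L):
        base = _base_layer(spec, layer)
        for head in range(spec.H):
            m = base
            if spec.noise_sigma > 0:
                m = base * rng.lognormal(0.0, spec.noise_sigma, size=base.shape)
            values[layer, head] = m / m.sum(axis=1, keepdims=True)
    meta = {
        "model": "synthetic",
        "renormalized": False,
        "planted_sites": [int(p) for p in spec.planted_sites],
        "conv_layer": int(spec.conv_layer),
        "seed": int(spec.seed),
    }
    return AttentionTensor("synthetic", values, meta)


def random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def make_embeddings(
    protein_id: str,
    n: int,
    family_vector: np.ndarray,
    rng: np.random.Generator,
) -> EmbeddingMatrix:
    """Per-residue embeddings: shared offset + shared per-position background
    + small family direction + member noise.  The CLS vector follows the
    same recipe with its own background."""
    bg_rng = np.random.default_rng(_BACKGROUND_SEED)
    offset = bg_rng.normal(0, 1, EMB_DIM) * EMB_OFFSET_SCALE
    background = bg_rng.normal(0, EMB_BACKGROUND_SCALE, (n, EMB_DIM))
    cls_background = bg_rng.normal(0, EMB_BACKGROUND_SCALE, EMB_DIM)
    fam = EMB_FAMILY_SCALE * family_vector
    vectors = (
        offset + background + fam + rng.normal(0, EMB_NOISE_SCALE, (n, EMB_DIM))
    )
    cls = offset + cls_background + fam + rng.normal(0, EMB_NOISE_SCALE, EMB_DIM)
    return EmbeddingMatrix(protein_id, vectors, cls)


def make_family(
    size: int,
    length: int = 120,
    planted_sites: tuple[int, ...] | None = None,
    trajectory_jitter: float = 0.05,
    seed: int = 0,
    family_id: str = "FAM",
    conv_layer: int | None = None,
    L: int = 33,
    H: int = 4,
    n_sites: int = 3,
    with_embeddings: bool = True,
) -> list[tuple[ProteinRecord, AttentionTensor, EmbeddingMatrix | None]]:
    """A family of proteins sharing planted sites and convergence layer.

    Planted sites and the convergence layer are drawn once per family
    (seeded) unless given; each member then gets its own noise realization
    of the shared attention program, a random sequence, and embeddings
    built around the family's direction vector.
    """
    if size < 2:
        raise ValueError("a family needs at least 2 members")
    rng = np.random.default_rng(seed)
    if planted_sites is None:
        planted_sites = tuple(
            sorted(int(p) + 1 for p in rng.choice(length, size=n_sites, replace=False))
        )
    if conv_layer is None:
        conv_layer = int(rng.integers(max(1, L // 4), max(2, L // 2)))
    fam_vec = rng.normal(0, 1, EMB_DIM)
    fam_vec /= np.linalg.norm(fam_vec)
    members = []
    for m in range(size):
        member_seed = int(rng.integers(0, 2**31 - 1))
        spec = SyntheticSpec(
            n=length,
            L=L,
            H=H,
            planted_sites=planted_sites,
            conv_layer=conv_layer,
            noise_sigma=trajectory_jitter,
            seed=member_seed,
        )
        tensor = make_attention_tensor(spec)
        pid = f"{family_id}_m{m}"
        tensor.protein_id = pid
        record = ProteinRecord(pid, random_sequence(length, rng), family_id)
        emb = None
        if with_embeddings:
            emb = make_embeddings(pid, length, fam_vec, rng)
        members.append((record, tensor, emb))
    return members


def make_structure(
    n: int,
    planted_sites: tuple[int, ...],
    active_offset_A: float = 0.0,
    seed: int = 0,
) -> tuple[ResidueCoordinates, list[int]]:
    """A persistent 3D CA trace with one active site near each planted site.

    The chain is a smooth persistent random walk: consecutive CA atoms are
    exactly 3.8 Å apart and the walk direction changes slowly, producing an
    extended curve on which sequence-distant residues are typically far
    apart in space.  For each planted site, one active-site residue is
    drawn among the residues whose CA lies within ``active_offset_A`` of it
    (the planted residue itself at offset 0).
    """
    if n < 3:
        raise ValueError("need at least 3 residues for a CA trace")
    if active_offset_A < 0:
        raise ValueError("active_offset_A must be ≥ 0")
    if not all(1 <= p <= n for p in planted_sites):
        raise ValueError(f"planted sites must lie in 1..{n}")
    rng = np.random.default_rng(seed)
    direction = rng.normal(0, 1, 3)
    direction /= np.linalg.norm(direction)
    coords = np.zeros((n, 3))
    for i in range(1, n):
        direction = direction + 0.15 * rng.normal(0, 1, 3)
        direction /= np.linalg.norm(direction)
        coords[i] = coords[i - 1] + CA_SPACING_A * direction
    mapping = {i + 1: coords[i] for i in range(n)}
    rc = ResidueCoordinates("synthetic", mapping)
    active = []
    for p in sorted(planted_sites):
        d = np.linalg.norm(coords - coords[p - 1], axis=1)
        candidates = np.flatnonzero(d <= active_offset_A + 1e-9) + 1
        active.append(int(rng.choice(candidates)))
    return rc, sorted(set(active))


def contact_map_from_structure(
    coords: ResidueCoordinates, midpoint_A: float = 8.0, steepness_A: float = 2.0
) -> ContactMap:
    """Soft contact probabilities from CA distances via a logistic falloff."""
    positions = coords.positions()
    xyz = np.vstack([coords.coords[p] for p in positions])
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    cm = 1.0 / (1.0 + np.exp((d - midpoint_A) / steepness_A))
    return ContactMap(coords.protein_id, cm)


def write_ground_truth(spec: SyntheticSpec, path: str | Path) -> None:
    """JSON sidecar recording the planted truth for test harnesses."""
    payload = {
        "planted_sites": [int(p) for p in spec.planted_sites],
        "conv_layer": int(spec.conv_layer),
        "seed": int(spec.seed),
        "n": spec.n,
        "L": spec.L,
        "H": spec.H,
        "concentration": spec.concentration,
        "noise_sigma": spec.noise_sigma,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def with_contact_final_layer(
    spec: SyntheticSpec, coords: ResidueCoordinates
) -> SyntheticSpec:
    """Copy of ``spec`` whose last layer mirrors the structure's contact map."""
    cm = contact_map_from_structure(coords)
    return replace(spec, contact_map=cm.values)
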