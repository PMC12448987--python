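"""Spatial evaluation of HA sites against annotated active sites, and
per-layer correlation between attention and the predicted contact map.

Proximity analysis uses alpha-carbon (CA) coordinates only: for each HA
site the Euclidean distance to the nearest annotated active-site CA is
computed, and the distribution of those distances is compared with a
seeded random-residue baseline by a Mann–Whitney U test.  The structural
analysis computes, per layer, the Spearman correlation between pooled
attention values in HA-site rows and the corresponding contact-map
entries; the layer of maximum correlation indicates where the network's
attention most resembles the predicted structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .attention_store import AttentionTensor, ContactMap
from .layer_profile import pool_heads

__all__ = [
    "ResidueCoordinates",
    "ProximityReport",
    "load_ca_coordinates",
    "nearest_active_distance",
    "random_site_baseline",
    "mann_whitney_u",
    "proximity_analysis",
    "attention_contact_spearman",
    "distance_fractions",
]

#: fixed report thresholds (Å) for the fraction of HA sites near an active site
REPORT_THRESHOLDS_A = (4.0, 8.0, 12.0)


@dataclass
class ResidueCoordinates:
    """CA coordinate per resolvable residue, keyed by 1-based position.

    Residue-numbering gaps in the structure are preserved: unresolved
    positions are simply absent from the mapping.
    """

    protein_id: str
    coords: dict[int, np.ndarray]

    def positions(self) -> list[int]:
        return sorted(self.coords)


@dataclass
class ProximityReport:
    protein_id: str
    per_site_distance: dict[int, float]  # HA position -> nearest active (Å)
    protein_min_distance: float
    random_baseline: list[float] = field(default_factory=list)
    mwu_statistic: float | None = None
    mwu_p: float | None = None


def load_ca_coordinates(
    path: str | Path,
    chain: str | None = None,
    expect_sequence: str | None = None,
) -> ResidueCoordinates:
    """Read CA coordinates from a PDB or mmCIF file.

    The first chain is used unless ``chain`` names one.  Alternate
    locations are resolved by highest occupancy (first encountered on
    ties).  If ``expect_sequence`` is given, the chain's one-letter
    sequence at the extracted positions must match it exactly; a mismatch
    aborts rather than risking a silently misaligned residue numbering.
    """
    import biotite.structure as struc

    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
        import biotite.structure.io.pdbx as pdbx

        cif = pdbx.CIFFile.read(str(path))
        atoms = pdbx.get_structure(cif, model=1, altloc="occupancy")
    else:
        import biotite.structure.io.pdb as pdb

        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no polymer atoms found")
    chain_id = chain if chain is not None else atoms.chain_id[0]
    ca = atoms[(atoms.chain_id == chain_id) & (atoms.atom_name == "CA")]
    if ca.array_length() == 0:
        raise ValueError(f"{path}: no CA atoms in chain {chain_id!r}")
    coords: dict[int, np.ndarray] = {}
    for i in range(ca.array_length()):
        pos = int(ca.res_id[i])
        if pos not in coords:  # first altloc kept (already occupancy-sorted)
            coords[pos] = np.asarray(ca.coord[i], dtype=np.float64)
    if expect_sequence is not None:
        from biotite.sequence import ProteinSequence

        observed = "".join(
            ProteinSequence.convert_letter_3to1(ca.res_name[i])
            for i in range(ca.array_length())
        )
        stated = "".join(
            expect_sequence[p - 1] for p in sorted(coords) if p <= len(expect_sequence)
        )
        if observed != stated:
            raise ValueError(
                f"{path}: chain {chain_id!r} residues do not match the stated "
                f"sequence at the numbered positions; refusing to align"
            )
    return ResidueCoordinates(str(path.stem), coords)


def _nearest(
    sites: list[int], targets: list[int], coords: ResidueCoordinates
) -> dict[int, float]:
    tpos = [p for p in targets if p in coords.coords]
    out: dict[int, float] = {}
    for s in sites:
        if s not in coords.coords:
            continue
        c = coords.coords[s]
        out[s] = min(float(np.linalg.norm(c - coords.coords[t])) for t in tpos)
    return out


def nearest_active_distance(
    ha_positions: list[int],
    active_positions: list[int],
    coords: ResidueCoordinates,
) -> ProximityReport:
    """Per-HA-site distance to the nearest active site, plus the protein
    minimum over all HA/active pairs.

    Positions lacking coordinates are dropped with a warning; if nothing
    remains on either side the analysis is impossible and raises.
    """
    ha_ok = [p for p in ha_positions if p in coords.coords]
    act_ok = [p for p in active_positions if p in coords.coords]
    dropped = (set(ha_positions) - set(ha_ok)) | (set(active_positions) - set(act_ok))
    if dropped:
        warnings.warn(
            f"{coords.protein_id}: no coordinates for positions "
            f"{sorted(dropped)}; dropped",
            stacklevel=2,
        )
    if not ha_ok or not act_ok:
        raise ValueError(
            f"{coords.protein_id}: no HA or active positions with coordinates"
        )
    per_site = _nearest(ha_ok, act_ok, coords)
    return ProximityReport(
        protein_id=coords.protein_id,
        per_site_distance=per_site,
        protein_min_distance=min(per_site.values()),
    )


def random_site_baseline(
    coords: ResidueCoordinates,
    active_positions: list[int],
    n_sites: int,
    seed: int,
) -> list[float]:
    """Nearest-active distances for ``n_sites`` random non-active residues.

    Residues are drawn uniformly without replacement from positions with
    coordinates, excluding the active sites themselves.  Callers typically
    set ``n_sites`` to the protein's HA-site count.
    """
    pool = [p for p in coords.positions() if p not in set(active_positions)]
    if len(pool) < n_sites:
        raise ValueError(
            f"{coords.protein_id}: only {len(pool)} non-active residues with "
            f"coordinates; cannot sample {n_sites}"
        )
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(pool, size=n_sites, replace=False))
    dists = _nearest([int(p) for p in chosen], active_positions, coords)
    return [dists[int(p)] for p in chosen]


def mann_whitney_u(a: list[float], b: list[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    The exact null distribution is used when the combined sample size is at
    most 20 and there are no ties; otherwise the tie-corrected normal
    approximation applies.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Mann–Whitney requires two non-empty samples")
    pooled = list(a) + list(b)
    exact = len(pooled) <= 20 and len(set(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def proximity_analysis(
    ha_positions: list[int],
    active_positions: list[int],
    coords: ResidueCoordinates,
    seed: int,
    n_random: int | None = None,
) -> ProximityReport:
    """Full per-protein proximity report including the random baseline MWU."""
    report = nearest_active_distance(ha_positions, active_positions, coords)
    n = n_random if n_random is not None else len(report.per_site_distance)
    report.random_baseline = random_site_baseline(
        coords, active_positions, n, seed
    )
    u, p = mann_whitney_u(
        list(report.per_site_distance.values()), report.random_baseline
    )
    report.mwu_statistic, report.mwu_p = u, p
    return report


def distance_fractions(
    distances: list[float], thresholds: tuple[float, ...] = REPORT_THRESHOLDS_A
) -> dict[float, float]:
    """Fraction of distances within each threshold (Å)."""
    d = np.asarray(distances, dtype=np.float64)
    return {t: float(np.mean(d <= t)) for t in thresholds}


def attention_contact_spearman(
    tensor: AttentionTensor,
    contacts: ContactMap,
    ha_positions: list[int],
) -> tuple[np.ndarray, int]:
    """Per-layer Spearman correlation between HA-row attention and contacts.

    For each layer, heads are mean-pooled and the pairs
    {(pooled[i, j], contact[i, j]) : i ∈ HA sites, j ≠ i} are rank
    correlated; diagonal pairs are excluded as degenerate.  Layers where
    either side is constant get NaN.  Returns the per-layer rho vector and
    the layer of maximum rho.
    """
    if tensor.n != contacts.n:
        raise ValueError("attention tensor and contact map disagree on n")
    if not ha_positions:
        raise ValueError("need at least one HA position")
    idx = np.asarray(ha_positions, dtype=int) - 1
    if idx.min() < 0 or idx.max() >= tensor.n:
        raise IndexError("HA position outside sequence")
    mask = np.ones((len(idx), tensor.n), dtype=bool)
    for r, i in enumerate(idx):
        mask[r, i] = False
    cvals = contacts.values[idx][mask]
    rhos = np.full(tensor.L, np.nan)
    for layer in range(tensor.L):
        avals = pool_heads(tensor, layer)[idx][mask]
        if np.ptp(avals) == 0 or np.ptp(cvals) == 0:
            continue
        rhos[layer] = stats.spearmanr(avals, cvals).statistic
    if np.all(np.isnan(rhos)):
        raise ValueError("Spearman undefined at every layer (constant inputs)")
    return rhos, int(np.nanargmax(rhos))


def write_proximity_tsv(reports: list[ProximityReport], path: str | Path) -> None:
    rows = []
    for r in reports:
        d = list(r.per_site_distance.values())
        frac = distance_fractions(d)
        rows.append(
            {
                "protein_id": r.protein_id,
                "n_ha": len(d),
                "min_distance_A": round(r.protein_min_distance, 3),
                "frac_within_4A": frac[4.0],
                "frac_within_8A": frac[8.0],
                "frac_within_12A": frac[12.0],
                "mwu_p": r.mwu_p,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
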