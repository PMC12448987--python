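"""Seeded end-to-end studies on synthetic data with planted ground truth.

Each study runs the full pipeline — generator → heatmap → convergence →
HA sites → evaluation — exactly as it would run on model-extracted
archives, and reports summary numbers against the planted truth:
planted-site recovery, family separability of the four distance measures,
HA/active-site spatial proximity, and the layer at which attention best
matches the contact map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .convergence import identify_ha_sites
from .family_eval import evaluate_families, silhouette
from .layer_profile import build_heatmap
from .similarity import distance_matrix, ha_trajectories, pooled_vector
from .structure_eval import (
    attention_contact_spearman,
    distance_fractions,
    mann_whitney_u,
    nearest_active_distance,
    random_site_baseline,
)
from .synthetic import (
    SyntheticSpec,
    contact_map_from_structure,
    make_attention_tensor,
    make_family,
    make_structure,
    with_contact_final_layer,
)

__all__ = [
    "RecoveryStudy",
    "FamilySeparationStudy",
    "ProximityStudy",
    "ContactCorrelationStudy",
    "recovery_study",
    "family_separation_study",
    "proximity_study",
    "contact_correlation_study",
]

MEASURES = ("ha", "cls", "mean", "max")


def _child_seeds(seed: int, count: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=count)]


@dataclass
class RecoveryStudy:
    jaccards: list[float]
    layer_errors: list[int]
    n_replicates: int

    @property
    def mean_jaccard(self) -> float:
        return float(np.mean(self.jaccards))

    @property
    def layer_within_one(self) -> float:
        return float(np.mean(np.abs(self.layer_errors) <= 1))


def recovery_study(n_replicates: int = 50, seed: int = 0) -> RecoveryStudy:
    """Planted-site recovery over seeded replicates of the default generator.

    Each replicate draws its own planted sites and convergence layer, builds
    the tensor, and compares the recovered HA set (Jaccard index) and
    convergence layer against the planted truth.
    """
    jaccards, layer_errors = [], []
    for s in _child_seeds(seed, n_replicates):
        rng = np.random.default_rng(s)
        sites = tuple(sorted(int(p) + 1 for p in rng.choice(120, 3, replace=False)))
        conv = int(rng.integers(8, 15))
        spec = SyntheticSpec(planted_sites=sites, conv_layer=conv, seed=s)
        res = identify_ha_sites(build_heatmap(make_attention_tensor(spec)))
        planted, got = set(sites), set(res.ha_sites)
        jaccards.append(len(planted & got) / len(planted | got))
        layer_errors.append(res.convergence_layer - conv)
    return RecoveryStudy(jaccards, layer_errors, n_replicates)


@dataclass
class FamilySeparationStudy:
    ks_means: dict[str, list[float]]  # per measure, one value per seed
    silhouettes: list[float]  # HA-measure global silhouette per seed

    def mean_ks(self, measure: str) -> float:
        return float(np.mean(self.ks_means[measure]))

    @property
    def mean_silhouette(self) -> float:
        return float(np.mean(self.silhouettes))


def family_separation_study(
    n_seeds: int = 20,
    seed: int = 0,
    n_families: int = 6,
    family_size: int = 6,
) -> FamilySeparationStudy:
    """In-family vs out-family KS for the HA distance and the three pooled
    baselines, plus the HA-measure global silhouette, on synthetic families."""
    ks_means: dict[str, list[float]] = {m: [] for m in MEASURES}
    silhouettes = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        reps: dict[str, dict] = {m: {} for m in MEASURES}
        families: dict[str, str] = {}
        for f in range(n_families):
            fam_id = f"F{f}"
            members = make_family(
                family_size, seed=int(rng.integers(0, 2**31 - 1)), family_id=fam_id
            )
            for record, tensor, emb in members:
                hm = build_heatmap(tensor)
                res = identify_ha_sites(hm)
                if res.ha_sites:
                    reps["ha"][record.protein_id] = ha_trajectories(hm, res.ha_sites)
                for m in ("cls", "mean", "max"):
                    reps[m][record.protein_id] = pooled_vector(emb, m)
                families[record.protein_id] = fam_id
        for m in MEASURES:
            reports, _ = evaluate_families(reps[m], families, m, seed=s)
            ks_means[m].append(float(np.mean([r.ks_statistic for r in reports])))
        ids = sorted(reps["ha"])
        D, _ = distance_matrix([reps["ha"][i] for i in ids], ids)
        _, sil, _ = silhouette([families[i] for i in ids], D)
        silhouettes.append(sil)
    return FamilySeparationStudy(ks_means, silhouettes)


@dataclass
class ProximityStudy:
    mwu_pvalues: list[float]  # one pooled test per seed
    ha_distances: list[float] = field(repr=False, default_factory=list)
    random_distances: list[float] = field(repr=False, default_factory=list)

    @property
    def max_p(self) -> float:
        return float(np.max(self.mwu_pvalues))

    def fractions(self, which: str = "ha") -> dict[float, float]:
        d = self.ha_distances if which == "ha" else self.random_distances
        return distance_fractions(d)


def proximity_study(
    n_seeds: int = 20,
    seed: int = 0,
    proteins_per_seed: int = 10,
    active_offset_A: float = 4.0,
) -> ProximityStudy:
    """HA-vs-active-site CA distances against a random-residue baseline.

    Active sites are planted within ``active_offset_A`` of the planted HA
    residues on an extended synthetic CA trace; per seed, distances are
    pooled over several proteins and compared by a Mann–Whitney U test.
    """
    pvals, ha_all, rand_all = [], [], []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        ha_d, rand_d = [], []
        for _ in range(proteins_per_seed):
            ps = int(rng.integers(0, 2**31 - 1))
            prng = np.random.default_rng(ps)
            sites = tuple(sorted(int(p) + 1 for p in prng.choice(120, 3, replace=False)))
            coords, active = make_structure(120, sites, active_offset_A, seed=ps)
            rep = nearest_active_distance(list(sites), active, coords)
            ha_d.extend(rep.per_site_distance.values())
            rand_d.extend(random_site_baseline(coords, active, len(sites), ps + 1))
        _, p = mann_whitney_u(ha_d, rand_d)
        pvals.append(p)
        ha_all.extend(ha_d)
        rand_all.extend(rand_d)
    return ProximityStudy(pvals, ha_all, rand_all)


@dataclass
class ContactCorrelationStudy:
    argmax_layers: list[int]
    last_layer: int

    @property
    def frac_argmax_last(self) -> float:
        return float(np.mean(np.asarray(self.argmax_layers) == self.last_layer))


def contact_correlation_study(
    n_proteins: int = 10, seed: int = 0
) -> ContactCorrelationStudy:
    """Layer of maximum attention/contact Spearman correlation when the
    final synthetic layer is built from the structure's contact map."""
    argmax_layers = []
    spec0 = SyntheticSpec()
    for s in _child_seeds(seed, n_proteins):
        rng = np.random.default_rng(s)
        sites = tuple(sorted(int(p) + 1 for p in rng.choice(120, 3, replace=False)))
        spec = SyntheticSpec(planted_sites=sites, seed=s)
        coords, _ = make_structure(spec.n, sites, seed=s)
        tensor = make_attention_tensor(with_contact_final_layer(spec, coords))
        cm = contact_map_from_structure(coords)
        res = identify_ha_sites(build_heatmap(tensor))
        positions = res.ha_sites if res.ha_sites else list(sites)
        _, best = attention_contact_spearman(tensor, cm, positions)
        argmax_layers.append(best)
    return ContactCorrelationStudy(argmax_layers, spec0.L - 1)
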