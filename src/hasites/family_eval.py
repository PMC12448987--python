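"""Family-separability evaluation of a protein distance measure.

For each family, the distribution of distances within the family is
compared to distances between family members and randomly drawn outside
proteins using a two-sample Kolmogorov–Smirnov test; a silhouette analysis
over a full pairwise distance matrix quantifies how tightly families
cluster under each measure.  The same machinery accepts the HA-trajectory
distance and the pooled-embedding baselines (CLS / mean / max), so the four
measures can be ranked on identical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .similarity import HATrajectorySet, cosine_distance, protein_distance

__all__ = [
    "FamilyEvalReport",
    "in_family_distances",
    "out_family_distances",
    "ks_two_sample",
    "silhouette",
    "evaluate_families",
    "summarize_reports",
]

Representation = "HATrajectorySet | np.ndarray"


@dataclass
class FamilyEvalReport:
    family_id: str
    measure: str
    ks_statistic: float
    p_value: float
    n_in_pairs: int
    n_out_pairs: int
    seed: int


def _dist(a, b) -> float:
    if isinstance(a, HATrajectorySet):
        return protein_distance(a, b)
    return cosine_distance(a, b)


def in_family_distances(members: list) -> list[float]:
    """Distances over all unordered pairs of family members."""
    if len(members) < 2:
        raise ValueError("need at least 2 usable family members")
    return [_dist(a, b) for a, b in combinations(members, 2)]


def out_family_distances(
    members: list,
    background: list,
    count: int,
    seed: int,
) -> list[float]:
    """Seeded sample of member-vs-background distances.

    Each of ``count`` pairs joins a uniformly drawn family member with a
    uniformly drawn background (non-member) protein.  By default callers
    use ``count`` equal to the in-family pair count for a balanced test.
    """
    if not background:
        raise ValueError("background pool is empty")
    rng = np.random.default_rng(seed)
    mi = rng.integers(0, len(members), size=count)
    bi = rng.integers(0, len(background), size=count)
    return [_dist(members[i], background[j]) for i, j in zip(mi, bi)]


def ks_two_sample(a: list[float], b: list[float]) -> tuple[float, float]:
    """Two-sample KS statistic (sup ECDF difference) with asymptotic p-value."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS test requires two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def silhouette(
    labels: list[str], distances: np.ndarray
) -> tuple[np.ndarray, float, list[int]]:
    """Silhouette scores from a precomputed distance matrix.

    For protein i with intra-family mean distance a(i) (self excluded) and
    b(i) the smallest mean distance to any other family, the score is
    (b−a)/max(a,b).  Proteins in singleton families score 0 and their
    indices are returned as flagged.  Returns (per-protein scores, global
    mean, flagged singleton indices).
    """
    D = np.asarray(distances, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix is asymmetric beyond 1e-9")
    labels = np.asarray(labels)
    if labels.size != D.shape[0]:
        raise ValueError("one label per matrix row required")
    fams = np.unique(labels)
    sizes = {f: int(np.sum(labels == f)) for f in fams}
    if len(fams) < 2:
        raise ValueError("silhouette needs at least 2 families")
    if all(sizes[f] < 2 for f in fams):
        raise ValueError("silhouette needs at least one family with ≥ 2 members")
    scores = np.zeros(labels.size)
    singletons: list[int] = []
    for i in range(labels.size):
        own = labels == labels[i]
        if sizes[labels[i]] < 2:
            singletons.append(i)
            continue
        a_i = D[i, own].sum() / (sizes[labels[i]] - 1)
        b_i = min(D[i, labels == f].mean() for f in fams if f != labels[i])
        scores[i] = (b_i - a_i) / max(a_i, b_i) if max(a_i, b_i) > 0 else 0.0
    return scores, float(scores.mean()), singletons


def evaluate_families(
    representations: dict[str, object],
    families: dict[str, str],
    measure: str,
    seed: int,
    out_count: int | None = None,
) -> tuple[list[FamilyEvalReport], list[str]]:
    """KS report per family for one distance measure.

    ``representations`` maps protein_id to either an
    :class:`~hasites.similarity.HATrajectorySet` or a pooled vector;
    proteins absent from the mapping (e.g. no HA sites) are excluded.
    Families with fewer than two usable members are skipped and listed.
    Per-family seeds are derived from ``seed`` so runs are reproducible.
    """
    by_family: dict[str, list] = {}
    for pid, rep in representations.items():
        fam = families.get(pid)
        if fam is not None:
            by_family.setdefault(fam, []).append((pid, rep))
    reports: list[FamilyEvalReport] = []
    skipped: list[str] = []
    for idx, fam in enumerate(sorted(by_family)):
        members = [rep for _, rep in by_family[fam]]
        if len(members) < 2:
            skipped.append(fam)
            continue
        member_ids = {pid for pid, _ in by_family[fam]}
        background = [
            rep for pid, rep in representations.items() if pid not in member_ids
        ]
        if not background:
            skipped.append(fam)
            continue
        fam_seed = (seed + 1000003 * idx) % (2**31)
        dins = in_family_distances(members)
        count = out_count if out_count is not None else len(dins)
        douts = out_family_distances(members, background, count, fam_seed)
        ks, p = ks_two_sample(dins, douts)
        reports.append(
            FamilyEvalReport(fam, measure, ks, p, len(dins), len(douts), fam_seed)
        )
    return reports, skipped


def summarize_reports(
    reports: list[FamilyEvalReport], alpha: float = 0.05
) -> dict[str, float]:
    """Across-family summary: min/max/mean/median KS, percentile range, and
    the number of families significant at ``alpha``.

    The reported interval is the 2.5–97.5 percentile range of the KS
    statistic across families.
    """
    ks = np.array([r.ks_statistic for r in reports])
    return {
        "n_families": len(reports),
        "min": float(ks.min()),
        "max": float(ks.max()),
        "mean": float(ks.mean()),
        "median": float(np.median(ks)),
        "pct_2.5": float(np.percentile(ks, 2.5)),
        "pct_97.5": float(np.percentile(ks, 97.5)),
        "n_significant": int(sum(r.p_value < alpha for r in reports)),
        "alpha": alpha,
    }


def write_reports_tsv(reports: list[FamilyEvalReport], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in reports]).to_csv(path, sep="\t", index=False)
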