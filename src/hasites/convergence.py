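"""Convergence-layer detection and high-attention (HA) site extraction.

The normalized attention profile of a layer, sorted in descending order,
typically shows a steep initial decay over a handful of residues followed
by a long shallow tail.  We fit two independent least-squares lines over
every admissible breakpoint of the sorted curve and keep the split with the
smallest total squared error.  The angle θ between the two fitted lines
(computed from their slopes after rescaling the rank axis to [0, 1], so
that θ is comparable across proteins of different lengths) measures how
sharply high-attention residues separate from the rest: θ near 90° means a
near-vertical drop onto a flat tail.  The layer whose θ is closest to 90°
is the *convergence layer*, and the residues left of the intersection of
its two fit lines are the HA sites.

Fitting the two segments independently — rather than forcing continuity at
the breakpoint — keeps each side an ordinary least-squares problem and lets
the intersection point of the two lines, not the breakpoint rank itself,
define the high/low attention cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layer_profile import AttentionHeatmap

__all__ = [
    "PiecewiseFit",
    "ConvergenceResult",
    "fit_two_segments",
    "segment_angle",
    "find_convergence_layer",
    "extract_ha_sites",
    "identify_ha_sites",
    "write_ha_tsv",
]

#: slope difference below which the two fit lines are treated as parallel
_PARALLEL_TOL = 1e-12


@dataclass
class PiecewiseFit:
    """Two independent least-squares segments over a sorted profile.

    ``k`` is the rank of the first point of the right segment (the
    breakpoint), with admissible range 2 ≤ k ≤ n−2 so each side has at
    least two points.  Slopes and intercepts are in rescaled coordinates
    where rank r maps to x = r/(n−1) ∈ [0, 1].
    """

    k: int
    left_slope: float
    left_intercept: float
    right_slope: float
    right_intercept: float
    sse_total: float
    theta_deg: float
    intersection_x: float | None


@dataclass
class ConvergenceResult:
    """Per-layer fits plus the chosen convergence layer and its HA sites."""

    protein_id: str
    per_layer_fits: list[PiecewiseFit]
    convergence_layer: int
    ha_sites: list[int] = field(default_factory=list)  # 1-based positions
    ha_attention_values: list[float] = field(default_factory=list)

    @property
    def theta_deg(self) -> float:
        return self.per_layer_fits[self.convergence_layer].theta_deg


def _segment_stats(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Prefix sums needed for closed-form OLS over every contiguous range."""
    z = np.zeros(1)
    csum = lambda a: np.concatenate([z, np.cumsum(a)])
    return csum(x), csum(y), csum(x * x), csum(x * y), csum(y * y)


def _ols_ranges(sums, lo: np.ndarray, hi: np.ndarray):
    """Closed-form OLS (slope, intercept, SSE) for ranges [lo, hi)."""
    Sx, Sy, Sxx, Sxy, Syy = sums
    m = (hi - lo).astype(np.float64)
    sx = Sx[hi] - Sx[lo]
    sy = Sy[hi] - Sy[lo]
    cxx = (Sxx[hi] - Sxx[lo]) - sx * sx / m
    cxy = (Sxy[hi] - Sxy[lo]) - sx * sy / m
    cyy = (Syy[hi] - Syy[lo]) - sy * sy / m
    slope = cxy / cxx
    intercept = (sy - slope * sx) / m
    sse = np.maximum(cyy - cxy * cxy / cxx, 0.0)
    return slope, intercept, sse


def fit_two_segments(values: np.ndarray) -> PiecewiseFit:
    """Fit two least-squares lines to a descending profile over all breakpoints.

    ``values`` must be sorted non-increasing with n ≥ 4.  The breakpoint k
    minimizing the total sum of squared errors is returned, ties broken
    toward the smallest k.  (Minimizing total SSE and total mean-squared
    error pick the same k.)
    """
    y = np.asarray(values, dtype=np.float64)
    n = y.size
    if n < 4:
        raise ValueError(f"need at least 4 points to fit two segments; got {n}")
    if np.any(np.diff(y) > 1e-12):
        raise ValueError("values must be sorted in non-increasing order")
    x = np.arange(n, dtype=np.float64) / (n - 1)
    sums = _segment_stats(x, y)
    ks = np.arange(2, n - 1)
    ls, li, lsse = _ols_ranges(sums, np.zeros_like(ks), ks)
    rs, ri, rsse = _ols_ranges(sums, ks, np.full_like(ks, n))
    total = lsse + rsse
    # ties (within float noise) break toward the smallest k
    best = int(np.flatnonzero(total <= total.min() + 1e-12)[0])
    k = int(ks[best])
    fit = PiecewiseFit(
        k=k,
        left_slope=float(ls[best]),
        left_intercept=float(li[best]),
        right_slope=float(rs[best]),
        right_intercept=float(ri[best]),
        sse_total=float(total[best]),
        theta_deg=0.0,
        intersection_x=None,
    )
    fit.theta_deg = segment_angle(fit)
    if abs(fit.left_slope - fit.right_slope) > _PARALLEL_TOL:
        fit.intersection_x = (fit.left_intercept - fit.right_intercept) / (
            fit.right_slope - fit.left_slope
        )
    return fit


def segment_angle(fit: PiecewiseFit) -> float:
    """Angle between the two fit lines, folded into [0, 90] degrees.

    θ = min(a, 180−a) with a = |atan(m_left) − atan(m_right)| in degrees,
    slopes taken in the rescaled [0, 1] coordinates.
    """
    a = abs(np.degrees(np.arctan(fit.left_slope) - np.arctan(fit.right_slope)))
    return float(min(a, 180.0 - a))


def _sort_profile(row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort a profile descending; ties keep ascending original residue order."""
    order = np.argsort(-row, kind="stable")
    return row[order], order


def find_convergence_layer(heatmap: AttentionHeatmap) -> ConvergenceResult:
    """Fit every layer's sorted profile and pick the layer with θ closest to 90°.

    Ties in |θ − 90| are broken toward the lowest layer index: the method
    looks for the *earliest* layer at which attention has converged.
    HA sites are not filled in; see :func:`identify_ha_sites`.
    """
    fits = []
    for row in heatmap.matrix:
        sorted_vals, _ = _sort_profile(row)
        fits.append(fit_two_segments(sorted_vals))
    gaps = [abs(f.theta_deg - 90.0) for f in fits]
    conv = int(np.argmin(gaps))  # argmin takes the lowest layer on ties
    return ConvergenceResult(heatmap.protein_id, fits, conv)


def extract_ha_sites(
    sorted_values: np.ndarray, order: np.ndarray, fit: PiecewiseFit
) -> list[int]:
    """Map the left-of-intersection ranks of a fit back to residue positions.

    Ranks r < k whose rescaled coordinate x_r lies left of the fit lines'
    intersection are HA sites.  If the lines are parallel, or intersect at
    or beyond x_k, the whole left segment qualifies; an intersection at or
    left of x_0 = 0 yields an empty set (a legal outcome: some proteins
    have no HA site).  Returns ascending 1-based positions.
    """
    n = sorted_values.size
    x = np.arange(n, dtype=np.float64) / (n - 1)
    if fit.intersection_x is None or fit.intersection_x >= x[fit.k]:
        ranks = np.arange(fit.k)
    elif fit.intersection_x <= 0.0:
        ranks = np.arange(0)
    else:
        left = np.arange(fit.k)
        ranks = left[x[left] < fit.intersection_x]
    return sorted(int(order[r]) + 1 for r in ranks)


def identify_ha_sites(heatmap: AttentionHeatmap) -> ConvergenceResult:
    """Full pipeline: convergence layer plus HA sites from its fit."""
    result = find_convergence_layer(heatmap)
    row = heatmap.matrix[result.convergence_layer]
    sorted_vals, order = _sort_profile(row)
    fit = result.per_layer_fits[result.convergence_layer]
    result.ha_sites = extract_ha_sites(sorted_vals, order, fit)
    result.ha_attention_values = [float(row[p - 1]) for p in result.ha_sites]
    return result


def write_ha_tsv(
    results: list[ConvergenceResult],
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write one combined TSV of HA sites (one row per site, 1-based)."""
    rows = []
    for res in results:
        if not res.ha_sites:
            rows.append(
                {
                    "protein_id": res.protein_id,
                    "convergence_layer": res.convergence_layer,
                    "theta_deg": round(res.theta_deg, 4),
                    "position": pd.NA,
                    "residue": pd.NA,
                    "normalized_attention": pd.NA,
                }
            )
        for pos, val in zip(res.ha_sites, res.ha_attention_values):
            seq = sequences.get(res.protein_id, "") if sequences else ""
            rows.append(
                {
                    "protein_id": res.protein_id,
                    "convergence_layer": res.convergence_layer,
                    "theta_deg": round(res.theta_deg, 4),
                    "position": pos,
                    "residue": seq[pos - 1] if seq else pd.NA,
                    "normalized_attention": round(val, 6),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
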