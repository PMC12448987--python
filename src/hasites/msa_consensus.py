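"""Mapping HA sites into a multiple sequence alignment and scoring
per-column residue consensus.

Alignments are consumed, never computed: any aligned-FASTA or Clustal file
(e.g. produced by Clustal Omega) is accepted.  Consensus of a column is the
percentage of alignment rows carrying the modal non-gap residue, with the
denominator counting *all* rows — gap rows can never be the consensus
residue, so columns present in few sequences score low.  The report
compares consensus at HA-site columns with the mean consensus over all
columns, and heatmaps can be re-laid onto alignment coordinates with gaps
marked absent (never numeric zero).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .layer_profile import AttentionHeatmap

__all__ = [
    "FamilyAlignment",
    "ConsensusReport",
    "read_alignment",
    "position_to_column",
    "column_consensus",
    "ha_consensus_report",
    "aligned_heatmap",
]

GAP = "-"


@dataclass
class FamilyAlignment:
    """Aligned rows of one family, keyed by protein id."""

    family_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.family_id}: aligned rows have unequal lengths {sorted(lengths)}"
            )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column(self, col: int) -> str:
        """Characters of 1-based column ``col`` in row order."""
        return "".join(r[col - 1] for r in self.rows.values())


@dataclass
class ConsensusReport:
    family_id: str
    per_column: np.ndarray  # consensus % per alignment column
    ha_rows: pd.DataFrame  # protein_id, position, column, consensus_pct
    alignment_mean: float  # mean consensus % over columns
    missing_proteins: list[str]


def read_alignment(path: str | Path, family_id: str = "") -> FamilyAlignment:
    """Read an aligned-FASTA or Clustal file (format sniffed from content)."""
    path = Path(path)
    fmt = "fasta"
    with open(path) as fh:
        first = fh.readline()
    if first.upper().startswith("CLUSTAL"):
        fmt = "clustal"
    aln = AlignIO.read(str(path), fmt)
    rows = {}
    for rec in aln:
        ident = rec.id
        if "|" in ident:
            parts = ident.split("|")
            if len(parts) >= 2 and parts[1]:
                ident = parts[1]
        rows[ident] = str(rec.seq).upper()
    return FamilyAlignment(family_id or path.stem, rows)


def position_to_column(aligned_row: str, position: int) -> int:
    """1-based alignment column holding the ``position``-th non-gap character."""
    if position < 1:
        raise IndexError(f"position {position} must be ≥ 1")
    count = 0
    for col, ch in enumerate(aligned_row, start=1):
        if ch != GAP:
            count += 1
            if count == position:
                return col
    raise IndexError(
        f"position {position} beyond degapped length {count} of aligned row"
    )


def column_consensus(column: str) -> float:
    """Percent of rows sharing the modal non-gap residue (0 for all-gap)."""
    if not column:
        raise ValueError("empty alignment column")
    counts = Counter(ch for ch in column if ch != GAP)
    if not counts:
        return 0.0
    return 100.0 * max(counts.values()) / len(column)


def ha_consensus_report(
    alignment: FamilyAlignment, ha_sites: dict[str, list[int]]
) -> ConsensusReport:
    """Consensus at every HA site's column vs the alignment-wide column mean.

    Proteins with HA sites but absent from the alignment are listed in
    ``missing_proteins`` and skipped.
    """
    per_column = np.array(
        [column_consensus(alignment.column(c)) for c in range(1, alignment.n_columns + 1)]
    )
    rows = []
    missing = []
    for pid, positions in sorted(ha_sites.items()):
        if pid not in alignment.rows:
            missing.append(pid)
            continue
        for pos in positions:
            col = position_to_column(alignment.rows[pid], pos)
            rows.append(
                {
                    "protein_id": pid,
                    "position": pos,
                    "column": col,
                    "consensus_pct": float(per_column[col - 1]),
                }
            )
    return ConsensusReport(
        family_id=alignment.family_id,
        per_column=per_column,
        ha_rows=pd.DataFrame(
            rows, columns=["protein_id", "position", "column", "consensus_pct"]
        ),
        alignment_mean=float(per_column.mean()) if per_column.size else 0.0,
        missing_proteins=missing,
    )


def consensus_histogram(
    report: ConsensusReport, bin_width: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of HA sites per consensus bin (default 10-point bins)."""
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(report.ha_rows["consensus_pct"], bins=edges)
    total = max(len(report.ha_rows), 1)
    return counts / total, edges


def aligned_heatmap(heatmap: AttentionHeatmap, aligned_row: str) -> np.ndarray:
    """Lay an L × n heatmap onto alignment columns; gaps become NaN.

    The degapped row must have exactly the heatmap's n residues.  NaN marks
    absence — exports must render it as an explicit NA token, never 0.
    """
    degapped = aligned_row.replace(GAP, "")
    if len(degapped) != heatmap.n:
        raise ValueError(
            f"aligned row has {len(degapped)} residues but heatmap has {heatmap.n}"
        )
    out = np.full((heatmap.L, len(aligned_row)), np.nan)
    residue_cols = [c for c, ch in enumerate(aligned_row) if ch != GAP]
    out[:, residue_cols] = heatmap.matrix
    return out


def write_aligned_heatmap_tsv(matrix: np.ndarray, path: str | Path) -> None:
    """TSV export with 'NA' at gap columns."""
    df = pd.DataFrame(
        matrix,
        index=pd.Index(range(matrix.shape[0]), name="layer"),
        columns=[str(c) for c in range(1, matrix.shape[1] + 1)],
    )
    df.to_csv(path, sep="\t", na_rep="NA")
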