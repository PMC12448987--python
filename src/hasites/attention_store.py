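"""Domain containers for per-protein attention data and a portable HDF5 archive.

A protein language model emits, for a sequence of ``n`` residues, one
attention matrix per layer and head (``L × H × n × n``), a per-residue
embedding matrix (``n × d``), and a predicted residue-residue contact map
(``n × n``).  The containers here hold those arrays after special tokens
have been stripped, validate the invariants that make downstream analysis
meaningful (non-negativity, row-stochastic attention rows), and round-trip
through a single HDF5 file so that every other module can run without a
model in the loop.

Archive layout::

    /attention   (L, H, n, n)  float32
    /embeddings  (n, d)        float32   [optional]
    /cls         (d,)          float32   [optional]
    /contacts    (n, n)        float32   [optional]
    /heatmap     (L, n)        float32   [optional, written by layer_profile]
    attrs: protein_id, sequence, family_id, model, model_meta (JSON)

Arrays are stored in 32-bit floats; all in-memory computation uses 64-bit.
Residue axes are 0-based internally; user-facing reports are 1-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AttentionTensor",
    "EmbeddingMatrix",
    "ContactMap",
    "ProteinRecord",
    "ArchiveError",
    "InvariantWarning",
    "write_archive",
    "read_archive",
    "read_fasta",
    "read_family_table",
]

#: 20 standard amino acids plus X for unknown residues.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

ROW_SUM_TOL = 1e-4


class ArchiveError(Exception):
    """Raised when an archive is missing, truncated, or inconsistent."""


class InvariantWarning(UserWarning):
    """Emitted when stored data violates a soft invariant (e.g. row sums)."""


@dataclass
class AttentionTensor:
    """Raw multi-head attention for one protein, special tokens removed.

    ``values`` has shape ``(L, H, n, n)`` indexed as
    (layer, head, query residue, key residue).  Each query row of each head
    is a softmax distribution over key positions and therefore sums to 1,
    unless ``model_meta['renormalized']`` records that rows were rescaled
    after special-token stripping (in which case they still sum to 1, just
    not to the model's original softmax output).
    """

    protein_id: str
    values: np.ndarray
    model_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError(
                f"attention values must be 4-dimensional (L, H, n, n); "
                f"got shape {self.values.shape}"
            )
        if self.values.shape[2] != self.values.shape[3]:
            raise ValueError(
                f"query/key axes must be square; got shape {self.values.shape}"
            )

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def H(self) -> int:
        return self.values.shape[1]

    @property
    def n(self) -> int:
        return self.values.shape[2]

    def validate(self, strict: bool = False) -> list[str]:
        """Check non-negativity and row-stochasticity.

        Returns a list of human-readable violation messages.  With
        ``strict=True`` violations raise ``ValueError`` instead.  Row-sum
        deviations are tolerated silently when the tensor is flagged as
        renormalized in ``model_meta``.
        """
        problems: list[str] = []
        neg = np.argwhere(self.values < 0)
        if neg.size:
            l, h, i, j = neg[0]
            problems.append(
                f"negative attention value at layer {l}, head {h}, "
                f"row {i}, column {j} ({neg.shape[0]} total)"
            )
        row_sums = self.values.sum(axis=3)
        bad = np.argwhere(np.abs(row_sums - 1.0) > ROW_SUM_TOL)
        if bad.size and not self.model_meta.get("renormalized", False):
            l, h, i = bad[0]
            problems.append(
                f"attention rows do not sum to 1 (first at layer {l}, "
                f"head {h}, row {i}: sum={row_sums[l, h, i]:.6f}; "
                f"{bad.shape[0]} rows total)"
            )
        if strict and problems:
            raise ValueError("; ".join(problems))
        return problems


@dataclass
class EmbeddingMatrix:
    """Per-residue embedding vectors plus the begin-token (CLS) embedding."""

    protein_id: str
    vectors: np.ndarray
    cls_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[1] < 1:
            raise ValueError("embedding matrix must be n × d with d > 0")
        if self.cls_vector is not None:
            self.cls_vector = np.asarray(self.cls_vector, dtype=np.float64)
            if self.cls_vector.shape != (self.vectors.shape[1],):
                raise ValueError(
                    "cls_vector length must equal the embedding dimension"
                )

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ContactMap:
    """Predicted contact probabilities, symmetric with entries in [0, 1]."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact map must be a square n × n matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, strict: bool = False) -> list[str]:
        problems: list[str] = []
        if not np.allclose(self.values, self.values.T, atol=1e-6):
            problems.append("contact map is not symmetric within 1e-6")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            problems.append("contact map entries outside [0, 1]")
        if strict and problems:
            raise ValueError("; ".join(problems))
        return problems


@dataclass
class ProteinRecord:
    """A protein sequence with optional family assignment."""

    protein_id: str
    sequence: str
    family_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.protein_id}: non-standard residue letters {sorted(bad)}"
            )

    @property
    def n(self) -> int:
        return len(self.sequence)


def _check_shared_n(
    tensor: AttentionTensor,
    embeddings: EmbeddingMatrix | None,
    contacts: ContactMap | None,
    sequence: str | None,
) -> None:
    n = tensor.n
    if embeddings is not None and embeddings.n != n:
        raise ArchiveError(
            f"/embeddings has {embeddings.n} residues but /attention has {n}"
        )
    if contacts is not None and contacts.n != n:
        raise ArchiveError(
            f"/contacts is {contacts.n}×{contacts.n} but /attention has n={n}"
        )
    if sequence and len(sequence) != n:
        raise ArchiveError(
            f"sequence length {len(sequence)} does not match attention n={n}"
        )


def write_archive(
    path: str | Path,
    tensor: AttentionTensor,
    embeddings: EmbeddingMatrix | None = None,
    contacts: ContactMap | None = None,
    sequence: str = "",
    family_id: str | None = None,
    heatmap: np.ndarray | None = None,
) -> None:
    """Write one protein's arrays to a single HDF5 archive.

    Components must agree on ``protein_id`` and residue count ``n``;
    mismatches raise :class:`ArchiveError` naming the offending dataset.
    """
    for comp in (embeddings, contacts):
        if comp is not None and comp.protein_id != tensor.protein_id:
            raise ArchiveError(
                f"protein_id mismatch: attention is '{tensor.protein_id}' "
                f"but a component is '{comp.protein_id}'"
            )
    _check_shared_n(tensor, embeddings, contacts, sequence)
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "attention", data=tensor.values.astype(np.float32), track_times=False
        )
        if embeddings is not None:
            f.create_dataset(
                "embeddings",
                data=embeddings.vectors.astype(np.float32),
                track_times=False,
            )
            if embeddings.cls_vector is not None:
                f.create_dataset(
                    "cls",
                    data=embeddings.cls_vector.astype(np.float32),
                    track_times=False,
                )
        if contacts is not None:
            f.create_dataset(
                "contacts", data=contacts.values.astype(np.float32), track_times=False
            )
        if heatmap is not None:
            f.create_dataset(
                "heatmap", data=np.asarray(heatmap, dtype=np.float32), track_times=False
            )
        f.attrs["protein_id"] = tensor.protein_id
        f.attrs["sequence"] = sequence
        f.attrs["family_id"] = family_id if family_id is not None else ""
        f.attrs["model"] = str(tensor.model_meta.get("model", "unknown"))
        f.attrs["model_meta"] = json.dumps(tensor.model_meta)


def read_archive(
    path: str | Path,
) -> tuple[AttentionTensor, EmbeddingMatrix | None, ContactMap | None, ProteinRecord | None]:
    """Read an archive back into domain containers.

    Invariant violations in the stored data (negative values, rows that do
    not sum to 1 without a renormalization flag) raise
    :class:`InvariantWarning` as warnings, never silently pass.  A missing
    or unreadable ``/attention`` dataset is unrecoverable and raises
    :class:`ArchiveError`.
    """
    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as exc:
        raise ArchiveError(f"cannot open archive {path}: {exc}") from exc
    with f:
        if "attention" not in f:
            raise ArchiveError(f"{path}: missing required /attention dataset")
        protein_id = str(f.attrs.get("protein_id", ""))
        sequence = str(f.attrs.get("sequence", ""))
        family_id = str(f.attrs.get("family_id", "")) or None
        try:
            model_meta = json.loads(f.attrs.get("model_meta", "{}"))
        except json.JSONDecodeError:
            model_meta = {}
        tensor = AttentionTensor(
            protein_id=protein_id,
            values=f["attention"][()],
            model_meta=model_meta,
        )
        embeddings = None
        if "embeddings" in f:
            cls = f["cls"][()] if "cls" in f else None
            embeddings = EmbeddingMatrix(protein_id, f["embeddings"][()], cls)
        contacts = ContactMap(protein_id, f["contacts"][()]) if "contacts" in f else None
    for msg in tensor.validate():
        warnings.warn(f"{path}: {msg}", InvariantWarning, stacklevel=2)
    if contacts is not None:
        for msg in contacts.validate():
            warnings.warn(f"{path}: {msg}", InvariantWarning, stacklevel=2)
    _check_shared_n(tensor, embeddings, contacts, sequence)
    record = ProteinRecord(protein_id, sequence, family_id) if sequence else None
    return tensor, embeddings, contacts, record


def read_heatmap(path: str | Path) -> np.ndarray | None:
    """Return the stored ``/heatmap`` dataset, or None if absent."""
    with h5py.File(path, "r") as f:
        if "heatmap" not in f:
            return None
        return f["heatmap"][()].astype(np.float64)


def read_fasta(path: str | Path) -> Iterator[ProteinRecord]:
    """Yield :class:`ProteinRecord` objects from a FASTA file.

    UniProt-style headers (``db|ACCESSION|NAME``) are reduced to the
    accession; other headers are used verbatim up to the first whitespace.
    """
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if "|" in ident:
            parts = ident.split("|")
            if len(parts) >= 2 and parts[1]:
                ident = parts[1]
        yield ProteinRecord(ident, str(rec.seq).upper())


def read_family_table(path: str | Path) -> dict[str, str]:
    """Read a protein→family TSV with columns ``protein_id`` and ``family_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"protein_id", "family_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: family table missing columns {sorted(missing)}")
    return dict(zip(df["protein_id"], df["family_id"]))
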