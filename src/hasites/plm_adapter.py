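"""Optional extraction of attention, embeddings, and contact maps from an
ESM-2 checkpoint into the standard archive format.

The heavy dependencies (torch, fair-esm) are an install extra; the rest of
the package runs entirely on archives or synthetic data.  Extraction strips
the begin/end special tokens so all arrays are n × n aligned to the residue
sequence, renormalizes the remaining attention rows to sum to 1, and
records that choice in the archive's model metadata.  The head count is
taken from the loaded model, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .attention_store import (
    AttentionTensor,
    ContactMap,
    EmbeddingMatrix,
    ProteinRecord,
    write_archive,
)

__all__ = ["ExtractionConfig", "strip_special_tokens", "extract", "extract_to_archive"]

DEFAULT_MODEL = "esm2_t33_650M_UR50D"


@dataclass
class ExtractionConfig:
    """Extraction policy: model, device, and a hard length cutoff.

    Sequences longer than ``max_length`` are refused with an error; there
    is no silent truncation, since a truncated attention matrix would be
    silently misaligned with the full sequence.
    """

    model_name: str = DEFAULT_MODEL
    device: str = "cpu"
    max_length: int = 1022
    renormalize: bool = True


def strip_special_tokens(
    attention: np.ndarray,
    n_begin: int = 1,
    n_end: int = 1,
    renormalize: bool = True,
) -> np.ndarray:
    """Drop special-token rows/columns from an (L, H, T, T) attention stack.

    The per-layer analysis is defined over sequence residues only, so the
    begin/end token rows and columns are removed; with ``renormalize`` each
    remaining query row is rescaled to sum to 1 (the mass it lost went to
    tokens that no longer exist).
    """
    a = np.asarray(attention, dtype=np.float64)
    if a.ndim != 4 or a.shape[2] != a.shape[3]:
        raise ValueError(f"expected (L, H, T, T) attention; got {a.shape}")
    stop = a.shape[2] - n_end if n_end else a.shape[2]
    a = a[:, :, n_begin:stop, n_begin:stop]
    if renormalize:
        sums = a.sum(axis=3, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("a query row lost all mass after token stripping")
        a = a / sums
    return a


def extract(
    record: ProteinRecord, config: ExtractionConfig | None = None
) -> tuple[AttentionTensor, EmbeddingMatrix, ContactMap]:
    """Run the model on one sequence and return archive-ready components.

    Requires the ``esm`` install extra.  The begin-token embedding is kept
    as the CLS vector; per-residue embeddings come from the final layer.
    """
    config = config or ExtractionConfig()
    if len(record.sequence) > config.max_length:
        raise ValueError(
            f"{record.protein_id}: sequence length {len(record.sequence)} exceeds "
            f"the {config.max_length}-residue policy; refusing to truncate"
        )
    try:
        import esm  # type: ignore
        import torch  # type: ignore
    except ImportError as exc:  # pragma: no cover - needs the esm extra
        raise ImportError(
            "model extraction requires torch and fair-esm; "
            "install with: pip install 'hasites[esm]'"
        ) from exc

    model, alphabet = esm.pretrained.load_model_and_alphabet(config.model_name)
    model = model.eval().to(config.device)
    converter = alphabet.get_batch_converter()
    _, _, tokens = converter([(record.protein_id, record.sequence)])
    tokens = tokens.to(config.device)
    with torch.no_grad():
        out = model(
            tokens,
            repr_layers=[model.num_layers],
            need_head_weights=True,
            return_contacts=True,
        )
    # attentions: (batch, L, H, T, T); batch of one
    att = out["attentions"][0].cpu().numpy()
    n_end = int(tokens.shape[1]) - 1 - len(record.sequence)  # eos + padding
    stripped = strip_special_tokens(att, 1, n_end, config.renormalize)
    meta = {
        "model": config.model_name,
        "heads": int(att.shape[1]),
        "layers": int(att.shape[0]),
        "renormalized": bool(config.renormalize),
        "special_tokens": "begin/end rows and columns removed",
    }
    tensor = AttentionTensor(record.protein_id, stripped, meta)
    reps = out["representations"][model.num_layers][0].cpu().numpy()
    emb = EmbeddingMatrix(
        record.protein_id,
        reps[1 : 1 + len(record.sequence)],
        cls_vector=reps[0],
    )
    contacts = ContactMap(record.protein_id, out["contacts"][0].cpu().numpy())
    return tensor, emb, contacts


def extract_to_archive(
    record: ProteinRecord,
    path: str | Path,
    config: ExtractionConfig | None = None,
) -> None:
    tensor, emb, contacts = extract(record, config)
    write_archive(
        path,
        tensor,
        embeddings=emb,
        contacts=contacts,
        sequence=record.sequence,
        family_id=record.family_id,
    )
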