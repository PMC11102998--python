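"""Protein feature views: gapped dipeptide composition and sequence embeddings.

The dipeptide-composition (DC) view counts ordered amino-acid pairs at two
gaps — adjacent residues (gap 0) and residues separated by one position
(gap 1) — each gap contributing a 400-entry block over the 20x20 ordered
pairs, for an 800-dimensional frequency vector.

The embedding view is a per-protein vector from a pretrained protein
language model, mean-pooled over residues.  The backend is pluggable; a
deterministic k-mer hash embedder is always available and is the default,
so the pipeline runs without any model download.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .containers import FeatureMatrix, FeatureSource, ProteinRecord
from .errors import ConfigurationError, EmptyDatasetError, MifamError

log = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order; pair (a1, a2)
#: maps to index 20 * pos(a1) + pos(a2) within its gap block.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

DC_DIM = 800
N_PAIRS = 400

#: Default fallback embedding width; the published pretrained backend is 1280.
DEFAULT_HASH_DIM = 256
PLM_DIM = 1280


@dataclass(frozen=True)
class EmbedderSpec:
    """How to turn a sequence into one vector.

    backend: ``"hash-fallback"`` (deterministic k-mer hashing, no external
        model) or ``"pretrained-plm"`` (a registered protein-language-model
        callable; per-residue representations are mean-pooled).
    d_embed: output width; ignored by the pretrained backend, which reports
        its own width (1280 for the published model).
    max_length: sequences longer than this are truncated (with a warning)
        before the pretrained backend, which has a hard input limit.
    """

    backend: str = "hash-fallback"
    d_embed: int = DEFAULT_HASH_DIM
    max_length: int = 1022
    pooling: str = "mean"

    def __post_init__(self) -> None:
        if self.backend not in ("hash-fallback", "pretrained-plm"):
            raise ConfigurationError(f"unknown embedder backend {self.backend!r}")
        if self.d_embed < 1 or self.max_length < 1:
            raise ConfigurationError("d_embed and max_length must be positive")
        if self.pooling != "mean":
            raise ConfigurationError("only mean pooling is supported")


def compute_dc(record: ProteinRecord) -> np.ndarray:
    """800-dim gapped dipeptide composition [gap-0 block | gap-1 block].

    Each block holds the frequency of every ordered amino-acid pair at that
    gap, normalized by the number of pairs of that gap type, so each block
    sums to 1 whenever at least one such pair exists.  Pairs containing a
    non-standard letter are excluded from both counts and denominators.
    """
    seq = record.sequence.upper()
    out = np.zeros(DC_DIM, dtype=np.float64)
    for gap, offset in ((1, 0), (2, N_PAIRS)):
        counts = np.zeros(N_PAIRS, dtype=np.float64)
        for i in range(len(seq) - gap):
            a, b = seq[i], seq[i + gap]
            if a in _AA_INDEX and b in _AA_INDEX:
                counts[20 * _AA_INDEX[a] + _AA_INDEX[b]] += 1
        total = counts.sum()
        if total > 0:
            out[offset:offset + N_PAIRS] = counts / total
    return out


# Pluggable pretrained-backend hook: a callable sequence -> (L, d) per-residue
# representations, registered by the user (e.g. wrapping fair-esm).
_PLM_BACKEND: Callable[[str], np.ndarray] | None = None


def set_plm_backend(fn: Callable[[str], np.ndarray] | None) -> None:
    """Register (or clear, with None) the pretrained embedder callable."""
    global _PLM_BACKEND
    _PLM_BACKEND = fn


def _hash_embed(seq: str, d_embed: int, k: int = 3) -> np.ndarray:
    """Deterministic bag-of-k-mers hash embedding, L2-normalized.

    Each k-mer is hashed (BLAKE2b) to a coordinate and a sign, giving a
    sparse random projection of k-mer counts that is sensitive to residue
    order and stable across runs and platforms.
    """
    vec = np.zeros(d_embed, dtype=np.float64)
    if len(seq) < k:
        k = len(seq)
    for i in range(len(seq) - k + 1):
        h = int.from_bytes(
            hashlib.blake2b(seq[i:i + k].encode("ascii", "replace"),
                            digest_size=8).digest(),
            "big",
        )
        sign = 1.0 if (h >> 60) & 1 else -1.0
        vec[h % d_embed] += sign
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def embed_protein(record: ProteinRecord, spec: EmbedderSpec | None = None) -> np.ndarray:
    """One embedding vector per protein, per the backend in ``spec``."""
    spec = spec or EmbedderSpec()
    seq = record.sequence.upper()
    if spec.backend == "hash-fallback":
        return _hash_embed(seq, spec.d_embed)
    if _PLM_BACKEND is None:
        raise ConfigurationError(
            "pretrained protein-language-model backend is not registered; "
            "call set_plm_backend(...) with an embedder, or use the "
            "'hash-fallback' backend"
        )
    if len(seq) > spec.max_length:
        log.warning(
            "protein %s: sequence length %d exceeds max_length %d, truncating",
            record.id, len(seq), spec.max_length,
        )
        seq = seq[: spec.max_length]
    residue_reps = np.asarray(_PLM_BACKEND(seq), dtype=np.float64)
    if residue_reps.ndim != 2:
        raise ConfigurationError("pretrained backend must return (L, d) per-residue array")
    return residue_reps.mean(axis=0)


def featurize_proteins(
    records: list[ProteinRecord], spec: EmbedderSpec | None = None
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Compute both protein views; rows aligned across the two matrices."""
    if not records:
        raise EmptyDatasetError("no protein records supplied")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise MifamError(
            f"duplicate protein ids: {sorted({i for i in ids if ids.count(i) > 1})}"
        )
    spec = spec or EmbedderSpec()
    dc_rows = []
    emb_rows = []
    for rec in records:
        dc = compute_dc(rec)
        if dc.sum() == 0:
            log.warning(
                "protein %s: no standard-residue pairs, DC vector is all zero",
                rec.id,
            )
        dc_rows.append(dc)
        emb_rows.append(embed_protein(rec, spec))
    return (
        FeatureMatrix(ids, np.vstack(dc_rows), FeatureSource.DC),
        FeatureMatrix(ids, np.vstack(emb_rows), FeatureSource.EMB),
    )
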