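"""Core in-memory containers shared by the featurization, graph and model stages.

Entities (drugs and protein targets) are carried around as id-aligned dense
matrices; similarity and adjacency matrices keep the same id list so every
stage can audit alignment instead of trusting positional order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import MifamError


class FeatureSource(str, Enum):
    """Provenance tag of a feature view."""

    PCP = "PCP"
    MACCS = "MACCS"
    DC = "DC"
    EMB = "EMB"
    FUSED = "FUSED"


@dataclass(frozen=True)
class DrugRecord:
    """A drug identified by ``id`` with a SMILES line notation string."""

    id: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.id:
            raise MifamError("drug record with empty id")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein target identified by ``id`` with an amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise MifamError("protein record with empty id")
        if not self.sequence:
            raise MifamError(f"protein record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class InteractionPair:
    """A labelled drug-target pair; label 1 = confirmed interaction."""

    drug_id: str
    protein_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise MifamError(
                f"pair ({self.drug_id}, {self.protein_id}) has non-binary "
                f"label {self.label!r}"
            )


def _check_ids(ids: Sequence[str]) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MifamError(f"duplicate ids: {dupes}")
    return ids


@dataclass
class FeatureMatrix:
    """An n x d real matrix whose rows are aligned with ``ids``."""

    ids: list[str]
    matrix: np.ndarray
    source: FeatureSource = FeatureSource.FUSED
    columns: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.ids = _check_ids(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise MifamError("feature matrix must be 2-D")
        if self.matrix.shape[0] != len(self.ids):
            raise MifamError(
                f"{len(self.ids)} ids but {self.matrix.shape[0]} feature rows"
            )
        if self.matrix.shape[1] < 1:
            raise MifamError("feature matrix must have at least one column")
        if not np.all(np.isfinite(self.matrix)):
            raise MifamError(f"non-finite entries in {self.source.value} features")
        if self.columns is not None and len(self.columns) != self.matrix.shape[1]:
            raise MifamError("column-name count does not match matrix width")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def row(self, entity_id: str) -> np.ndarray:
        return self.matrix[self.ids.index(entity_id)]


@dataclass
class SimilarityMatrix:
    """Symmetric cosine-similarity matrix over one entity set, entries in [-1, 1]."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.ids = _check_ids(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise MifamError("similarity matrix must be square and match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise MifamError("similarity matrix must be symmetric")
        if self.matrix.min() < -1 - 1e-9 or self.matrix.max() > 1 + 1e-9:
            raise MifamError("similarity entries must lie in [-1, 1]")


@dataclass
class AdjacencyMatrix:
    """Symmetric binary entity graph with self-loops; the GAT neighbourhood."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.ids = _check_ids(self.ids)
        self.matrix = np.asarray(self.matrix)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise MifamError("adjacency matrix must be square and match ids")
        if not np.array_equal(self.matrix, self.matrix.astype(bool).astype(self.matrix.dtype)):
            raise MifamError("adjacency entries must be binary")
        self.matrix = self.matrix.astype(np.int8)
        if not np.array_equal(self.matrix, self.matrix.T):
            raise MifamError("adjacency matrix must be symmetric")
        if not np.all(np.diag(self.matrix) == 1):
            raise MifamError("adjacency matrix must carry self-loops")

    @property
    def n(self) -> int:
        return len(self.ids)

    def neighbor_mask(self) -> np.ndarray:
        """Boolean n x n mask of N_i united with the self-loop."""
        return self.matrix.astype(bool)
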