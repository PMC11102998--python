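"""Feature fusion and similarity-graph construction.

Each feature view is PCA-reduced to a common dimension (128 by default),
views are fused by column-wise concatenation, and per-view binary
similarity graphs — cosine similarity thresholded at ``tau``, with
self-loops — are fused by elementwise logical OR.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import cosine_similarity

from .containers import AdjacencyMatrix, FeatureMatrix, FeatureSource, SimilarityMatrix
from .errors import MifamError

log = logging.getLogger(__name__)

DEFAULT_PCA_DIM = 128
DEFAULT_TAU = 0.5


def pca_reduce(F: FeatureMatrix, d_out: int = DEFAULT_PCA_DIM) -> FeatureMatrix:
    """Project rows onto the top principal components of the mean-centered matrix.

    The effective dimension is min(d_out, d, n - 1); components are ordered by
    decreasing explained variance and no whitening is applied.  To remove the
    sign ambiguity of eigenvectors, each component is flipped so that its
    largest-magnitude loading is positive.
    """
    if F.n < 2:
        raise MifamError("PCA requires at least 2 rows")
    d_eff = min(d_out, F.d, F.n - 1)
    if d_eff < d_out:
        log.warning("PCA dimension capped from %d to %d (rank limit)", d_out, d_eff)
    pca = PCA(n_components=d_eff, svd_solver="full")
    scores = pca.fit_transform(F.matrix)
    # fix the sign of each component by its largest-|.| loading
    comp = pca.components_
    flip = np.sign(comp[np.arange(d_eff), np.argmax(np.abs(comp), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    return FeatureMatrix(list(F.ids), scores, F.source)


def cosine_similarity_matrix(F: FeatureMatrix) -> SimilarityMatrix:
    """Pairwise cosine similarity S(A, B) = A.B / (|A| |B|) between rows.

    All-zero rows get similarity 0 against everything, themselves included;
    their self-loop is restored when the similarity is binarized into an
    adjacency matrix.
    """
    S = cosine_similarity(F.matrix)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    zero = ~F.matrix.any(axis=1)
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    return SimilarityMatrix(list(F.ids), S)


def binarize_similarity(
    S: SimilarityMatrix,
    tau: float = DEFAULT_TAU,
    mode: str = "threshold",
    k: int = 10,
) -> AdjacencyMatrix:
    """Turn a similarity matrix into a binary graph with self-loops.

    ``threshold`` mode keeps edge (i, j) iff S(i, j) >= tau; ``topk`` mode
    keeps each node's k most similar neighbours, symmetrized by union, which
    is useful when a global threshold would leave the graph too dense or too
    sparse.
    """
    if mode == "threshold":
        if not -1.0 <= tau <= 1.0:
            raise MifamError(f"tau must lie in [-1, 1], got {tau}")
        A = (S.matrix >= tau).astype(np.int8)
    elif mode == "topk":
        if k < 1:
            raise MifamError("k must be >= 1")
        n = len(S.ids)
        A = np.zeros((n, n), dtype=np.int8)
        order = np.argsort(-S.matrix, axis=1, kind="stable")
        for i in range(n):
            picked = [j for j in order[i] if j != i][:k]
            A[i, picked] = 1
        A = np.maximum(A, A.T)
    else:
        raise MifamError(f"unknown binarization mode {mode!r}")
    np.fill_diagonal(A, 1)
    return AdjacencyMatrix(list(S.ids), A)


def or_fuse(A1: AdjacencyMatrix, A2: AdjacencyMatrix) -> AdjacencyMatrix:
    """Elementwise logical OR of two graphs over the same entity list."""
    if A1.ids != A2.ids:
        raise MifamError("cannot OR-fuse adjacency matrices with different ids")
    return AdjacencyMatrix(list(A1.ids), np.maximum(A1.matrix, A2.matrix))


def concat_features(F1: FeatureMatrix, F2: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation [F1 || F2] of two id-aligned views."""
    if F1.ids != F2.ids:
        raise MifamError("cannot concatenate feature matrices with different ids")
    return FeatureMatrix(
        list(F1.ids), np.hstack([F1.matrix, F2.matrix]), FeatureSource.FUSED
    )


def build_fused_inputs(
    view1: FeatureMatrix,
    view2: FeatureMatrix,
    pca_dim: int = DEFAULT_PCA_DIM,
    tau: float = DEFAULT_TAU,
) -> tuple[FeatureMatrix, AdjacencyMatrix]:
    """Full per-entity fusion stage for one entity type.

    PCA-reduce each view, threshold each view's cosine-similarity matrix into
    a binary graph, OR-fuse the graphs, and concatenate the reduced views.
    Returns the fused feature matrix and fused adjacency.
    """
    r1 = pca_reduce(view1, pca_dim)
    r2 = pca_reduce(view2, pca_dim)
    a1 = binarize_similarity(cosine_similarity_matrix(r1), tau)
    a2 = binarize_similarity(cosine_similarity_matrix(r2), tau)
    return concat_features(r1, r2), or_fuse(a1, a2)
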