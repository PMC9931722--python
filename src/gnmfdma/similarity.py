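"""Similarity fusion, p-nearest-neighbor sparsification and graph Laplacians.

The overall drug similarity SD is a weighted element-wise mean of up to four
per-source matrices (chemical structure, indication phenotype, side effect,
gene functional consistency); the miRNA similarity SM averages two sources.
Each fused matrix is then localised: a p-nearest-neighbor weight mask G with
entries 1 (mutual neighbors), 0.5 (one-sided) or 0 (neither) multiplies the
similarity element-wise, giving the sparse matrix S* whose Laplacian
L = D - S* regularises the factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SimilarityMatrix, ValidationError


@dataclass
class SparseGraph:
    """A p-NN-masked similarity with its degree matrix and Laplacian.

    ``weight_mask`` is G (entries in {0, 0.5, 1}), ``sparse_similarity`` is
    S* = S o G, ``degree`` the diagonal D with D_ii = sum_l S*_il and
    ``laplacian`` L = D - S*.
    """

    entity_ids: list[str]
    weight_mask: np.ndarray
    sparse_similarity: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray


def fuse_similarities(
    matrices: list[SimilarityMatrix], weights: list[float] | None = None
) -> SimilarityMatrix:
    """Element-wise weighted mean of similarity matrices over identical ids.

    Default weights are all 1 (an unweighted mean). The fused kind is
    ``fused_drug`` or ``fused_mirna`` according to the inputs' entity side.
    """
    if not matrices:
        raise ValidationError("need at least one similarity matrix to fuse")
    if weights is None:
        weights = [1.0] * len(matrices)
    if len(weights) != len(matrices):
        raise ValidationError("weights length does not match number of matrices")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValidationError("fusion weights must be non-negative")
    if w.sum() <= 0:
        raise ValidationError("at least one fusion weight must be positive")
    ids = matrices[0].entity_ids
    for s in matrices[1:]:
        if s.entity_ids != ids:
            raise ValidationError("similarity matrices have mismatched entity ids")
    fused = sum(wi * s.values for wi, s in zip(w, matrices)) / w.sum()
    kind = "fused_mirna" if matrices[0].kind.startswith(("mirna", "fused_mirna")) else "fused_drug"
    return SimilarityMatrix(list(ids), fused, kind=kind)


def knn_weight_matrix(S: SimilarityMatrix, p: int) -> np.ndarray:
    """p-nearest-neighbor weight mask G over a similarity matrix.

    For i != j: G_ij = 1 if each is in the other's p-neighborhood, 0 if
    neither is, 0.5 otherwise; G_ii = 1. Neighborhoods exclude self and are
    ranked by descending similarity, ties broken by ascending entity index.
    """
    n = S.n
    if not (1 <= p <= n - 1):
        raise ValidationError(f"p={p} out of range for {n} entities")
    vals = S.values
    # stable argsort on (-sim, index) gives descending similarity with
    # ascending-index tie-break
    member = np.zeros((n, n), dtype=bool)  # member[i, j]: j in N_p(i)
    for i in range(n):
        order = np.argsort(-vals[i], kind="stable")
        order = order[order != i]
        member[i, order[:p]] = True
    G = np.full((n, n), 0.5)
    both = member & member.T
    neither = ~member & ~member.T
    G[both] = 1.0
    G[neither] = 0.0
    np.fill_diagonal(G, 1.0)
    return G


def sparsify(S: SimilarityMatrix, G: np.ndarray) -> np.ndarray:
    """Element-wise product S o G — the sparse similarity matrix S*."""
    G = np.asarray(G, dtype=float)
    if G.shape != S.values.shape:
        raise ValidationError(f"mask shape {G.shape} != similarity shape {S.values.shape}")
    return S.values * G


def build_graph(S: SimilarityMatrix, p: int) -> SparseGraph:
    """Compose mask -> sparsify -> degree -> Laplacian for one entity space."""
    G = knn_weight_matrix(S, p)
    S_star = sparsify(S, G)
    D = np.diag(S_star.sum(axis=1))
    L = D - S_star
    return SparseGraph(
        entity_ids=list(S.entity_ids),
        weight_mask=G,
        sparse_similarity=S_star,
        degree=D,
        laplacian=L,
    )
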