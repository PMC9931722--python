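"""Weighted K-nearest-known-neighbor reconstruction of the association matrix.

A sparse binary association matrix under-reports true associations: many 0s
are unobserved positives. Before factorization, each drug's interaction
profile is rebuilt from its K most similar drugs that have at least one
known association ("known neighbors"), weighted by similarity and a
geometric decay alpha^(i-1) over the neighbor rank i; symmetrically for
miRNAs. The drug-side and miRNA-side reconstructions are averaged and
merged with the original matrix by element-wise max, so observed 1s are
never erased.

The profile for drug d_l is

    Yd(d_l) = sum_i alpha^(i-1) * SD(d_i, d_l) * Y(d_i)  /  sum_i SD(d_i, d_l)

over neighbors i = 1..K in descending similarity. Note the denominator sums
the raw similarities without the decay, so for alpha < 1 the profile is a
deliberately damped (not convex) combination of neighbor profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, SimilarityMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class WknknResult:
    """Reconstructed association matrix with its two one-sided intermediates."""

    y_new: AssociationMatrix
    y_drug: np.ndarray
    y_mirna: np.ndarray


def _side_profiles(
    Y: np.ndarray, S: np.ndarray, K: int, alpha: float, known_only: bool
) -> np.ndarray:
    """Row-side reconstruction: Y is (n_entities x n_items), S is (n x n)."""
    n = Y.shape[0]
    out = np.zeros_like(Y, dtype=float)
    known = Y.sum(axis=1) > 0
    for l in range(n):
        cand = np.argsort(-S[:, l], kind="stable")
        cand = cand[cand != l]
        if known_only:
            cand = cand[known[cand]]
        if len(cand) == 0:
            logger.warning("entity %d has no eligible neighbors; profile left 0", l)
            continue
        if len(cand) < K:
            logger.warning(
                "entity %d has only %d known neighbors (K=%d); using all",
                l, len(cand), K,
            )
        nb = cand[:K]
        sims = S[nb, l]
        denom = sims.sum()
        if denom <= 0:
            logger.warning("entity %d: zero similarity to its neighbors; profile 0", l)
            continue
        theta = alpha ** np.arange(len(nb)) * sims
        out[l] = theta @ Y[nb] / denom
    return out


def wknkn_profiles(
    Y: AssociationMatrix,
    SD: SimilarityMatrix,
    SM: SimilarityMatrix,
    K: int = 3,
    alpha: float = 0.9,
    all_neighbors: bool = False,
) -> WknknResult:
    """Rebuild the association matrix from weighted nearest-known-neighbor profiles.

    Parameters
    ----------
    Y : AssociationMatrix
        Binary training associations (drugs x miRNAs).
    SD, SM : SimilarityMatrix
        Fused drug and miRNA similarities, id-aligned with ``Y``.
    K : int
        Number of neighbors per entity (default 3).
    alpha : float
        Decay in (0, 1]; neighbor i contributes with weight
        alpha^(i-1) * similarity (default 0.9).
    all_neighbors : bool
        If True, rank all other entities rather than only those with at
        least one known association.

    Returns
    -------
    WknknResult
        ``y_new`` = max(Y, (Yd + Ym)/2) element-wise; entries that were 1
        stay exactly 1 and all values lie in [0, 1].
    """
    if K < 1:
        raise ValidationError(f"K must be >= 1, got {K}")
    if not (0 < alpha <= 1):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    SD.check_ids(Y.drug_ids)
    SM.check_ids(Y.mirna_ids)
    Yv = Y.values
    yd = _side_profiles(Yv, SD.values, K, alpha, known_only=not all_neighbors)
    ym = _side_profiles(Yv.T, SM.values, K, alpha, known_only=not all_neighbors).T
    ydm = (yd + ym) / 2.0
    np.clip(ydm, 0.0, 1.0, out=ydm)  # guard numeric drift only
    y_new = np.maximum(Yv, ydm)
    return WknknResult(
        y_new=AssociationMatrix(
            list(Y.drug_ids), list(Y.mirna_ids), y_new, binary=False
        ),
        y_drug=yd,
        y_mirna=ym,
    )
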