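"""Synthetic benchmark generator for bipartite association prediction.

Emulates the statistical structure the model assumes, at the scale of the
curated drug-miRNA dataset the method targets (~40 drugs x ~300 miRNAs,
~6% association density): a low-rank non-negative score surface whose top
quantile defines the binary associations, and similarity matrices that are
noisy views of the same latent factor geometry.

Latent factor entries are squared-normal (chi-square with 1 df), a
heavy-tailed choice that concentrates mass on a few large loadings and so
produces the skewed per-drug association counts seen in real curated
association data; uniform factors would give an unrealistically flat
degree distribution. Each similarity matrix is cosine similarity between
latent factor columns blended with a symmetric uniform noise matrix at
mixing weight ``noise``; the four drug-side matrices (and two miRNA-side
matrices) use independent noise draws, so they are genuinely distinct
views of one geometry, which is what the fusion step is for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import AssociationMatrix, SimilarityMatrix, ValidationError, write_matrix

_DRUG_KINDS = ("drug_chemical", "drug_phenotype", "drug_side_effect", "drug_gene")
_MIRNA_KINDS = ("mirna_phenotype", "mirna_gene")


@dataclass
class SyntheticDataset:
    """Generated associations, similarities and the latent truth behind them."""

    assoc: AssociationMatrix
    drug_sims: list[SimilarityMatrix]
    mirna_sims: list[SimilarityMatrix]
    truth: np.ndarray
    planted_rank: int
    seed: int
    params: dict


def _noisy_cosine_similarity(
    F: np.ndarray, noise: float, rng: np.random.Generator, kind: str, ids: list[str]
) -> SimilarityMatrix:
    """Cosine similarity of factor columns blended with symmetric uniform noise."""
    norms = np.linalg.norm(F, axis=0, keepdims=True)
    Fn = F / np.maximum(norms, 1e-300)
    cos = Fn.T @ Fn  # in [0,1]: factors are non-negative
    n = cos.shape[0]
    U = rng.uniform(size=(n, n))
    U = (U + U.T) / 2.0
    S = (1.0 - noise) * cos + noise * U
    np.fill_diagonal(S, 1.0)
    np.clip(S, 0.0, 1.0, out=S)
    return SimilarityMatrix(ids, S, kind=kind)


def generate(
    n: int = 40,
    m: int = 300,
    r: int = 5,
    density: float = 0.06,
    noise: float = 0.2,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a dataset with planted low-rank association structure.

    Parameters
    ----------
    n, m : int
        Numbers of drugs and miRNAs (defaults match the target data scale).
    r : int
        Planted factor rank.
    density : float
        Fraction of pairs set to 1 — the top ``round(density*n*m)`` entries
        of the latent score surface.
    noise : float
        Mixing weight in [0, 1] of the uniform component of each similarity
        matrix; 0 gives pure factor cosine, 1 destroys all factor signal.
    seed : int
        Seed; the dataset is a deterministic function of all arguments.
    """
    if r >= min(n, m):
        raise ValidationError(f"rank r={r} must be < min(n, m)")
    if not (0 < density < 0.5):
        raise ValidationError("density must be in (0, 0.5)")
    if noise < 0 or noise > 1:
        raise ValidationError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    W0 = rng.normal(size=(r, n)) ** 2
    H0 = rng.normal(size=(r, m)) ** 2
    truth = W0.T @ H0
    n_pos = int(round(density * n * m))
    flat = np.argsort(-truth, axis=None, kind="stable")[:n_pos]
    Y = np.zeros(n * m)
    Y[flat] = 1.0
    Y = Y.reshape(n, m)
    drug_ids = [f"d{i+1}" for i in range(n)]
    mirna_ids = [f"m{j+1}" for j in range(m)]
    drug_sims = [
        _noisy_cosine_similarity(W0, noise, rng, kind, drug_ids) for kind in _DRUG_KINDS
    ]
    mirna_sims = [
        _noisy_cosine_similarity(H0, noise, rng, kind, mirna_ids)
        for kind in _MIRNA_KINDS
    ]
    return SyntheticDataset(
        assoc=AssociationMatrix(drug_ids, mirna_ids, Y),
        drug_sims=drug_sims,
        mirna_sims=mirna_sims,
        truth=truth,
        planted_rank=r,
        seed=seed,
        params={
            "n": n, "m": m, "r": r, "density": density, "noise": noise, "seed": seed,
        },
    )


def permute_similarities(
    sims: list[SimilarityMatrix], seed: int = 0
) -> list[SimilarityMatrix]:
    """Destroy similarity information by a random entity relabeling.

    One shared permutation is applied to rows and columns of every matrix
    while the original id labels stay in place, so each matrix remains a
    valid similarity but is decoupled from the associations. Negative
    control for side-information benefit.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sims[0].n)
    return [
        SimilarityMatrix(list(s.entity_ids), s.values[np.ix_(perm, perm)], kind=s.kind)
        for s in sims
    ]


def write_dataset(ds: SyntheticDataset, dir: str | Path) -> dict[str, Path]:
    """Write every matrix in the dense labeled format plus a JSON manifest."""
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    files["assoc"] = dir / "associations.tsv"
    write_matrix(ds.assoc, files["assoc"])
    for s in ds.drug_sims + ds.mirna_sims:
        p = dir / f"sim_{s.kind}.tsv"
        write_matrix(s, p)
        files[s.kind] = p
    manifest = dir / "manifest.json"
    manifest.write_text(json.dumps(ds.params, indent=2) + "\n", encoding="utf-8")
    files["manifest"] = manifest
    return files
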