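"""Labeled matrix containers and text readers/writers.

Two container types cover everything the pipeline touches: a bipartite
drug x miRNA association matrix (binary on ingest, real-valued after
neighbor-profile reconstruction) and a square symmetric similarity matrix
over a single entity type. Both are thin wrappers over a pandas DataFrame
carrying identifier labels, with validation at construction.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SIMILARITY_KINDS = frozenset(
    {
        "drug_chemical",
        "drug_phenotype",
        "drug_side_effect",
        "drug_gene",
        "mirna_phenotype",
        "mirna_gene",
        "fused_drug",
        "fused_mirna",
    }
)

_SYM_TOL = 1e-6
_SYM_ENFORCE_TOL = 1e-8
_CLIP_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")
    if len(ids) == 0:
        raise ValidationError(f"empty {what} identifier list")
    return ids


@dataclass
class AssociationMatrix:
    """Bipartite drug x miRNA association matrix Y with identifier labels.

    Values are binary {0, 1} on ingest and real-valued in [0, 1] after
    the weighted nearest-known-neighbor reconstruction.
    """

    drug_ids: list[str]
    mirna_ids: list[str]
    values: np.ndarray
    binary: bool = field(default=True)

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.drug_ids), len(self.mirna_ids)
        if self.values.shape != (n, m):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"{n} drugs x {m} miRNAs"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("association matrix contains non-finite values")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValidationError("association values outside [0, 1]")
        if self.binary:
            bad = (self.values != 0) & (self.values != 1)
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"non-binary value {self.values[i, j]!r} at "
                    f"drug={self.drug_ids[i]!r}, mirna={self.mirna_ids[j]!r}"
                )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_associations(self) -> int:
        """Number of known (nonzero) pairs."""
        return int(np.count_nonzero(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids, columns=self.mirna_ids)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.drug_ids), list(self.mirna_ids), self.values.copy(), self.binary
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one entity type.

    Entries in [0, 1]; diagonal is defined as 1 (self-similarity) and is
    forced at ingest — all similarity measures this pipeline consumes are
    reflexive.
    """

    entity_ids: list[str]
    values: np.ndarray
    kind: str = "fused_drug"

    def __post_init__(self) -> None:
        if self.kind not in SIMILARITY_KINDS:
            raise ValidationError(f"unknown similarity kind {self.kind!r}")
        self.entity_ids = _check_unique(self.entity_ids, "entity")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"similarity shape {self.values.shape} is not square of size {n}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("similarity matrix contains non-finite values")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > _SYM_TOL:
            raise ValidationError(f"similarity asymmetry {asym:.3g} exceeds {_SYM_TOL}")
        if asym > 0:
            self.values = (self.values + self.values.T) / 2.0
        lo, hi = self.values.min(), self.values.max()
        if lo < -_CLIP_TOL or hi > 1 + _CLIP_TOL:
            raise ValidationError(f"similarity values outside [0, 1]: [{lo}, {hi}]")
        np.clip(self.values, 0.0, 1.0, out=self.values)
        np.fill_diagonal(self.values, 1.0)

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.entity_ids)

    def check_ids(self, reference: Sequence[str]) -> None:
        """Require the entity universe to match ``reference`` exactly, in order."""
        ref = [str(x) for x in reference]
        if self.entity_ids != ref:
            missing = sorted(set(ref) - set(self.entity_ids))
            extra = sorted(set(self.entity_ids) - set(ref))
            raise ValidationError(
                f"entity id mismatch (missing={missing}, extra={extra}, "
                f"order_only={not missing and not extra})"
            )


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    first = Path(path).read_text(encoding="utf-8").splitlines()[0]
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_dense(path: Path, sep: str | None) -> pd.DataFrame:
    sep = _sniff_sep(path, sep)
    # check header duplicates before pandas silently renames them
    header = Path(path).read_text(encoding="utf-8").splitlines()[0].split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValidationError(f"duplicate column identifiers in {path}")
    return pd.read_csv(path, sep=sep, index_col=0)


def read_association_matrix(
    path: str | Path,
    format: str = "dense",
    sep: str | None = None,
    drug_ids: Sequence[str] | None = None,
    mirna_ids: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Read an association matrix from dense labeled text or a 2-column edge list.

    Dense format: header row of miRNA ids, first column of drug ids.
    Edge list: rows of ``drug_id<sep>mirna_id``; duplicates collapse to a
    single 1; identifier order is first-appearance order unless explicit id
    lists are supplied.
    """
    path = Path(path)
    if format == "dense":
        df = _read_dense(path, sep)
        if df.size == 0:
            raise ValidationError(f"empty association matrix in {path}")
        return AssociationMatrix(
            [str(x) for x in df.index],
            [str(x) for x in df.columns],
            df.to_numpy(dtype=float),
        )
    if format == "edge_list":
        df = pd.read_csv(path, sep=_sniff_sep(path, sep), header=None, dtype=str)
        if df.shape[0] and {str(x).lower() for x in df.iloc[0]} & {"drug", "drug_id"}:
            df = df.iloc[1:]
        if df.shape[1] != 2:
            raise ValidationError(f"edge list must have 2 columns, got {df.shape[1]}")
        if df.empty:
            raise ValidationError(f"empty edge list in {path}")
        pairs = [(str(a), str(b)) for a, b in df.itertuples(index=False)]
        d_ids = list(drug_ids) if drug_ids is not None else list(dict.fromkeys(a for a, _ in pairs))
        m_ids = list(mirna_ids) if mirna_ids is not None else list(dict.fromkeys(b for _, b in pairs))
        d_pos = {x: i for i, x in enumerate(d_ids)}
        m_pos = {x: i for i, x in enumerate(m_ids)}
        Y = np.zeros((len(d_ids), len(m_ids)))
        for a, b in pairs:
            if a not in d_pos or b not in m_pos:
                raise ValidationError(f"edge ({a}, {b}) outside the supplied id universe")
            Y[d_pos[a], m_pos[b]] = 1.0
        return AssociationMatrix(d_ids, m_ids, Y)
    raise ValueError(f"unknown format {format!r}")


def read_similarity_matrix(
    path: str | Path,
    kind: str,
    sep: str | None = None,
    reference_ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Read a dense labeled square similarity matrix.

    Symmetrized as (S + S.T)/2 when the asymmetry is within tolerance;
    larger asymmetry, out-of-range values, or a non-square file are errors.
    """
    path = Path(path)
    df = _read_dense(path, sep)
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValidationError(f"similarity file {path} is not square/label-aligned")
    sim = SimilarityMatrix(rows, df.to_numpy(dtype=float), kind=kind)
    if reference_ids is not None:
        sim.check_ids(reference_ids)
    return sim


def write_matrix(obj: AssociationMatrix | SimilarityMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write either container in the dense labeled text format."""
    obj.to_frame().to_csv(Path(path), sep=sep)


def write_predictions(
    scores: pd.DataFrame, path: str | Path, sep: str = "\t", top_n: int | None = None
) -> None:
    """Write (drug_id, mirna_id, score) rows sorted by score descending."""
    long = scores.stack().rename("score").reset_index()
    long.columns = ["drug_id", "mirna_id", "score"]
    long = long.sort_values(
        ["score", "drug_id", "mirna_id"], ascending=[False, True, True]
    )
    if top_n is not None:
        long = long.head(top_n)
    long.to_csv(Path(path), sep=sep, index=False)
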