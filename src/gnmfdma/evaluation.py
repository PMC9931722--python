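"""Cross-validated evaluation of association predictions.

Known pairs are partitioned into folds; each fold in turn is hidden from
training (its 1s masked to 0) and the remaining pairs train the full
pipeline. Held-out pairs are the positives of the fold's ROC; negatives are
all pairs that are 0 in the complete known matrix (unknowns treated as
negatives, the standard convention for association-prediction CV).
Threshold metrics are taken at the cutoff achieving a fixed specificity
(default 85% true-negative rate). A separate full-training analysis counts
how many known pairs each drug recovers within its top-q% ranked miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import AssociationMatrix, SimilarityMatrix, ValidationError
from .model import GNMFDMA, Config


@dataclass
class FoldSplit:
    """Partition of the known (drug, miRNA) pairs into CV folds."""

    fold_assignments: dict[tuple[int, int], int]
    n_folds: int
    seed: int

    def pairs_in_fold(self, fold: int) -> list[tuple[int, int]]:
        return [p for p, f in self.fold_assignments.items() if f == fold]


def make_folds(Y: AssociationMatrix, n_folds: int = 5, seed: int = 0) -> FoldSplit:
    """Uniform random partition of positive pairs; fold sizes differ by <= 1."""
    pos = [tuple(map(int, ij)) for ij in np.argwhere(Y.values > 0)]
    if len(pos) < n_folds:
        raise ValidationError(
            f"{len(pos)} positives cannot be split into {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos))
    assignments = {pos[idx]: int(i % n_folds) for i, idx in enumerate(order)}
    return FoldSplit(fold_assignments=assignments, n_folds=n_folds, seed=seed)


def auc(scores, labels) -> float:
    """Tie-corrected ROC AUC: P(random positive outranks random negative)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class ThresholdMetrics:
    sensitivity: float
    precision: float
    accuracy: float
    f1: float
    threshold: float
    specificity_achieved: float


def metrics_at_specificity(
    scores, labels, specificity: float = 0.85
) -> ThresholdMetrics:
    """Sen/Pre/Acc/F1 at the smallest cutoff achieving the requested TNR.

    A pair is called positive when its score is strictly greater than the
    threshold. Precision (and hence F1) is reported as 0 when no pair is
    called positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not (0 < specificity < 1):
        raise ValidationError("specificity must be in (0, 1)")
    if len(np.unique(labels)) < 2:
        raise ValidationError("threshold metrics need both classes present")
    neg = np.sort(scores[labels == 0])
    n_neg = len(neg)
    # smallest threshold t with  #{neg <= t} / n_neg >= specificity
    idx = int(np.ceil(specificity * n_neg)) - 1
    threshold = float(neg[idx])
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sen = tp / (tp + fn) if tp + fn else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / (tp + fp + tn + fn)
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    return ThresholdMetrics(
        sensitivity=sen,
        precision=pre,
        accuracy=acc,
        f1=f1,
        threshold=threshold,
        specificity_achieved=tn / (tn + fp),
    )


@dataclass
class EvalReport:
    """Per-fold CV metrics with their aggregate."""

    per_fold: list[dict]
    mean_auc: float
    sd_auc: float
    cv_seed: int
    fit_seed: int
    config: Config
    recovery: dict[float, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_fold)
        mean = df.drop(columns="fold").mean(numeric_only=True).to_frame().T
        mean.insert(0, "fold", "mean")
        return pd.concat([df.astype({"fold": object}), mean], ignore_index=True)


def run_cv(
    assoc: AssociationMatrix,
    drug_sims: list[SimilarityMatrix],
    mirna_sims: list[SimilarityMatrix],
    config: Config | None = None,
    n_folds: int = 5,
    cv_seed: int = 0,
    use_wknkn: bool = True,
    specificity: float = 0.85,
    pooled_auc: bool = False,
) -> EvalReport:
    """Five-fold CV over known pairs with the full pipeline retrained per fold.

    Each fold's positives are masked to 0 in the training matrix before the
    neighbor-profile reconstruction, so held-out labels never reach the
    training stage. Per-fold AUCs are averaged by default; ``pooled_auc``
    additionally reports the AUC of all folds' scores pooled.
    """
    config = config or Config()
    split = make_folds(assoc, n_folds=n_folds, seed=cv_seed)
    Y_full = assoc.values
    neg_mask = Y_full == 0
    per_fold = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for fold in range(n_folds):
        held = split.pairs_in_fold(fold)
        Y_train = Y_full.copy()
        for i, j in held:
            Y_train[i, j] = 0.0
        train_assoc = AssociationMatrix(
            list(assoc.drug_ids), list(assoc.mirna_ids), Y_train
        )
        model = GNMFDMA(
            train_assoc, drug_sims, mirna_sims, config=config, use_wknkn=use_wknkn
        )
        res = model.fit()
        scores = res.predict()
        pos_scores = np.array([scores[i, j] for i, j in held])
        neg_scores = scores[neg_mask]
        s = np.concatenate([pos_scores, neg_scores])
        y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
        tm = metrics_at_specificity(s, y, specificity)
        per_fold.append(
            {
                "fold": fold,
                "auc": auc(s, y),
                "sensitivity": tm.sensitivity,
                "precision": tm.precision,
                "accuracy": tm.accuracy,
                "f1": tm.f1,
                "threshold_used": tm.threshold,
                "n_test_pos": len(held),
                "converged": res.converged,
            }
        )
        pooled_scores.append(s)
        pooled_labels.append(y)
    aucs = np.array([r["auc"] for r in per_fold])
    report = EvalReport(
        per_fold=per_fold,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        cv_seed=cv_seed,
        fit_seed=config.seed,
        config=config,
    )
    if pooled_auc:
        report.per_fold.append(
            {
                "fold": "pooled",
                "auc": auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels)),
            }
        )
    return report


def top_fraction_recovery(
    scores: np.ndarray, Y: AssociationMatrix, q: float
) -> int:
    """Count known pairs ranked within each drug's top ceil(q*m) miRNAs.

    Intended for a model trained on all known associations: measures how
    well training pairs surface at the top of per-drug rankings.
    """
    if not (0 < q <= 1):
        raise ValidationError("q must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    m = Y.n_mirnas
    top = int(np.ceil(q * m))
    count = 0
    for i in range(Y.n_drugs):
        ranked = np.argsort(-scores[i], kind="stable")[:top]
        count += int(Y.values[i, ranked].sum())
    return count


def rank_candidates(
    scores: pd.DataFrame,
    Y: AssociationMatrix,
    drug_id: str,
    top_n: int | None = None,
    exclude_known: bool = False,
) -> list[tuple[str, float]]:
    """Ranked (mirna_id, score) list for one drug, ties broken by id."""
    if drug_id not in Y.drug_ids:
        raise ValidationError(f"unknown drug id {drug_id!r}")
    i = Y.drug_ids.index(drug_id)
    row = scores.loc[drug_id]
    items = [(str(mid), float(row[mid])) for mid in Y.mirna_ids]
    if exclude_known:
        items = [(mid, s) for (mid, s), known in zip(items, Y.values[i]) if not known]
    items.sort(key=lambda t: (-t[1], t[0]))
    if top_n is not None:
        items = items[:top_n]
    return items
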