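import numpy as np
import pandas as pd
import pytest

from conftest import random_association
from gnmfdma import (
    AssociationMatrix,
    Config,
    ValidationError,
    auc,
    make_folds,
    metrics_at_specificity,
    rank_candidates,
    run_cv,
    top_fraction_recovery,
)


def brute_force_auc(scores, labels):
    """O(P*N) rank statistic: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestFolds:
    def test_study_scale_fold_sizes(self):
        rng = np.random.default_rng(1)
        Y = np.zeros(39 * 286)
        Y[rng.choice(39 * 286, 664, replace=False)] = 1
        am = AssociationMatrix(
            [f"d{i}" for i in range(39)], [f"m{j}" for j in range(286)],
            Y.reshape(39, 286),
        )
        split = make_folds(am, 5, seed=3)
        sizes = sorted(len(split.pairs_in_fold(f)) for f in range(5))
        assert sizes == [132, 133, 133, 133, 133]

    def test_partition_and_determinism(self, rng):
        am = random_association(rng, 10, 12, density=0.3)
        s1 = make_folds(am, 4, seed=9)
        s2 = make_folds(am, 4, seed=9)
        assert s1.fold_assignments == s2.fold_assignments
        all_pairs = set()
        for f in range(4):
            pairs = s1.pairs_in_fold(f)
            assert not (all_pairs & set(pairs))
            all_pairs |= set(pairs)
        assert all_pairs == {tuple(map(int, ij)) for ij in np.argwhere(am.values > 0)}

    def test_too_few_positives(self):
        am = AssociationMatrix(["d1"], ["m1", "m2"], np.array([[1.0, 0.0]]))
        with pytest.raises(ValidationError):
            make_folds(am, 5, seed=0)


class TestAuc:
    def test_perfect_and_tied(self):
        assert auc([0.9, 0.1], [1, 0]) == 1.0
        assert auc([0.5, 0.5], [1, 0]) == 0.5

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 7), size=20)
            labels = rng.integers(0, 2, size=20)
            if labels.sum() in (0, 20):
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        assert auc(np.exp(5 * scores), labels) == pytest.approx(auc(scores, labels))

    def test_single_class_error(self):
        with pytest.raises(ValidationError):
            auc([0.1, 0.2], [1, 1])


class TestMetricsAtSpecificity:
    def test_hand_computed_confusion(self):
        # thresholding at 80% specificity leaves TP=3, FP=1, TN=4, FN=2
        scores = [0.5, 0.6, 0.7, 0.3, 0.2, 0.1, 0.2, 0.3, 0.4, 0.9]
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        m = metrics_at_specificity(scores, labels, specificity=0.8)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.precision == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.7)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0]
        for spec in (0.6, 0.85, 0.99):
            m = metrics_at_specificity(scores, labels, specificity=spec)
            assert (m.sensitivity, m.precision, m.accuracy, m.f1) == (1, 1, 1, 1)

    def test_achieved_specificity_at_least_requested(self, rng):
        for _ in range(20):
            scores = rng.uniform(size=40)
            labels = rng.integers(0, 2, size=40)
            labels[0], labels[1] = 0, 1
            for spec in (0.5, 0.85, 0.95):
                m = metrics_at_specificity(scores, labels, spec)
                assert m.specificity_achieved >= spec - 1e-12

    def test_sensitivity_nonincreasing_in_specificity(self, rng):
        scores = rng.uniform(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[0], labels[1] = 0, 1
        sens = [
            metrics_at_specificity(scores, labels, s).sensitivity
            for s in (0.5, 0.7, 0.85, 0.95)
        ]
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_no_positive_calls_reports_zero(self):
        # all positives score below every negative: nothing exceeds threshold
        m = metrics_at_specificity([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 0.9)
        assert m.precision == 0.0 and m.f1 == 0.0


class TestTopFractionRecovery:
    def test_q_one_counts_all_positives(self, rng):
        am = random_association(rng, 5, 8, density=0.3)
        scores = rng.uniform(size=(5, 8))
        assert top_fraction_recovery(scores, am, 1.0) == am.n_associations

    def test_perfectly_ranked_scores(self, rng):
        am = random_association(rng, 4, 10, density=0.2)
        scores = am.values + rng.uniform(0, 0.5, size=(4, 10)) * am.values
        q = max(am.values.sum(axis=1)) / 10
        assert top_fraction_recovery(scores, am, q) == am.n_associations

    def test_hand_enumerated_toy(self):
        # 3 drugs x 10 miRNAs, q=0.2 -> top-2 per drug
        Y = np.zeros((3, 10))
        Y[0, 0] = Y[0, 5] = Y[1, 3] = Y[2, 9] = 1.0
        am = AssociationMatrix(
            [f"d{i}" for i in range(3)], [f"m{j}" for j in range(10)], Y
        )
        scores = np.zeros((3, 10))
        scores[0] = [9, 8, 0, 0, 0, 7, 0, 0, 0, 0]  # top-2: m0, m1 -> recovers m0
        scores[1] = [0, 0, 5, 6, 0, 0, 0, 0, 0, 0]  # top-2: m3, m2 -> recovers m3
        scores[2] = [1, 2, 0, 0, 0, 0, 0, 0, 0, 0]  # top-2: m1, m0 -> recovers none
        assert top_fraction_recovery(scores, am, 0.2) == 2


class TestRankCandidates:
    def _setup(self):
        Y = np.zeros((1, 5))
        Y[0, 0] = 1.0
        am = AssociationMatrix(["d1"], [f"m{j+1}" for j in range(5)], Y)
        scores = pd.DataFrame(
            [[0.9, 0.1, 0.9, 0.2, 0.5]], index=["d1"], columns=am.mirna_ids
        )
        return am, scores

    def test_tie_break_by_id(self):
        am, scores = self._setup()
        ranked = rank_candidates(scores, am, "d1")
        assert [m for m, _ in ranked] == ["m1", "m3", "m5", "m4", "m2"]

    def test_exclude_known_and_top_n(self):
        am, scores = self._setup()
        ranked = rank_candidates(scores, am, "d1", top_n=2, exclude_known=True)
        assert [m for m, _ in ranked] == ["m3", "m5"]

    def test_top_n_larger_than_m_gives_full_list(self):
        am, scores = self._setup()
        assert len(rank_candidates(scores, am, "d1", top_n=100)) == 5

    def test_unknown_drug_error(self):
        am, scores = self._setup()
        with pytest.raises(ValidationError):
            rank_candidates(scores, am, "nope")


class TestRunCv:
    def test_report_structure_and_determinism(self, tiny_dataset):
        cfg = Config(k=4, p=3, seed=2, max_iter=200)
        rep1 = run_cv(
            tiny_dataset.assoc, tiny_dataset.drug_sims, tiny_dataset.mirna_sims,
            config=cfg, n_folds=3, cv_seed=5,
        )
        rep2 = run_cv(
            tiny_dataset.assoc, tiny_dataset.drug_sims, tiny_dataset.mirna_sims,
            config=cfg, n_folds=3, cv_seed=5,
        )
        assert rep1.mean_auc == rep2.mean_auc
        assert len(rep1.per_fold) == 3
        aucs = [r["auc"] for r in rep1.per_fold]
        assert rep1.mean_auc == pytest.approx(np.mean(aucs))
        assert rep1.sd_auc == pytest.approx(np.std(aucs, ddof=1))
        for r in rep1.per_fold:
            for key in ("auc", "sensitivity", "precision", "accuracy", "f1"):
                assert 0.0 <= r[key] <= 1.0
        frame = rep1.to_frame()
        assert str(frame.iloc[-1]["fold"]) == "mean"

    def test_training_never_sees_held_out_labels(self, tiny_dataset, monkeypatch):
        # canary: capture the matrices run_cv actually trains on and check
        # each fold's held-out positives are zeroed there
        import gnmfdma.evaluation as ev

        captured = []
        real = ev.GNMFDMA

        class Spy(real):
            def __init__(self, assoc, *args, **kwargs):
                captured.append(assoc.values.copy())
                super().__init__(assoc, *args, **kwargs)

        monkeypatch.setattr(ev, "GNMFDMA", Spy)
        am = tiny_dataset.assoc
        cfg = Config(k=3, p=3, seed=2, max_iter=50)
        run_cv(am, tiny_dataset.drug_sims, tiny_dataset.mirna_sims,
               config=cfg, n_folds=3, cv_seed=5)
        split = make_folds(am, 3, seed=5)
        assert len(captured) == 3
        for fold, Y_train in enumerate(captured):
            held = split.pairs_in_fold(fold)
            assert all(Y_train[i, j] == 0 for i, j in held)
            assert Y_train.sum() == am.values.sum() - len(held)

    def test_pooled_auc_row_appended(self, tiny_dataset):
        cfg = Config(k=4, p=3, seed=2, max_iter=100)
        rep = run_cv(
            tiny_dataset.assoc, tiny_dataset.drug_sims, tiny_dataset.mirna_sims,
            config=cfg, n_folds=3, cv_seed=5, pooled_auc=True,
        )
        assert rep.per_fold[-1]["fold"] == "pooled"
        assert 0.0 <= rep.per_fold[-1]["auc"] <= 1.0
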