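"""Ordinal metrics against brute-force definitional oracles and sklearn."""

import numpy as np
import pytest
import sklearn.metrics as skm

from ordsmooth.metrics import (
    ScoreTable,
    UndefinedMetricError,
    confusion_matrix,
    multiclass_mcc,
    pairwise_average_auroc,
    quadratic_weight_matrix,
    quadratic_weighted_kappa,
    weighted_prf,
)

from conftest import random_confusion, random_score_table

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


# ---------------------------------------------------------------------------
# brute-force definitional oracles (independent of the implementation)


def kappa_oracle(cm):
    """Definitional quadratic-weighted kappa: explicit double loop."""
    cm = np.asarray(cm, dtype=float)
    K = cm.shape[0]
    n = cm.sum()
    num = den = 0.0
    for i in range(K):
        for j in range(K):
            w = (i - j) ** 2 / (K - 1) ** 2
            num += w * cm[i, j] / n
            den += w * (cm[i].sum() / n) * (cm[:, j].sum() / n)
    return 1.0 - num / den


def prf_oracle(cm):
    """Explicit per-class TP/FP/FN arithmetic, support-weighted."""
    cm = np.asarray(cm, dtype=float)
    K = cm.shape[0]
    n = cm.sum()
    P = R = F = 0.0
    for k in range(K):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = cm[k].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        w = cm[k].sum() / n
        P += w * prec
        R += w * rec
        F += w * f1
    return P, R, F


def binary_mcc_oracle(cm):
    """Textbook binary MCC from TP/TN/FP/FN (class 1 positive)."""
    tn, fp, fn, tp = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
    den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / den


def auroc_oracle(table):
    """Exhaustive cross-class pair counting: concordant + half of ties,
    averaged over both directions of every present class pair."""
    present = np.unique(table.y_true)
    vals = []
    for ii in range(len(present)):
        for jj in range(ii + 1, len(present)):
            i, j = present[ii], present[jj]
            pair = []
            for pos, cls in ((i, j), (j, i)):
                pos_scores = table.scores[table.y_true == pos][:, pos]
                neg_scores = table.scores[table.y_true == cls][:, pos]
                wins = 0.0
                for a in pos_scores:
                    for b in neg_scores:
                        if a > b:
                            wins += 1.0
                        elif a == b:
                            wins += 0.5
                pair.append(wins / (len(pos_scores) * len(neg_scores)))
            vals.append(0.5 * (pair[0] + pair[1]))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------


class TestConfusionMatrix:
    def test_identity_two_class(self):
        t = ScoreTable(ids=[0, 1], y_true=[0, 1], scores=[[1, 0], [0, 1]])
        np.testing.assert_array_equal(confusion_matrix(t), [[1, 0], [0, 1]])

    def test_constant_prediction_fills_one_column(self, rng):
        t = random_score_table(rng, 40, 5)
        t.scores = np.tile([1.0, 0, 0, 0, 0], (40, 1))
        cm = confusion_matrix(t)
        assert cm[:, 0].sum() == 40 and cm[:, 1:].sum() == 0

    def test_permutation_invariant(self, rng):
        t = random_score_table(rng, 60, 3)
        perm = rng.permutation(60)
        np.testing.assert_array_equal(
            confusion_matrix(t), confusion_matrix(t.subset(perm))
        )

    def test_empty_table_rejected(self):
        t = ScoreTable(ids=[], y_true=[], scores=np.empty((0, 3)))
        with pytest.raises(ValueError):
            confusion_matrix(t)

    def test_argmax_ties_break_to_lowest_grade(self):
        t = ScoreTable(ids=[0], y_true=[2], scores=[[0.3, 0.3, 0.3, 0.05, 0.05]])
        assert t.y_pred[0] == 0


class TestWeightMatrix:
    def test_structure(self):
        w = quadratic_weight_matrix(5)
        assert (np.diag(w) == 0).all()
        np.testing.assert_array_equal(w, w.T)
        assert w[0, 4] == w[4, 0] == 1.0


class TestQuadKappa:
    def test_perfect_diagonal(self):
        assert quadratic_weighted_kappa(np.diag([5, 3, 2, 4, 1])) == 1.0

    def test_uniform_two_class_is_zero(self):
        assert quadratic_weighted_kappa([[1, 1], [1, 1]]) == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_raises(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[1, 1] = 10
        with pytest.raises(UndefinedMetricError):
            quadratic_weighted_kappa(cm)

    def test_transpose_symmetry(self, rng):
        for _ in range(50):
            cm = random_confusion(rng, 5)
            assert quadratic_weighted_kappa(cm) == pytest.approx(
                quadratic_weighted_kappa(cm.T), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            t = random_score_table(rng, 120, 4)
            cm = confusion_matrix(t)
            assert quadratic_weighted_kappa(cm) == pytest.approx(
                skm.cohen_kappa_score(t.y_true, t.y_pred, labels=range(4), weights="quadratic"),
                abs=1e-12,
            )


class TestWeightedPRF:
    def test_perfect_diagonal(self):
        assert weighted_prf(np.diag([3, 1, 7])) == (1.0, 1.0, 1.0)

    def test_unpredicted_class_contributes_zero_precision(self):
        cm = np.array([[5, 0], [3, 0]])  # class 1 never predicted
        p, r, f = weighted_prf(cm)
        oracle = prf_oracle(cm)
        assert (p, r, f) == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            t = random_score_table(rng, 150, 5)
            p, r, f = weighted_prf(confusion_matrix(t))
            sp, sr, sf, _ = skm.precision_recall_fscore_support(
                t.y_true, t.y_pred, labels=range(5), average="weighted", zero_division=0
            )
            assert (p, r, f) == pytest.approx((sp, sr, sf), abs=1e-12)


class TestMCC:
    def test_perfect_diagonal(self):
        assert multiclass_mcc(np.diag([4, 2, 9])) == pytest.approx(1.0)

    def test_uniform_matrix_is_zero(self):
        assert multiclass_mcc(np.full((4, 4), 3)) == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_returns_zero(self):
        cm = np.array([[5, 0], [5, 0]])  # all predictions in one class
        assert multiclass_mcc(cm) == 0.0

    def test_binary_matches_textbook_formula(self, rng):
        for _ in range(200):
            cm = random_confusion(rng, 2)
            assert multiclass_mcc(cm) == pytest.approx(binary_mcc_oracle(cm), abs=1e-12)

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            t = random_score_table(rng, 100, 3)
            assert multiclass_mcc(confusion_matrix(t)) == pytest.approx(
                skm.matthews_corrcoef(t.y_true, t.y_pred), abs=1e-12
            )


class TestPairwiseAUROC:
    def test_perfectly_separated(self):
        y = np.repeat(np.arange(4), 5)
        t = ScoreTable(ids=np.arange(20), y_true=y, scores=np.eye(4)[y])
        assert pairwise_average_auroc(t) == 1.0

    def test_all_ties_give_half(self):
        t = ScoreTable(
            ids=np.arange(10),
            y_true=np.repeat([0, 1], 5),
            scores=np.ones((10, 2)),
        )
        assert pairwise_average_auroc(t) == 0.5

    def test_single_class_undefined(self):
        t = ScoreTable(ids=[0, 1], y_true=[1, 1], scores=np.ones((2, 3)))
        with pytest.raises(UndefinedMetricError):
            pairwise_average_auroc(t)

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(40):
            K = rng.choice([2, 3, 5])
            t = random_score_table(rng, int(rng.integers(10, 60)), int(K))
            assert pairwise_average_auroc(t) == pytest.approx(
                auroc_oracle(t), abs=1e-12
            )

    def test_matches_sklearn_hand_till(self, rng):
        for _ in range(10):
            t = random_score_table(rng, 80, 4)
            if len(np.unique(t.y_true)) < 4:
                continue
            probs = t.scores / t.scores.sum(axis=1, keepdims=True)
            tp = ScoreTable(ids=t.ids, y_true=t.y_true, scores=probs)
            assert pairwise_average_auroc(tp) == pytest.approx(
                skm.roc_auc_score(t.y_true, probs, multi_class="ovo", average="macro"),
                abs=1e-10,
            )


class TestGlobalInvariances:
    """Protocol-wide invariants on random score tables."""

    def test_oracle_equivalence_suite(self, rng):
        """All four metric families match their definitional oracles on
        many random instances across K in {2, 3, 5}."""
        checked = 0
        for _ in range(220):
            K = int(rng.choice([2, 3, 5]))
            n = int(rng.integers(10, 200))
            t = random_score_table(rng, n, K)
            cm = confusion_matrix(t)
            assert quadratic_weighted_kappa(cm) == pytest.approx(kappa_oracle(cm), abs=1e-12)
            assert weighted_prf(cm) == pytest.approx(prf_oracle(cm), abs=1e-12)
            if K == 2:
                assert multiclass_mcc(cm) == pytest.approx(binary_mcc_oracle(cm), abs=1e-12)
            checked += 1
        assert checked >= 200

    def test_duplication_leaves_metrics_unchanged(self, rng):
        t = random_score_table(rng, 50, 5)
        d = t.subset(np.concatenate([np.arange(50), np.arange(50)]))
        cm, cmd = confusion_matrix(t), confusion_matrix(d)
        assert quadratic_weighted_kappa(cm) == pytest.approx(
            quadratic_weighted_kappa(cmd), abs=1e-12
        )
        assert multiclass_mcc(cm) == pytest.approx(multiclass_mcc(cmd), abs=1e-12)
        assert weighted_prf(cm) == pytest.approx(weighted_prf(cmd), abs=1e-12)
        assert pairwise_average_auroc(t) == pytest.approx(
            pairwise_average_auroc(d), abs=1e-12
        )

    def test_permutation_invariance(self, rng):
        t = random_score_table(rng, 70, 3)
        p = t.subset(rng.permutation(70))
        assert pairwise_average_auroc(t) == pytest.approx(
            pairwise_average_auroc(p), abs=1e-12
        )
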