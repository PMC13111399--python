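"""Metric arithmetic, McNemar, MEREC and TOPSIS against hand computations
and third-party oracles."""

import numpy as np
import pytest

from roughns import (
    DecisionMatrixMCDM,
    ValidationError,
    classification_metrics,
    confusion_counts,
    mcnemar_test,
    merec_weights,
    topsis_rank,
)


class TestConfusionCounts:
    def test_hand_case(self):
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        c = confusion_counts(y_true, y_pred)
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 1, 1, 5)

    def test_perfect_predictions(self):
        c = confusion_counts([0, 1, 0], [0, 1, 0])
        assert c.fp == 0 and c.fn == 0

    def test_all_positive_on_all_negative_truth(self):
        c = confusion_counts([0, 0, 0], [1, 1, 1], classes=[0, 1])
        assert c.tp == 0 and c.tn == 0 and c.fp == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts([0, 1], [0])


class TestMetrics:
    def test_table_formula_hand_case(self):
        c = confusion_counts(
            [1, 1, 1, 1, 0, 0, 0, 0, 0, 0], [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        )
        m = classification_metrics(c)
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_perfect_gives_all_ones(self):
        m = classification_metrics(confusion_counts([0, 1] * 5, [0, 1] * 5))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_zero_tp_with_fp_gives_zero_precision_and_f1(self):
        m = classification_metrics(
            confusion_counts([0, 0, 1], [1, 0, 0], classes=[0, 1])
        )
        assert m.precision == 0.0 and m.f1 == 0.0

    def test_f1_below_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y_true = rng.integers(0, 2, 30)
            y_pred = rng.integers(0, 2, 30)
            m = classification_metrics(confusion_counts(y_true, y_pred, classes=[0, 1]))
            assert m.f1 <= (m.precision + m.recall) / 2 + 1e-12

    def test_weighted_multiclass_agrees_with_sklearn(self):
        from sklearn.metrics import precision_score, recall_score

        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        m = classification_metrics(confusion_counts(y_true, y_pred))
        assert m.precision == pytest.approx(
            precision_score(y_true, y_pred, average="weighted", zero_division=0)
        )
        assert m.recall == pytest.approx(
            recall_score(y_true, y_pred, average="weighted", zero_division=0)
        )


class TestMcNemar:
    def _vectors(self, b, c, both_right=30, both_wrong=5):
        """Construct prediction vectors realising given discordant counts."""
        y, a, p = [], [], []
        for _ in range(both_right):
            y.append(1); a.append(1); p.append(1)
        for _ in range(both_wrong):
            y.append(1); a.append(0); p.append(0)
        for _ in range(b):  # A right, B wrong
            y.append(1); a.append(1); p.append(0)
        for _ in range(c):  # A wrong, B right
            y.append(1); a.append(0); p.append(1)
        return np.array(y), np.array(a), np.array(p)

    def test_identical_classifiers(self):
        y, a, _ = self._vectors(0, 0)
        res = mcnemar_test(y, a, a)
        assert res.b == 0 and res.c == 0 and res.p_value == 1.0 and res.undefined

    def test_hand_case_without_correction(self):
        y, a, p = self._vectors(10, 2)
        res = mcnemar_test(y, a, p, correction=False)
        assert res.chi2 == pytest.approx(64 / 12)

    def test_hand_case_with_correction(self):
        y, a, p = self._vectors(10, 2)
        res = mcnemar_test(y, a, p, correction=True)
        assert res.chi2 == pytest.approx(49 / 12)
        assert res.exact  # b + c = 12 < 25 switches to the binomial branch

    def test_symmetric_under_swapping_classifiers(self):
        y, a, p = self._vectors(10, 2)
        r1 = mcnemar_test(y, a, p)
        r2 = mcnemar_test(y, p, a)
        assert r1.chi2 == pytest.approx(r2.chi2)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_p_decreases_with_imbalance_at_fixed_total(self):
        ps = []
        for b in (16, 20, 24, 28):
            y, a, p = self._vectors(b, 32 - b)
            ps.append(mcnemar_test(y, a, p).p_value)
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_agrees_with_statsmodels_large_counts(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        y, a, p = self._vectors(40, 15)
        res = mcnemar_test(y, a, p, correction=True)
        table = [[0, res.b], [res.c, 0]]
        ref = sm_mcnemar(table, exact=False, correction=True)
        assert res.chi2 == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_exact_branch_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        y, a, p = self._vectors(10, 2)
        res = mcnemar_test(y, a, p)
        ref = sm_mcnemar([[0, 10], [2, 0]], exact=True)
        assert res.p_value == pytest.approx(float(ref.pvalue))


class TestMEREC:
    def test_identical_alternatives_give_uniform_weights(self):
        dm = DecisionMatrixMCDM(["m1", "m2"], ["acc", "f1"], [[0.9, 0.8], [0.9, 0.8]])
        assert np.allclose(merec_weights(dm), [0.5, 0.5])

    def test_constant_best_column_has_zero_effect(self):
        # h = 1 for every alternative in column 0, so removing it changes
        # nothing and its weight is 0
        dm = DecisionMatrixMCDM(["m1", "m2"], ["c0", "c1"], [[0.7, 0.9], [0.7, 0.5]])
        w = merec_weights(dm)
        assert w[0] == pytest.approx(0.0)
        assert w[1] == pytest.approx(1.0)

    def test_symmetric_matrix_gives_equal_weights(self):
        dm = DecisionMatrixMCDM(["m1", "m2"], ["c0", "c1"], [[1.0, 2.0], [2.0, 1.0]])
        assert np.allclose(merec_weights(dm), [0.5, 0.5])

    def test_weights_nonnegative_sum_one_and_row_permutation_invariant(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.1, 1.0, size=(5, 4))
        dm = DecisionMatrixMCDM([f"m{i}" for i in range(5)], [f"c{j}" for j in range(4)], X)
        w = merec_weights(dm)
        assert np.all(w >= 0) and w.sum() == pytest.approx(1.0)
        perm = rng.permutation(5)
        dm2 = DecisionMatrixMCDM([f"m{i}" for i in perm], [f"c{j}" for j in range(4)], X[perm])
        assert np.allclose(merec_weights(dm2), w)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.1, 1.0, size=(4, 3))
        dm = DecisionMatrixMCDM(["a", "b", "c", "d"], ["x", "y", "z"], X)
        w = merec_weights(dm)
        perm = [2, 0, 1]
        dm2 = DecisionMatrixMCDM(["a", "b", "c", "d"], ["z", "x", "y"], X[:, perm])
        assert np.allclose(merec_weights(dm2), w[perm])

    def test_nonpositive_cell_rejected(self):
        dm = DecisionMatrixMCDM(["m1", "m2"], ["c0"], [[0.5], [0.0]])
        with pytest.raises(ValidationError):
            merec_weights(dm)


class TestTOPSIS:
    def test_dominating_pair_hand_case(self):
        dm = DecisionMatrixMCDM(
            ["best", "worst"], ["c0", "c1"], [[3.0, 4.0], [1.0, 2.0]],
            weights=np.array([0.5, 0.5]),
        )
        closeness, order = topsis_rank(dm)
        assert closeness[0] == pytest.approx(1.0)
        assert closeness[1] == pytest.approx(0.0)
        assert order.tolist() == [0, 1]

    def test_identical_alternatives_tie_with_warning(self):
        dm = DecisionMatrixMCDM(
            ["m1", "m2"], ["c0", "c1"], [[0.9, 0.8], [0.9, 0.8]],
            weights=np.array([0.5, 0.5]),
        )
        with pytest.warns(UserWarning):
            closeness, _ = topsis_rank(dm)
        assert closeness[0] == closeness[1] == 0.5

    def test_single_criterion_ranking_is_sorting(self):
        dm = DecisionMatrixMCDM(
            ["m1", "m2", "m3"], ["acc"], [[0.7], [0.95], [0.8]],
            weights=np.array([1.0]),
        )
        _, order = topsis_rank(dm)
        assert order.tolist() == [1, 2, 0]

    def test_closeness_bounded_and_dominated_add_preserves_order(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0.5, 1.0, size=(4, 3))
        w = np.array([0.2, 0.3, 0.5])
        dm = DecisionMatrixMCDM([f"m{i}" for i in range(4)], ["a", "b", "c"], X, weights=w)
        closeness, _ = topsis_rank(dm)
        assert np.all((0 <= closeness) & (closeness <= 1))

    def test_bad_weights_rejected(self):
        dm = DecisionMatrixMCDM(
            ["m1", "m2"], ["c0"], [[1.0], [2.0]], weights=np.array([0.7])
        )
        with pytest.raises(ValidationError):
            topsis_rank(dm)
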