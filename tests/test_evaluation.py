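"""Splits, metrics, ROC/AUC, the DeLong test, and the CV harness."""

import numpy as np
import pytest

from attbiomarker.evaluation import (
    AttCnnAdapter,
    SklearnAdapter,
    binary_metrics,
    compare_classifiers,
    crossval_evaluate,
    delong_test,
    make_split_plan,
    roc_auc,
    stratified_holdout,
    stratified_kfold,
)

from conftest import make_matrix


def pair_counting_auc(y, s):
    """Exhaustive pair ordering with ties counted one half."""
    pos = s[y == 1]
    neg = s[y == 0]
    total = correct = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                correct += 1
            elif a == b:
                correct += 0.5
    return correct / total


class TestSplits:
    def test_holdout_proportions(self):
        y = np.array([0] * 10 + [1] * 10)
        tr, te = stratified_holdout(y, 0.2, seed=0)
        assert (y[te] == 1).sum() == 2 and (y[te] == 0).sum() == 2
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == 20

    def test_holdout_deterministic(self):
        y = np.array([0] * 9 + [1] * 7)
        a = stratified_holdout(y, 0.25, seed=5)
        b = stratified_holdout(y, 0.25, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_holdout_rounds_half_to_even(self):
        # 3 per class at fraction 0.5: round(1.5) = 2 test samples per class
        y = np.array([0, 0, 0, 1, 1, 1])
        tr, te = stratified_holdout(y, 0.5, seed=1)
        assert (y[te] == 0).sum() == 2 and (y[te] == 1).sum() == 2

    def test_holdout_class_vanishing_errors(self):
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="absent from one partition"):
            stratified_holdout(y, 0.05, seed=0)

    def test_kfold_balanced_partition(self):
        y = np.array([0] * 25 + [1] * 25)
        folds = stratified_kfold(y, k=5, seed=0)
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == list(range(50))
        for tr, va in folds:
            assert (y[va] == 0).sum() == 5 and (y[va] == 1).sum() == 5
            assert len(set(tr) & set(va)) == 0

    def test_kfold_class_smaller_than_k_errors(self):
        y = np.array([0] * 3 + [1] * 10)
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_kfold(y, k=5, seed=0)

    def test_split_plan_stratification_property(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 97)
        plan = make_split_plan(y, 0.2, k=5, seed=3)
        global_ratio = y[plan.train_indices].mean()
        fold_union = np.concatenate([va for _, va in plan.folds])
        assert sorted(fold_union) == sorted(plan.train_indices)
        for _, va in plan.folds:
            # per-fold class count within 1 sample of proportional share
            assert abs((y[va] == 1).sum() - global_ratio * len(va)) <= 1


class TestBinaryMetrics:
    def test_perfect_probabilities(self):
        y = np.array([0, 0, 1, 1])
        row = binary_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert (row.auc, row.acc, row.f1, row.pre, row.rec) == (1, 1, 1, 1, 1)

    def test_threshold_tie_predicts_positive(self):
        y = np.array([0, 1])
        row = binary_metrics(y, np.array([0.5, 0.5]))
        # both predicted positive: acc 0.5, recall 1, precision 0.5
        assert row.acc == 0.5 and row.rec == 1.0 and row.pre == 0.5

    def test_hand_counted_confusion(self):
        # TP=3 FP=1 FN=2 TN=4
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        prob = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2, 0.1, 0.05])
        row = binary_metrics(y, prob)
        assert row.pre == pytest.approx(0.75)
        assert row.rec == pytest.approx(0.6)
        assert row.f1 == pytest.approx(2 / 3)
        assert row.acc == pytest.approx(0.7)

    def test_single_class_auc_nan_other_metrics_kept(self):
        with pytest.warns(UserWarning, match="AUC undefined"):
            row = binary_metrics(np.array([1, 1]), np.array([0.9, 0.2]))
        assert np.isnan(row.auc)
        assert row.rec == 0.5


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0, 0, 1, 1]), np.array([1, 2, 3, 4])) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc(np.array([0, 1, 0, 1]), np.ones(4)) == 0.5

    def test_three_of_four_pairs_ordered(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.4, 0.5, 0.1])
        assert roc_auc(y, s) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.ones(4), np.arange(4))

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        y = np.zeros(n, dtype=int)
        y[: max(1, n // 3)] = 1
        rng.shuffle(y)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        s = np.round(rng.normal(size=n), 1)  # rounding forces ties
        assert roc_auc(y, s) == pytest.approx(pair_counting_auc(y, s), abs=1e-12)


class TestDeLong:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 15)
        s = rng.normal(size=30)
        res = delong_test(y, s, s)
        assert res.delta_auc == 0 and res.z == 0 and res.p == 1

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        a = rng.normal(size=40) + 0.5 * y
        b = rng.normal(size=40) + 0.3 * y
        ab = delong_test(y, a, b)
        ba = delong_test(y, b, a)
        assert ab.delta_auc == pytest.approx(-ba.delta_auc, abs=1e-15)
        assert ab.z**2 == pytest.approx(ba.z**2, rel=1e-12)
        assert ab.p == pytest.approx(ba.p, abs=1e-12)

    def test_p_matches_bootstrap_null_on_small_case(self):
        """Stratified-bootstrap reference distribution of dAUC under the
        null of equal AUCs (score-pair resampling preserves correlation)."""
        rng = np.random.default_rng(2)
        n = 30
        y = np.repeat([0, 1], n // 2)
        signal = rng.normal(size=n) + 1.0 * y
        a = signal + rng.normal(scale=0.8, size=n)
        b = signal + rng.normal(scale=0.8, size=n)
        observed = delong_test(y, a, b)

        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        reps = 10_000
        deltas = np.empty(reps)
        for r in range(reps):
            idx = np.concatenate(
                [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
            )
            deltas[r] = roc_auc(y[idx], a[idx]) - roc_auc(y[idx], b[idx])
        centered = deltas - deltas.mean()
        p_boot = float((np.abs(centered) >= abs(observed.delta_auc)).mean())
        assert observed.p == pytest.approx(p_boot, abs=0.02)

    def test_degenerate_variance_with_nonzero_delta_errors(self):
        y = np.array([0, 0, 1, 1])
        a = np.array([0.0, 0.0, 1.0, 1.0])
        b = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate variance"):
            delong_test(y, a, b)


class _StubModel:
    """Deterministic probability = min-max scaled value of one gene."""

    def __init__(self, gene=0):
        self.gene = gene

    def fit(self, X, y):
        self.lo = X[:, self.gene].min()
        self.hi = X[:, self.gene].max()
        return self

    def predict_proba_1d(self, X):
        span = self.hi - self.lo or 1.0
        return np.clip((X[:, self.gene] - self.lo) / span, 0.0, 1.0)


class TestCrossvalHarness:
    def test_stub_model_report_matches_manual_evaluation(self, random_labeled_matrix):
        m = random_labeled_matrix
        plan = make_split_plan(m.labels, seed=0)
        rep = crossval_evaluate(lambda s: _StubModel(), m, plan)
        for row, (tr, va) in zip(rep.per_fold, plan.folds):
            stub = _StubModel().fit(m.values[tr], m.labels[tr])
            manual = binary_metrics(m.labels[va], stub.predict_proba_1d(m.values[va]))
            assert row.auc == manual.auc and row.acc == manual.acc
        assert rep.test_set.auc > 0.8  # gene 0 is informative

    def test_label_independent_scores_near_chance(self):
        rng = np.random.default_rng(10)
        y = np.repeat([0, 1], 100)
        X = rng.normal(size=(200, 5))
        m = make_matrix(X, y)
        plan = make_split_plan(y, seed=1)
        rep = crossval_evaluate(lambda s: _StubModel(gene=2), m, plan)
        assert 0.35 <= rep.aggregate["auc"]["mean"] <= 0.65

    def test_single_classifier_table_matches_crossval(self, random_labeled_matrix):
        m = random_labeled_matrix
        plan = make_split_plan(m.labels, seed=0)
        reports, pairwise = compare_classifiers(m, plan, {"stub": lambda s: _StubModel()})
        solo = crossval_evaluate(lambda s: _StubModel(), m, plan)
        assert reports["stub"].test_set.auc == solo.test_set.auc
        assert pairwise == []

    def test_identical_classifiers_have_delong_p_one(self, random_labeled_matrix):
        m = random_labeled_matrix
        plan = make_split_plan(m.labels, seed=0)
        reports, pairwise = compare_classifiers(
            m, plan, {"a": lambda s: _StubModel(), "b": lambda s: _StubModel()}
        )
        assert len(pairwise) == 1
        assert pairwise[0]["p"] == 1.0 and pairwise[0]["delta_auc"] == 0.0

    def test_failing_classifier_recorded_others_continue(self, random_labeled_matrix):
        class Broken:
            def fit(self, X, y):
                raise RuntimeError("boom")

        m = random_labeled_matrix
        plan = make_split_plan(m.labels, seed=0)
        reports, pairwise = compare_classifiers(
            m, plan, {"ok": lambda s: _StubModel(), "bad": lambda s: Broken()}
        )
        assert "ok" in reports and "bad" not in reports
        assert any("error" in row for row in pairwise)

    def test_sklearn_adapter_round_trip(self, random_labeled_matrix):
        from sklearn.linear_model import LogisticRegression

        m = random_labeled_matrix
        plan = make_split_plan(m.labels, seed=0)
        rep = crossval_evaluate(
            lambda s: SklearnAdapter(LogisticRegression(max_iter=500)), m, plan
        )
        assert rep.test_set.auc > 0.7
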