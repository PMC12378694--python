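"""Split arithmetic, scaling modes, grid search, SVM vs QP oracle, metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from ccepflow.cohort import generate_feature_cohort
from ccepflow.config import CohortConfig, ModelConfig
from ccepflow.errors import InvalidInputError, StratificationError
from ccepflow.model import (
    cross_validate_final,
    evaluate,
    fit_linear_svm,
    grid_search_c,
    split_cohort,
    standardize,
)
from ccepflow.targets import ClinicalParams, FeatureTargets


def svm_qp_oracle(X, y01, c):
    """Brute-force primal soft-margin SVM via constrained optimization."""
    X = np.asarray(X, dtype=float)
    y = 2.0 * np.asarray(y01) - 1.0
    n, d = X.shape

    def objective(wb):
        w, b = wb[:d], wb[d]
        margins = 1.0 - y * (X @ w + b)
        return 0.5 * w @ w + c * np.maximum(margins, 0.0).sum()

    best = None
    for s in range(4):  # multistart: hinge loss is convex but kink-y for SLSQP
        x0 = np.zeros(d + 1) if s == 0 else np.random.default_rng(s).normal(size=d + 1)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:d], best.x[d]


class TestSplit:
    def test_cohort_56_splits_42_14_with_23_19(self):
        y = np.array([0] * 30 + [1] * 26)  # 0 = SF, 1 = nSF
        cfg = ModelConfig()
        train, test = split_cohort(y, cfg, seed=5)
        assert len(train) == 42 and len(test) == 14
        assert (y[train] == 0).sum() == 23 and (y[train] == 1).sum() == 19
        assert (y[test] == 0).sum() == 7 and (y[test] == 1).sum() == 7
        assert set(train).isdisjoint(test)
        assert len(set(train) | set(test)) == 56

    def test_balanced_8_splits_6_2(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        train, test = split_cohort(y, ModelConfig(), seed=1)
        assert len(train) == 6 and len(test) == 2
        assert (y[train] == 0).sum() == 3 and (y[test] == 1).sum() == 1

    def test_deterministic_given_seed(self):
        y = np.array([0] * 30 + [1] * 26)
        a = split_cohort(y, ModelConfig(), seed=9)
        b = split_cohort(y, ModelConfig(), seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_small_class_rejected(self):
        with pytest.raises(StratificationError):
            split_cohort(np.array([0] * 10 + [1] * 3), ModelConfig(), seed=0)


class TestStandardize:
    def _frames(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 4)), columns=list("abcd"))
        return df.iloc[:30], df.iloc[30:]

    def test_train_only_mode(self):
        train, test = self._frames()
        tr, te, _ = standardize(train, test, mode="train-only")
        np.testing.assert_allclose(tr.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(tr.std(ddof=1), 1, atol=1e-12)
        assert abs(te.mean()).max() > 1e-6  # test stats not forced to zero

    def test_study_literal_pools_before_scaling(self):
        train, test = self._frames()
        tr, te, _ = standardize(train, test, mode="study-literal")
        pooled = pd.concat([tr, te])
        np.testing.assert_allclose(pooled.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(pooled.std(ddof=1), 1, atol=1e-12)

    def test_constant_column_passed_through(self):
        train, test = self._frames()
        train = train.assign(const=1.0)
        test = test.assign(const=1.0)
        with pytest.warns(UserWarning, match="const"):
            tr, te, scaler = standardize(train, test)
        assert (tr["const"] == 1.0).all()
        assert "const" in scaler.constant_columns


class TestGridSearch:
    def test_separable_data_ties_break_to_smallest_c(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(np.r_[rng.normal(-4, 0.2, (15, 2)), rng.normal(4, 0.2, (15, 2))])
        y = np.array([0] * 15 + [1] * 15)
        best_c, grid, _ = grid_search_c(X, y, ModelConfig(), seed=0)
        assert grid["cv_accuracy"].nunique() == 1  # every C perfect
        assert best_c == 0.01

    def test_grid_times_folds_models(self):
        calls = []
        import ccepflow.model as m

        orig = m.fit_linear_svm
        try:
            m.fit_linear_svm = lambda X, y, c: calls.append(c) or orig(X, y, c)
            rng = np.random.default_rng(4)
            X = pd.DataFrame(rng.normal(size=(30, 3)))
            y = np.array([0, 1] * 15)
            grid_search_c(X, y, ModelConfig(), seed=0)
        finally:
            m.fit_linear_svm = orig
        assert len(calls) == 25  # 5 C values x 5 folds

    def test_single_element_grid(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        y = np.array([0, 1] * 10)
        best_c, grid, _ = grid_search_c(X, y, ModelConfig(c_grid=(3.5,)), seed=0)
        assert best_c == 3.5 and len(grid) == 1


class TestLinearSvm:
    def test_two_point_symmetry(self):
        X = np.array([[-1.0], [1.0]])
        w, b, f = fit_linear_svm(X, np.array([0, 1]), c=100.0)
        assert w[0] > 0
        assert abs(b) <= 1e-6

    def test_label_flip_negates_solution(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 3))
        y = np.array([0, 1] * 6)
        w1, b1, _ = fit_linear_svm(X, y, c=1.0)
        w2, b2, _ = fit_linear_svm(X, 1 - y, c=1.0)
        np.testing.assert_allclose(w1, -w2, atol=1e-5)
        assert b1 == pytest.approx(-b2, abs=1e-5)

    @pytest.mark.parametrize("c", [0.5, 5.0])
    def test_matches_qp_oracle_on_toy_sets(self, c):
        X = np.array([[0.0, 0.0], [0.4, 0.8], [2.0, 2.0], [1.8, 1.0], [0.2, 1.9], [2.2, 0.1]])
        y = np.array([0, 0, 1, 1, 0, 1])
        w, b, _ = fit_linear_svm(X, y, c)
        w_qp, b_qp = svm_qp_oracle(X, y, c)
        np.testing.assert_allclose(w, w_qp, atol=1e-3)
        assert b == pytest.approx(b_qp, abs=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_linear_svm(np.zeros((4, 2)), np.zeros(4), 1.0)


class TestEvaluate:
    def test_perfect_classifier(self):
        y = np.array([0, 0, 1, 1])
        m = evaluate(np.array([-2.0, -1.0, 1.0, 2.0]), y)
        for k in ("accuracy", "sensitivity", "specificity", "f1", "auc"):
            assert m[k] == 1.0
        assert m["roc"][0].tolist() == [0.0, 0.0]
        assert m["roc"][-1].tolist() == [1.0, 1.0]

    def test_known_confusion_matrix(self):
        # TP=5 FN=2 FP=1 TN=6
        y = np.array([1] * 7 + [0] * 7)
        scores = np.array([1.0] * 5 + [-1.0] * 2 + [1.0] * 1 + [-1.0] * 6)
        m = evaluate(scores, y)
        np.testing.assert_array_equal(m["confusion"], [[6, 1], [2, 5]])
        assert m["accuracy"] == pytest.approx(11 / 14)
        assert m["sensitivity"] == pytest.approx(5 / 7)
        assert m["specificity"] == pytest.approx(6 / 7)
        assert m["f1"] == pytest.approx(10 / 13)

    def test_metric_identities(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 60)
        s = rng.normal(size=60)
        m = evaluate(s, y)
        (tn, fp), (fn, tp) = m["confusion"]
        assert m["accuracy"] == pytest.approx((tp + tn) / 60)
        prec, rec = m["precision"], m["sensitivity"]
        if prec + rec > 0:
            assert m["f1"] == pytest.approx(2 * prec * rec / (prec + rec))

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(9)
        aucs = [
            evaluate(rng.normal(size=40), np.array([0, 1] * 20))["auc"]
            for _ in range(1000)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


@pytest.fixture(scope="module")
def table():
    return generate_feature_cohort(
        CohortConfig(), FeatureTargets.default(), ClinicalParams.default(), seed=0
    )


class TestCrossValidateFinal:

    def test_deterministic_given_seed(self, table):
        r1 = cross_validate_final(table, ModelConfig(), seed=3)
        r2 = cross_validate_final(table, ModelConfig(), seed=3)
        assert r1.best_c == r2.best_c
        np.testing.assert_array_equal(r1.train_index, r2.train_index)
        assert r1.cv_metrics == r2.cv_metrics
        assert r1.auc == r2.auc
        np.testing.assert_allclose(r1.weights, r2.weights)

    def test_partition_disjoint_exhaustive_and_confusion_sums(self, table):
        r = cross_validate_final(table, ModelConfig(), seed=4)
        assert set(r.train_index).isdisjoint(r.test_index)
        assert len(r.train_index) + len(r.test_index) == len(table)
        assert int(r.cv_confusion.sum()) == len(r.train_index)
        assert int(np.sum(r.test_metrics["confusion"])) == len(r.test_index)
        assert r.roc_points[0].tolist() == [0.0, 0.0]
        assert r.roc_points[-1].tolist() == [1.0, 1.0]

    def test_grid_search_never_touches_test_rows(self, table, monkeypatch):
        """Instrument the SVM fit: no training call may contain a test row."""
        import ccepflow.model as m

        seen = []
        orig = m.fit_linear_svm

        def spy(X, y, c):
            seen.append(np.asarray(X))
            return orig(X, y, c)

        monkeypatch.setattr(m, "fit_linear_svm", spy)
        for mode in ("train-only", "study-literal"):
            seen.clear()
            cfg = ModelConfig(leakage_mode=mode)
            r = cross_validate_final(table, cfg, seed=11)
            X = table[list(r.feature_names)]
            _, test_scaled, _ = standardize(
                X.iloc[r.train_index], X.iloc[r.test_index], mode=mode
            )
            test_rows = {tuple(np.round(row, 9)) for row in test_scaled.to_numpy()}
            for X_fit in seen:
                fitted = {tuple(np.round(row, 9)) for row in X_fit}
                assert not (fitted & test_rows)
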