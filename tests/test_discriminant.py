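"""From-scratch discriminant analysis: Wilks lambda, stepwise selection,
Fisher classification, LOO/holdout validation, VIF, PCA + varimax."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leukoflow.discriminant import (
    ConfigError,
    MulticollinearityError,
    fit_classifier,
    holdout_eval,
    loo_cv,
    nested_loo_cv,
    pca_varimax,
    stepwise_select,
    varimax_rotate,
    wilks_lambda,
)

from reference_impl import reference_wilks_lambda, svd_varimax


class TestWilksLambda:
    def test_identical_group_means_lambda_one(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])[:, None]
        labels = ["a"] * 3 + ["b"] * 3
        assert wilks_lambda(x, labels) == pytest.approx(1.0)

    def test_separated_groups_lambda_near_zero(self, rng):
        X = np.vstack([rng.normal(0, 1e-4, (10, 2)), rng.normal(10, 1e-4, (10, 2))])
        labels = ["a"] * 10 + ["b"] * 10
        assert wilks_lambda(X, labels) < 1e-6

    def test_matches_bruteforce_oracle_on_random_instances(self):
        """Property: lambda equals the explicit det-ratio computation."""
        for s in range(100):
            r = np.random.default_rng(s)
            X = r.normal(0, 1, (18, 4)) + np.repeat(r.normal(0, 1, (3, 4)), 6, axis=0)
            labels = np.repeat(["a", "b", "c"], 6)
            assert wilks_lambda(X, labels) == pytest.approx(
                reference_wilks_lambda(X, labels), abs=1e-10)

    def test_two_group_single_variable_t_identity(self, rng):
        """For 2 groups and 1 variable, lambda = 1 / (1 + t^2/(n-2))."""
        x1, x2 = rng.normal(0, 1, 12), rng.normal(1.0, 1, 9)
        lam = wilks_lambda(np.concatenate([x1, x2])[:, None],
                           ["a"] * 12 + ["b"] * 9)
        t, _ = stats.ttest_ind(x1, x2)
        n = 21
        assert lam == pytest.approx(1.0 / (1.0 + t**2 / (n - 2)), abs=1e-10)

    def test_singular_total_matrix_names_offenders(self, rng):
        x = rng.normal(0, 1, 12)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(0, 1, 12)})
        with pytest.raises(MulticollinearityError, match="b"):
            wilks_lambda(X, ["g1"] * 6 + ["g2"] * 6)


class TestStepwise:
    def test_planted_variable_recovered_first(self):
        hits = 0
        for s in range(40):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.normal(0, 1, (20, 10)),
                             columns=[f"v{i}" for i in range(10)])
            y = np.array(["a"] * 10 + ["b"] * 10)
            X["v3"] = r.normal(0, 1, 20) + np.where(y == "b", 3.0, 0.0)
            sel, trace = stepwise_select(X, y)
            hits += bool(sel and sel[0] == "v3")
            assert set(trace.columns) == {"step", "action", "variable",
                                          "wilks_lambda", "partial_F"}
        assert hits / 40 >= 0.95

    def test_duplicated_informative_variable_enters_once(self, rng):
        y = np.array(["a"] * 10 + ["b"] * 10)
        v = rng.normal(0, 1, 20) + np.where(y == "b", 3.0, 0.0)
        X = pd.DataFrame({"v1": v, "v2": v.copy(), "noise": rng.normal(0, 1, 20)})
        sel, _ = stepwise_select(X, y)
        assert sel.count("v1") + sel.count("v2") == 1

    def test_f_out_above_f_in_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (12, 3)))
        with pytest.raises(ConfigError):
            stepwise_select(X, ["a"] * 6 + ["b"] * 6, f_in=2.0, f_out=3.0)

    def test_first_entry_f_equals_anova_f(self, rng):
        """The F-to-enter of the first variable is the one-way ANOVA F."""
        X = pd.DataFrame({"v": np.concatenate([rng.normal(0, 1, 10),
                                               rng.normal(1.5, 1, 10)])})
        y = ["a"] * 10 + ["b"] * 10
        sel, trace = stepwise_select(X, y, f_in=0.01, f_out=0.005)
        F_ref, _ = stats.f_oneway(X["v"][:10], X["v"][10:])
        assert trace.loc[0, "partial_F"] == pytest.approx(F_ref, rel=1e-9)


class TestFitClassifier:
    def test_orthogonal_predictors_unit_vif(self):
        n = 16
        a = np.tile([1.0, -1.0], n // 2)
        b = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        X = pd.DataFrame({"a": a, "b": b})
        y = ["g1"] * (n // 2) + ["g2"] * (n // 2)
        model = fit_classifier(X, y)
        assert model.vif["a"] == pytest.approx(1.0, abs=1e-9)
        assert model.vif["b"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_predictor_raises(self, rng):
        x = rng.normal(0, 1, 14)
        X = pd.DataFrame({"a": x, "b": x.copy()})
        with pytest.raises(MulticollinearityError):
            fit_classifier(X, ["g1"] * 7 + ["g2"] * 7)

    def test_model_invariants(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("abcd"))
        y = np.repeat(["g1", "g2", "g3"], 10)
        X.loc[y == "g2", "a"] += 2.0
        model = fit_classifier(X, y)
        assert 0 <= model.wilks_lambda <= 1
        assert model.standardized_coefficients.shape == (4, 2)  # min(g-1, p)
        assert model.priors.sum() == pytest.approx(1.0)
        assert (model.vif >= 1 - 1e-9).all()

    def test_classification_invariant_under_affine_rescaling(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (24, 3)), columns=list("abc"))
        y = np.repeat(["g1", "g2"], 12)
        X.loc[y == "g2", "b"] += 1.5
        m0 = fit_classifier(X, y)
        X2 = X.copy()
        X2["b"] = X2["b"] * 37.0 - 5.0
        m2 = fit_classifier(X2, y)
        assert list(m0.classify(X)) == list(m2.classify(X2))

    def test_matches_sklearn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X = rng.normal(0, 1, (30, 3))
        y = np.repeat(["g1", "g2", "g3"], 10)
        X[y == "g1", 0] += 2.0
        X[y == "g3", 2] -= 2.0
        model = fit_classifier(pd.DataFrame(X, columns=list("abc")), y)
        clf = sklearn.LinearDiscriminantAnalysis(priors=[1 / 3] * 3,
                                                 store_covariance=True)
        clf.fit(X, y)
        assert list(model.classify(pd.DataFrame(X, columns=list("abc")))) \
            == list(clf.predict(X))

    def test_proportional_priors(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 15)})
        y = ["g1"] * 5 + ["g2"] * 10
        model = fit_classifier(X, y, priors="proportional")
        assert model.priors["g2"] == pytest.approx(2 / 3)


class TestValidation:
    def test_loo_perfect_on_separable_groups(self, rng):
        X = pd.DataFrame(np.vstack([rng.normal(0, 1, (10, 3)),
                                    rng.normal(6, 1, (10, 3))]),
                         columns=list("abc"))
        y = ["g1"] * 10 + ["g2"] * 10
        res = loo_cv(X, y, list("abc"))
        assert res.overall_accuracy == 100.0
        assert list(res.confusion.sum(axis=1)) == [10, 10]

    def test_loo_chance_level_under_permutation(self):
        """Label permutation: mean LOO accuracy sits at chance (50 +- 15%)."""
        accs = []
        for s in range(60):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.normal(0, 1, (20, 3)), columns=list("abc"))
            y = r.permutation(["g1"] * 10 + ["g2"] * 10)
            accs.append(loo_cv(X, y, list("abc")).overall_accuracy)
        assert np.mean(accs) == pytest.approx(50.0, abs=15.0)

    def test_loo_minimal_three_per_group(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 6)})
        y = ["g1"] * 3 + ["g2"] * 3
        res = loo_cv(X, y, ["a"])
        assert list(res.confusion.sum(axis=1)) == [3, 3]

    def test_nested_loo_not_more_optimistic(self, rng):
        """Honest nested selection can only be as good or worse on null data."""
        X = pd.DataFrame(rng.normal(0, 1, (20, 5)),
                         columns=[f"v{i}" for i in range(5)])
        y = ["g1"] * 10 + ["g2"] * 10
        nested = nested_loo_cv(X, y)
        assert 0.0 <= nested.overall_accuracy <= 100.0

    def test_holdout_from_training_distribution(self, rng):
        X = pd.DataFrame(np.vstack([rng.normal(0, 1, (12, 2)),
                                    rng.normal(8, 1, (12, 2))]),
                         columns=list("ab"))
        y = np.array(["g1"] * 12 + ["g2"] * 12)
        train = list(range(0, 8)) + list(range(12, 20))
        test = list(range(8, 12)) + list(range(20, 24))
        res = holdout_eval(X, y, train, test, list("ab"))
        assert res.overall_accuracy == 100.0

    def test_holdout_centroid_goes_to_its_group(self, rng):
        X = pd.DataFrame(np.vstack([rng.normal(0, 1, (8, 2)),
                                    rng.normal(5, 1, (8, 2))]), columns=list("ab"))
        y = np.array(["g1"] * 8 + ["g2"] * 8)
        centroid = X.iloc[:8].mean().to_frame().T
        X2 = pd.concat([X, centroid], ignore_index=True)
        y2 = np.append(y, "g1")
        res = holdout_eval(X2, y2, list(range(16)), [16], list("ab"))
        assert res.predictions.iloc[0] == "g1"

    def test_holdout_empty_test_set(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 8)})
        y = ["g1"] * 4 + ["g2"] * 4
        res = holdout_eval(X, y, list(range(8)), [], ["a"])
        assert len(res.predictions) == 0

    def test_holdout_unseen_group_refused(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 9)})
        y = np.array(["g1"] * 4 + ["g2"] * 4 + ["g3"])
        res = holdout_eval(X, y, list(range(8)), [8], ["a"])
        assert res.skipped == [8]

    def test_overlapping_train_test_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 8)})
        y = ["g1"] * 4 + ["g2"] * 4
        with pytest.raises(ValueError):
            holdout_eval(X, y, [0, 1, 2, 3, 4, 5], [5, 6, 7], ["a"])


class TestPCAVarimax:
    def test_independent_variables_isotropic(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (3000, 5)))
        res = pca_varimax(X)
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=0.15)
        np.testing.assert_allclose(res.percent_variance, 20.0, atol=3.0)

    def test_rank_one_structure(self, rng):
        x = rng.normal(0, 1, 50)
        X = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = pca_varimax(X)
        np.testing.assert_allclose(res.eigenvalues, [2.0, 0.0], atol=1e-9)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_eigenvalue_sum_equals_dimension(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (40, 7)))
        res = pca_varimax(X)
        assert res.eigenvalues.sum() == pytest.approx(7.0)
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_varimax_matches_independent_svd_routine(self, rng):
        """Pairwise-rotation varimax agrees with the SVD algorithm up to
        column order and sign."""
        X = rng.normal(0, 1, (80, 10))
        X[:, 1] = X[:, 0] * 0.8 + X[:, 1] * 0.2
        X[:, 5] = X[:, 4] * 0.7 + X[:, 5] * 0.3
        res = pca_varimax(pd.DataFrame(X))
        L = res.loadings.loc[:, res.retained].to_numpy()
        got = varimax_rotate(L)
        ref = svd_varimax(L)
        # align columns by absolute correlation, then fix signs
        for k in range(got.shape[1]):
            sims = [abs(got[:, k] @ ref[:, j]) for j in range(ref.shape[1])]
            j = int(np.argmax(sims))
            r = ref[:, j] * np.sign(got[:, k] @ ref[:, j])
            np.testing.assert_allclose(got[:, k], r, atol=1e-5)

    def test_constant_column_dropped(self, rng, caplog):
        X = pd.DataFrame({"a": rng.normal(0, 1, 20), "b": np.ones(20),
                          "c": rng.normal(0, 1, 20)})
        with caplog.at_level("WARNING"):
            res = pca_varimax(X)
        assert res.dropped_variables == ["b"]
        assert list(res.loadings.index) == ["a", "c"]
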