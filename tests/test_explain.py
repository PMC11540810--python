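"""Explainability: exact Shapley values, permutation importance, correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from thumbrom import (
    ModelSpec,
    UndefinedStatisticError,
    ValidationError,
    correlation_matrix,
    exact_shapley,
    fit_model,
    permutation_importance,
    shap_summary,
)
from thumbrom.features import FEATURE_NAMES


def ordering_oracle_shapley(predict_fn, instance, background):
    """Average marginal contribution over all k! feature orderings.

    Independent enumeration strategy: for each ordering, add features one at
    a time (marginal/interventional value function, plain loops).
    """
    instance = np.asarray(instance, dtype=float)
    background = np.asarray(background, dtype=float)
    k = len(instance)

    def value(subset):
        total = 0.0
        for row in background:
            x = row.copy()
            for j in subset:
                x[j] = instance[j]
            total += float(predict_fn(x.reshape(1, -1))[0])
        return total / len(background)

    phi = np.zeros(k)
    orderings = list(itertools.permutations(range(k)))
    for order in orderings:
        present = []
        v_prev = value(present)
        for f in order:
            present.append(f)
            v_now = value(present)
            phi[f] += v_now - v_prev
            v_prev = v_now
    return phi / len(orderings)


class TestExactShapley:
    def test_linear_model_closed_form(self, rng):
        w = np.array([2.0, 3.0, 0.0, -1.5])
        model = lambda X: X @ w
        background = rng.normal(size=(40, 4))
        instance = np.array([1.0, 1.0, 5.0, -2.0])
        sv = exact_shapley(model, instance, background)
        expected = w * (instance - background.mean(axis=0))
        np.testing.assert_allclose(sv.phi.to_numpy(), expected, atol=1e-9)
        assert sv.base_value == pytest.approx(background.mean(axis=0) @ w)

    def test_efficiency_for_tree_model(self, rng):
        X = pd.DataFrame(rng.random((150, 7)) * 50, columns=FEATURE_NAMES)
        y = X["tip_joint_angle"] * 0.8 + X["palmsize2"] * 10 + rng.normal(0, 1, 150)
        model = fit_model(ModelSpec("random_forest"), X, y, seed=0)
        for i in range(5):
            sv = exact_shapley(model, X.iloc[i], X.iloc[50:120])
            assert sv.base_value + sv.phi.sum() == pytest.approx(sv.prediction,
                                                                 abs=1e-6)

    def test_symmetric_features_get_equal_attribution(self, rng):
        model = lambda X: X[:, 0] + X[:, 1]  # exchangeable pair
        background = np.zeros((10, 3))
        sv = exact_shapley(model, np.array([4.0, 4.0, 9.0]), background)
        assert sv.phi.iloc[0] == pytest.approx(sv.phi.iloc[1], abs=1e-12)
        assert sv.phi.iloc[2] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_permutation_ordering_oracle(self, rng, k):
        # nonlinear model with interactions: the two enumeration strategies
        # must produce identical attributions
        def model(X):
            out = X[:, 0] * X[:, 1] + np.sin(X[:, -1])
            if k >= 3:
                out = out + 0.5 * X[:, 2] ** 2
            return out

        background = rng.normal(size=(12, k))
        instance = rng.normal(size=k)
        sv = exact_shapley(model, instance, background)
        oracle = ordering_oracle_shapley(model, instance, background)
        np.testing.assert_allclose(sv.phi.to_numpy(), oracle, atol=1e-9)

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            exact_shapley(lambda X: X[:, 0], np.array([1.0]), np.empty((0, 1)))


class TestShapSummary:
    def test_single_instance_ranking_matches_abs_phi(self, rng):
        w = np.array([5.0, -1.0, 0.5])
        model = lambda X: X @ w
        background = np.zeros((8, 3))
        instance = np.array([[1.0, 1.0, 1.0]])
        summary = shap_summary(model, instance, background)
        assert summary.ranking["feature"].tolist() == ["f0", "f1", "f2"]

    def test_constant_model_all_zero_with_name_tiebreak(self):
        model = lambda X: np.full(len(X), 7.0)
        background = np.ones((5, 3))
        summary = shap_summary(model, np.ones((4, 3)), background,
                               feature_names=["c", "a", "b"])
        assert np.allclose(summary.phi.to_numpy(), 0.0)
        assert summary.ranking["feature"].tolist() == ["a", "b", "c"]

    def test_mean_abs_phi_descending(self, rng):
        X = pd.DataFrame(rng.random((80, 7)) * 30, columns=FEATURE_NAMES)
        y = X["tip_distance"] * 20 + rng.normal(0, 1, 80)
        model = fit_model(ModelSpec("linear_regression"), X, y)
        summary = shap_summary(model, X.iloc[:10], X.iloc[20:60])
        vals = summary.ranking["mean_abs_phi"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-12)


class TestPermutationImportance:
    def test_inert_constant_feature_has_zero_importance(self, rng):
        X = pd.DataFrame(rng.random((300, 7)) * 40, columns=FEATURE_NAMES)
        X["palmsize1"] = 3.14  # constant: shuffling it cannot change anything
        y = X["tip_joint_angle"].to_numpy() * 1.5
        model = fit_model(ModelSpec("linear_regression"), X, y)
        imp = permutation_importance(model, X, y, n_repeats=10, seed=0)
        row = imp.table.set_index("feature").loc["palmsize1"]
        assert abs(row["importance"]) < 0.01

    def test_single_informative_feature_dominates(self, rng):
        X = pd.DataFrame(rng.random((400, 7)) * 50, columns=FEATURE_NAMES)
        y = X["mp_distance"].to_numpy().copy()
        model = fit_model(ModelSpec("linear_regression"), X, y)
        imp = permutation_importance(model, X, y, metric="r2", seed=1)
        t = imp.table.set_index("feature")
        assert t.loc["mp_distance", "importance"] > 0.5
        others = t.drop(index="mp_distance")["importance"].abs()
        assert (others < 0.01).all()

    def test_deterministic_given_seed(self, rng):
        X = pd.DataFrame(rng.random((100, 7)), columns=FEATURE_NAMES)
        y = X.sum(axis=1).to_numpy()
        model = fit_model(ModelSpec("random_forest"), X, y, seed=0)
        a = permutation_importance(model, X, y, seed=9)
        b = permutation_importance(model, X, y, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_independent_noise_feature_importance_shrinks_with_n(self, rng):
        sizes = (100, 2000)
        scores = []
        for n in sizes:
            X = pd.DataFrame(rng.random((n, 7)) * 20, columns=FEATURE_NAMES)
            y = X["tip_joint_angle"].to_numpy() + rng.normal(0, 0.5, n)
            model = fit_model(ModelSpec("linear_regression"), X, y)
            imp = permutation_importance(model, X, y, seed=2)
            scores.append(abs(imp.table.set_index("feature")
                              .loc["palmsize2", "importance"]))
        assert scores[1] <= scores[0] + 1e-3

    def test_unknown_metric(self, rng):
        X = pd.DataFrame(rng.random((50, 7)), columns=FEATURE_NAMES)
        y = X.sum(axis=1).to_numpy()
        model = fit_model(ModelSpec("linear_regression"), X, y)
        with pytest.raises(ValidationError):
            permutation_importance(model, X, y, metric="accuracy")


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 7)), columns=FEATURE_NAMES)
        df["true_angle_deg"] = rng.normal(size=50)
        corr = correlation_matrix(df)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        assert (corr.values <= 1.0 + 1e-12).all()

    def test_anticorrelated_pair(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                           "b": [-1.0, -2.0, -3.0, -4.0]})
        corr = correlation_matrix(df, columns=["a", "b"])
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert corr.loc["a", "a"] == 1.0

    def test_zero_variance_column_named_in_error(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 7)), columns=FEATURE_NAMES)
        df["palmsize2"] = 1.0
        df["true_angle_deg"] = rng.normal(size=20)
        with pytest.raises(UndefinedStatisticError, match="palmsize2"):
            correlation_matrix(df)
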