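"""Shapley axioms against a brute-force oracle, surrogate recovery, Grad-CAM."""

import dataclasses
from itertools import combinations
from math import factorial

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

import uqtriage as uq
from uqtriage._nn import DropoutMLP, TinyConvNet3D
from uqtriage.explainability import (
    attribution_uncertainty_correlation, coalition_value, shapley_attributions,
    surrogate_attributions, total_abs_attribution)

from conftest import feature_matrix


def brute_force_shapley(forest, x, p):
    """2^p coalition enumeration with the path-conditional valuation."""
    phi = np.zeros(p)
    for i in range(p):
        rest = [j for j in range(p) if j != i]
        for r in range(p):
            w = factorial(r) * factorial(p - r - 1) / factorial(p)
            for S in combinations(rest, r):
                phi[i] += w * (coalition_value(forest, x, S + (i,))
                               - coalition_value(forest, x, S))
    return phi


class TestTreeShapley:
    @pytest.mark.parametrize("p,n_trees,depth", [(6, 3, 3), (8, 2, 3)])
    def test_matches_exponential_oracle(self, p, n_trees, depth):
        rng = np.random.default_rng(p)
        X = rng.standard_normal((60, p))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=n_trees, max_depth=depth,
                                    random_state=0).fit(X, y)
        recs = shapley_attributions(rf, X[:4])
        for i, rec in enumerate(recs):
            assert np.allclose(rec.values, brute_force_shapley(rf, X[i], p),
                               atol=1e-10)

    def test_efficiency_on_fitted_cohort(self, fitted):
        models, _, X, _ = fitted
        Xs = X[:30, models.feature_idx]
        recs = shapley_attributions(models.radiomics, Xs)
        preds = models.radiomics.predict_proba(Xs)[:, 1]
        for rec, pred in zip(recs, preds):
            assert rec.baseline + rec.values.sum() == pytest.approx(pred, abs=1e-6)

    def test_null_player_gets_zero(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.standard_normal(80), np.zeros(80)])
        y = (X[:, 0] > 0).astype(int)
        tree = DecisionTreeClassifier(random_state=0).fit(X, y)
        recs = shapley_attributions(tree, X[:10])
        assert all(rec.values[1] == 0.0 for rec in recs)

    def test_symmetric_ensemble_symmetric_attribution(self):
        # two stumps, one splitting each of two interchangeable features;
        # the averaged game is symmetric, so equal inputs get equal credit
        rng = np.random.default_rng(1)
        z = rng.standard_normal(100)
        y = (z > 0).astype(int)
        X0 = np.column_stack([z, np.zeros(100)])
        X1 = np.column_stack([np.zeros(100), z])
        t0 = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X0, y)
        t1 = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X1, y)
        x = np.array([1.3, 1.3])
        v0 = shapley_attributions(t0, [x])[0].values
        v1 = shapley_attributions(t1, [x])[0].values
        mean = (v0 + v1) / 2
        assert mean[0] == pytest.approx(mean[1], abs=1e-12)

    def test_constant_prediction_all_zero(self):
        X = np.random.default_rng(2).standard_normal((30, 3))
        tree = DecisionTreeClassifier().fit(X, np.zeros(30, dtype=int))
        recs = shapley_attributions(tree, X[:5], class_idx=0)
        assert all(np.allclose(r.values, 0.0) for r in recs)

    def test_schema_mismatch_rejected(self, fitted):
        models, _, X, _ = fitted
        with pytest.raises(ValueError):
            shapley_attributions(models.radiomics, X[:2, :3])

    def test_signal_features_rank_first_globally(self):
        firsts = 0
        for seed in range(10):
            cfg = uq.SyntheticConfig(n_cases=150, difficulty=0.5, seed=100 + seed)
            X, y = feature_matrix(uq.cohort_to_frame(uq.generate_cohort(cfg)))
            rf = RandomForestClassifier(n_estimators=47, min_samples_leaf=5,
                                        random_state=seed).fit(X, y)
            recs = shapley_attributions(rf, X)
            global_imp = np.abs(np.stack([r.values for r in recs])).mean(axis=0)
            firsts += int(np.argmax(global_imp)) < cfg.n_informative
        assert firsts >= 9


class TestSurrogate:
    def test_linear_target_concentrates_attribution(self):
        wins = 0
        for seed in range(10):
            rec = surrogate_attributions(
                lambda Z: 1 / (1 + np.exp(-2 * Z[:, 2])), np.zeros(6),
                n_perturbations=5000, seed=seed)
            wins += abs(rec.values[2]) / rec.total_abs >= 0.95
        assert wins > 5

    def test_constant_function_zero_coefficients(self):
        rec = surrogate_attributions(lambda Z: np.full(len(Z), 0.4),
                                     np.zeros(4), n_perturbations=500, seed=0)
        assert np.allclose(rec.values, 0.0, atol=1e-9)

    def test_zero_variance_feature_excluded(self):
        with pytest.warns(UserWarning):
            rec = surrogate_attributions(
                lambda Z: Z[:, 0], np.zeros(3),
                feature_scale=np.array([1.0, 0.0, 1.0]),
                n_perturbations=500, seed=0)
        assert rec.values[1] == 0.0

    def test_minimum_perturbations_enforced(self):
        with pytest.raises(ValueError):
            surrogate_attributions(lambda Z: Z[:, 0], np.zeros(2),
                                   n_perturbations=50)

    def test_seeded_reproducibility(self):
        f = lambda Z: Z[:, 0] ** 2
        a = surrogate_attributions(f, np.ones(3), n_perturbations=500, seed=3)
        b = surrogate_attributions(f, np.ones(3), n_perturbations=500, seed=3)
        assert np.array_equal(a.values, b.values)


class TestTotalAbs:
    def test_hand_example_and_sign_invariance(self):
        rec = uq.AttributionRecord("c", "shapley", np.array([0.2, -0.3, 0.1]), 0.0)
        assert total_abs_attribution(rec) == pytest.approx(0.6)
        flipped = uq.AttributionRecord("c", "shapley",
                                       np.array([-0.2, 0.3, -0.1]), 0.0)
        assert total_abs_attribution(flipped) == pytest.approx(0.6)
        zero = uq.AttributionRecord("c", "shapley", np.zeros(3), 0.0)
        assert total_abs_attribution(zero) == 0.0


class TestCorrelation:
    def test_perfect_anti_rank(self):
        res = attribution_uncertainty_correlation([3, 2, 1], [0.1, 0.2, 0.3])
        assert res["spearman_rho"] == pytest.approx(-1.0)

    def test_identical_vectors(self):
        v = [0.1, 0.5, 0.9, 0.3]
        res = attribution_uncertainty_correlation(v, v)
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        res = attribution_uncertainty_correlation(rng.random(1000),
                                                  rng.random(1000))
        assert abs(res["spearman_rho"]) < 0.1

    def test_ci_band_contains_fit(self):
        rng = np.random.default_rng(1)
        x = rng.random(50)
        y = 2 * x + 0.1 * rng.standard_normal(50)
        res = attribution_uncertainty_correlation(x, y)
        grid = np.linspace(0, 1, 11)
        lo, hi = res["ci_band"](grid)
        fit = res["intercept"] + res["slope"] * grid
        assert np.all(lo <= fit) and np.all(fit <= hi)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            attribution_uncertainty_correlation([1, 1, 1], [0.1, 0.2, 0.3])


@pytest.fixture(scope="module")
def trained_convnet():
    cfg = uq.SyntheticConfig(n_cases=30, n_centers=4, difficulty=0.0,
                             image_shape=(16, 16, 16), seed=3)
    # fixed lesion size isolates the texture signal the network learns
    cases = [dataclasses.replace(c, size_mm=25.0)
             for c in uq.generate_cohort(cfg)]
    imgs = uq.generate_images(cases, cfg)
    y = np.array([c.label == "High-Risk" for c in cases], dtype=int)
    X = np.stack([v for v, _ in imgs])
    net = TinyConvNet3D(seed=0).fit(X, y, epochs=150)
    return net, X, y, imgs


class TestGradCam:
    def test_map_nonnegative_and_localizes(self, trained_convnet):
        net, X, y, imgs = trained_convnet
        high = [i for i in range(len(y)) if y[i] == 1][:10]
        hits = 0
        for i in high:
            cam = uq.grad_cam(net, X[i], target_class=1)
            assert np.all(cam.heat >= 0)
            argmax = np.unravel_index(np.argmax(cam.heat), cam.heat.shape)
            hits += bool(imgs[i][1][argmax])
        assert hits >= 8

    def test_zero_head_gives_zero_map(self, trained_convnet):
        net, X, _, _ = trained_convnet
        import copy
        dead = copy.deepcopy(net)
        dead.Wd = np.zeros_like(dead.Wd)
        cam = uq.grad_cam(dead, X[0], target_class=1)
        assert np.allclose(cam.heat, 0.0)

    def test_non_convolutional_model_rejected(self):
        mlp = DropoutMLP(n_features=4, seed=0)
        with pytest.raises(ValueError):
            uq.grad_cam(mlp, np.zeros((8, 8, 8)))
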