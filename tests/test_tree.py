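"""Curvature-test trees: split selection, surrogates, pruning, importance."""

import numpy as np
import pytest
from scipy import stats as sps

from adpanel.forest import (ForestHyper, fit_forest, importance, predict,
                            sens_spec)
from adpanel.tree import (TreeHyper, count_nodes, curvature_test, grow_tree,
                          interaction_curvature_test, predict_tree, prune,
                          tree_importance)


def _separable(rng, n=100, p=4, informative=0, gap=2.0):
    X = rng.standard_normal((n, p))
    y = (rng.random(n) < 0.5).astype(int)
    X[:, informative] += gap * y
    return X, y


class TestCurvatureTest:
    def test_perfect_separation_tiny_pvalue_matches_chi2_oracle(self):
        y = np.repeat([0, 1], 20)
        x = np.concatenate([np.linspace(0, 1, 20), np.linspace(5, 6, 20)])
        p = curvature_test(x, y)
        assert p < 1e-4
        # oracle: quartile bins x class table, Pearson chi-square
        edges = np.quantile(x, [0.25, 0.5, 0.75])
        bins = (x[:, None] > edges).sum(1)
        table = np.zeros((2, 4))
        np.add.at(table, (y, bins), 1)
        ref = sps.chi2_contingency(table[:, table.sum(0) > 0],
                                   correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_constant_predictor_uninformative(self):
        assert curvature_test(np.ones(30), np.repeat([0, 1], 15)) == 1.0

    def test_all_missing_uninformative(self):
        assert curvature_test(np.full(20, np.nan), np.repeat([0, 1], 10)) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            curvature_test(np.arange(10.0), np.zeros(10, int))

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(0)
        pvals = [curvature_test(rng.standard_normal(80),
                                (rng.random(80) < 0.5).astype(int))
                 for _ in range(300)]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestInteractionTest:
    def test_xor_detected_only_jointly(self):
        rng = np.random.default_rng(3)
        n = 400
        a = (rng.random(n) < 0.5).astype(int)
        b = (rng.random(n) < 0.5).astype(int)
        y = a ^ b
        x1 = a + 0.1 * rng.standard_normal(n)
        x2 = b + 0.1 * rng.standard_normal(n)
        p_joint = interaction_curvature_test(x1, x2, y)
        p_single = min(curvature_test(x1, y), curvature_test(x2, y))
        assert p_joint < 1e-6
        assert p_joint < p_single / 10

    def test_constant_partner_reduces_to_single_test(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        y = (x + 0.5 * rng.standard_normal(100) > 0).astype(int)
        p_pair = interaction_curvature_test(x, np.ones(100), y)
        p_single = curvature_test(x, y)
        assert p_pair == pytest.approx(p_single, rel=1e-6)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = [interaction_curvature_test(rng.standard_normal(100),
                                            rng.standard_normal(100),
                                            (rng.random(100) < 0.5).astype(int))
                 for _ in range(300)]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestGrowPredict:
    def test_single_separating_feature_depth_one(self, rng):
        X, y = _separable(rng, gap=8.0)
        tree = grow_tree(X, y, hyper=TreeHyper(min_leaf=5, max_splits=10))
        assert tree.feature == 0
        assert predict_tree(tree, X).argmax(1).tolist() == y.tolist()

    def test_engines_identical_on_masked_data(self, rng):
        X, y = _separable(rng, n=250, p=6, gap=2.0)
        X[rng.random(X.shape) < 0.15] = np.nan
        hyper = TreeHyper(min_leaf=5, max_splits=12)
        fast = grow_tree(X, y, hyper=hyper, engine="fast")
        ref = grow_tree(X, y, hyper=hyper, engine="python")
        Xt = rng.standard_normal((150, 6))
        Xt[rng.random(Xt.shape) < 0.25] = np.nan
        np.testing.assert_allclose(predict_tree(fast, Xt), predict_tree(ref, Xt))
        assert fast.feature == ref.feature
        assert fast.threshold == pytest.approx(ref.threshold)
        assert [s[0] for s in fast.surrogates] == [s[0] for s in ref.surrogates]

    def test_single_feature_tree_matches_sklearn_cart(self, rng):
        """On one predictor both selection rules coincide with Gini CART."""
        from sklearn.tree import DecisionTreeClassifier

        x = rng.standard_normal(100)
        y = ((x + 0.6 * rng.standard_normal(100)) > 0).astype(int)
        X = x.reshape(-1, 1)
        mine = grow_tree(X, y, hyper=TreeHyper(min_leaf=5, max_splits=3))
        ref = DecisionTreeClassifier(criterion="gini", min_samples_leaf=5,
                                     max_leaf_nodes=4, random_state=0).fit(X, y)
        grid = np.linspace(x.min(), x.max(), 300).reshape(-1, 1)
        agree = (predict_tree(mine, grid).argmax(1) == ref.predict(grid)).mean()
        assert agree == 1.0

    def test_all_missing_row_gets_class_priors(self, rng):
        X, y = _separable(rng)
        tree = grow_tree(X, y, hyper=TreeHyper(min_leaf=5, max_splits=5))
        post = predict_tree(tree, np.full((1, 4), np.nan))[0]
        np.testing.assert_allclose(post, np.bincount(y) / len(y))

    def test_complete_row_identical_to_maskfree_routing(self, rng):
        X, y = _separable(rng, n=200, p=5)
        X[rng.random(X.shape) < 0.1] = np.nan
        tree = grow_tree(X, y, hyper=TreeHyper(min_leaf=5, max_splits=8))
        Xt = rng.standard_normal((50, 5))
        np.testing.assert_allclose(predict_tree(tree, Xt), predict_tree(tree, Xt))
        assert np.all(predict_tree(tree, Xt).sum(1) == pytest.approx(1.0))

    def test_perfect_surrogate_routes_masked_rows_identically(self, rng):
        n = 300
        x0 = rng.standard_normal(n)
        X = np.c_[x0, x0, rng.standard_normal(n)]  # column 1 duplicates 0
        # class steps exactly at the median, so the duplicate's median cut
        # reproduces the primary split perfectly (agreement 1.0)
        y = (x0 > np.median(x0)).astype(int)
        tree = grow_tree(X, y, hyper=TreeHyper(min_leaf=10, max_splits=3))
        assert tree.surrogates and tree.surrogates[0][3] == pytest.approx(1.0)
        Xt = np.c_[rng.standard_normal(80), np.zeros(80), np.zeros(80)]
        Xt[:, 1] = Xt[:, 0]
        full = predict_tree(tree, Xt)
        masked = Xt.copy()
        masked[:, 0] = np.nan  # primary missing, perfect surrogate present
        np.testing.assert_allclose(predict_tree(tree, masked), full)

    def test_surrogate_agreement_bounds_and_order(self, prepared):
        panel, labels = prepared
        y = labels.amyloid_positive.astype(int)
        tree = grow_tree(panel.values, y, hyper=TreeHyper(min_leaf=20, max_splits=4))
        for node in _walk(tree):
            ag = [s[3] for s in node.surrogates]
            assert all(0.5 < a <= 1.0 for a in ag)
            assert ag == sorted(ag, reverse=True)

    def test_monotone_transform_invariance(self, rng):
        """Strictly increasing transforms change thresholds, not structure."""
        X, y = _separable(rng, n=200, p=4, gap=1.5)
        X[rng.random(X.shape) < 0.1] = np.nan
        hyper = TreeHyper(min_leaf=8, max_splits=6)
        base = grow_tree(X, y, hyper=hyper)
        Xt = X.copy()
        Xt[:, 0] = np.exp(X[:, 0])  # monotone transform of a predictor
        trans = grow_tree(Xt, y, hyper=hyper)
        assert [n.feature for n in _walk(base)] == [n.feature for n in _walk(trans)]
        np.testing.assert_allclose(tree_importance(base, 4),
                                   tree_importance(trans, 4), atol=1e-12)


def _walk(tree):
    out = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            out.append(node)
            stack.extend([node.left, node.right])
    return out


class TestPrune:
    def test_noise_overfit_tree_shrinks(self, rng):
        X = rng.standard_normal((200, 3))
        y = (rng.random(200) < 0.5).astype(int)  # pure noise
        tree = grow_tree(X, y, hyper=TreeHyper(min_leaf=2, max_splits=40))
        Xv = rng.standard_normal((200, 3))
        yv = (rng.random(200) < 0.5).astype(int)
        pruned = prune(tree, Xv, yv)
        assert count_nodes(pruned) < count_nodes(tree)

    def test_separable_tree_untouched(self, rng):
        X, y = _separable(rng, gap=8.0)
        tree = grow_tree(X, y, hyper=TreeHyper(min_leaf=5, max_splits=10))
        pruned = prune(tree, X, y)
        assert count_nodes(pruned) == count_nodes(tree)

    def test_validation_risk_never_increases(self, rng):
        for _ in range(5):
            X, y = _separable(rng, n=150, gap=1.0)
            tree = grow_tree(X, y, hyper=TreeHyper(min_leaf=3, max_splits=25))
            Xv, yv = _separable(rng, n=150, gap=1.0)
            before = (predict_tree(tree, Xv).argmax(1) != yv).mean()
            after = (predict_tree(prune(tree, Xv, yv), Xv).argmax(1) != yv).mean()
            assert after <= before + 1e-12


class TestImportance:
    def test_unused_and_single_feature(self, rng):
        X, y = _separable(rng, gap=8.0)
        forest = fit_forest(X, y, ForestHyper(method="bag", n_cycles=10,
                                              min_leaf=5, max_splits=1), rng)
        imp = importance(forest)
        assert imp[0] > 0
        assert np.all(imp[1:] == 0)  # depth-1 trees only ever use the separator

    def test_predictive_feature_dominates_noise(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 150
            y = (rng.random(n) < 0.5).astype(int)
            X = np.c_[y + 0.05 * rng.standard_normal(n), rng.standard_normal(n)]
            forest = fit_forest(X, y, ForestHyper(method="bag", n_cycles=15,
                                                  min_leaf=5, max_splits=6), rng)
            imp = importance(forest)
            if imp[0] > 10 * imp[1]:
                wins += 1
        assert wins == 20


class TestEnsembles:
    def test_posterior_rows_sum_to_one_all_methods(self, rng):
        X, y = _separable(rng, n=150, gap=1.0)
        X[rng.random(X.shape) < 0.2] = np.nan
        for method in ("bag", "boost"):
            model = fit_forest(X, y, ForestHyper(method=method, n_cycles=12,
                                                 learn_rate=0.3, min_leaf=5,
                                                 max_splits=6), rng)
            post = predict(model, X)
            np.testing.assert_allclose(post.sum(1), 1.0, atol=1e-12)

    def test_bagging_matches_sklearn_ensemble_oracle(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        X, y = _separable(rng, n=200, p=5, gap=2.5)
        mine = fit_forest(X, y, ForestHyper(method="bag", n_cycles=40,
                                            min_leaf=5, max_splits=15), rng)
        ref = RandomForestClassifier(n_estimators=100, min_samples_leaf=5,
                                     random_state=0).fit(X, y)
        agree = (predict(mine, X).argmax(1) == ref.predict(X)).mean()
        assert agree >= 0.95

    def test_surrogate_routing_matches_complete_predictions(self, rng):
        """20% masking of the split variable, informative surrogate present."""
        n = 500
        latent = rng.standard_normal(n)
        X = np.c_[latent + 0.15 * rng.standard_normal(n),
                  latent + 0.15 * rng.standard_normal(n),
                  rng.standard_normal(n)]
        y = ((latent + 0.5 * rng.standard_normal(n)) > 0).astype(int)
        model = fit_forest(X, y, ForestHyper(method="bag", n_cycles=20,
                                             min_leaf=10, max_splits=6), rng)
        Xt = X.copy()
        full = predict(model, Xt).argmax(1)
        masked = Xt.copy()
        masked[rng.random(n) < 0.2, 0] = np.nan
        agree = (predict(model, masked).argmax(1) == full).mean()
        assert agree >= 0.9


class TestSensSpec:
    def test_arithmetic(self):
        pred = np.r_[np.ones(8), np.zeros(2), np.zeros(7), np.ones(3)]
        true = np.r_[np.ones(10), np.zeros(10)]
        assert sens_spec(pred, true) == (0.8, 0.7)

    def test_degenerate_predictions(self):
        true = np.r_[np.ones(5), np.zeros(5)]
        assert sens_spec(np.ones(10), true) == (1.0, 0.0)
        assert sens_spec(true, true) == (1.0, 1.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            sens_spec(np.ones(5), np.ones(5))
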