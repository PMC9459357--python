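"""Post-hoc CATE description: second-stage OLS, pruned CART, honest leaf
re-estimation, best-tree summaries, explained variation."""

import numpy as np
import pytest

from trialhte.aggregate import aipw_scores_from_arrays
from trialhte.explore import (SubgroupTree, best_tree, fit_pruned_cart,
                              honest_subgroup_ates, r2_explained,
                              second_stage_ols)


def _step_tau(rng, n, p_extra=3):
    X = np.column_stack(
        [rng.integers(0, 2, n).astype(float)]
        + [rng.normal(size=n) for _ in range(p_extra)])
    tau = np.where(X[:, 0] > 0, -0.06, -0.02)
    names = ["mod"] + [f"z{i}" for i in range(p_extra)]
    return X, tau, names


class TestSecondStageOLS:
    def test_exact_linear_interpolation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        tau = 0.5 - 0.2 * X[:, 0] + 0.7 * X[:, 2]
        fit = second_stage_ols(tau, X, names=list("abc"))
        assert fit.intercept == pytest.approx(0.5, abs=1e-8)
        assert fit.slopes["a"] == pytest.approx(-0.2, abs=1e-8)
        assert fit.slopes["b"] == pytest.approx(0.0, abs=1e-8)
        assert fit.slopes["c"] == pytest.approx(0.7, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_cate(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 2))
        fit = second_stage_ols(np.full(100, -0.04), X, names=["a", "b"])
        assert fit.intercept == pytest.approx(-0.04, abs=1e-12)
        assert all(abs(v) < 1e-12 for v in fit.slopes.values())

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 4))
        tau = rng.normal(size=150)
        fit = second_stage_ols(tau, X, names=list("abcd"))
        Z = np.column_stack([np.ones(150), X])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ tau)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        for j, name in enumerate("abcd"):
            assert fit.slopes[name] == pytest.approx(beta[j + 1], abs=1e-8)

    def test_aliased_columns_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])  # aliased third column
        import logging
        with caplog.at_level(logging.WARNING, logger="trialhte"):
            fit = second_stage_ols(rng.normal(size=80), X,
                                   names=["a", "b", "a2"])
        assert fit.dropped == ["a2"]
        assert "a2" not in fit.slopes


class TestPrunedCART:
    def test_noise_free_step_gives_exactly_one_split(self):
        rng = np.random.default_rng(4)
        X, tau, names = _step_tau(rng, 400)
        tree = fit_pruned_cart(tau, X, cp=0.2, names=names)
        assert tree.leaf_count == 2
        assert tree.root["feature"] == "mod"
        vals = sorted(leaf["mean"] for leaf in tree.leaves())
        assert vals == pytest.approx([-0.06, -0.02])

    def test_cp_one_prunes_to_root(self):
        rng = np.random.default_rng(5)
        X, tau, names = _step_tau(rng, 300)
        tree = fit_pruned_cart(tau, X, cp=1.0, names=names)
        assert tree.leaf_count == 1

    def test_cp_zero_reproduces_cross_classification_cells(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([rng.integers(0, 2, 60),
                             rng.integers(0, 2, 60)]).astype(float)
        cell_tau = {(0, 0): 0.1, (0, 1): -0.2, (1, 0): 0.05, (1, 1): -0.4}
        tau = np.array([cell_tau[(int(a), int(b))] for a, b in X])
        tree = fit_pruned_cart(tau, X, cp=0.0, names=["a", "b"])
        assert tree.leaf_count == 4
        import pytest as _pt
        assert sorted(leaf["mean"] for leaf in tree.leaves()) == \
            _pt.approx(sorted(cell_tau.values()))

    def test_in_sample_r2_monotone_in_cp(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(500, 3))
        tau = np.tanh(X[:, 0]) * 0.1 + rng.normal(scale=0.02, size=500)
        r2s = []
        for cp in (0.5, 0.2, 0.05, 0.0):
            tree = fit_pruned_cart(tau, X, cp=cp, names=list("abc"))
            r2s.append(r2_explained(tree.predict(X), tau))
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_max_leaves_search(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(600, 4))
        tau = rng.normal(size=600)
        tree = fit_pruned_cart(tau, X, cp=0.0, names=list("abcd"),
                               max_leaves=10)
        assert tree.leaf_count <= 10

    def test_serialization_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        X, tau, names = _step_tau(rng, 200)
        tree = fit_pruned_cart(tau, X, cp=0.2, names=names)
        path = tmp_path / "tree.json"
        tree.to_json(path)
        back = SubgroupTree.from_json(path)
        np.testing.assert_array_equal(back.assign(X), tree.assign(X))
        assert back.leaf_count == tree.leaf_count
        assert "mod" in tree.to_text()


class TestHonestLeafEstimates:
    def _scores(self, rng, n, tau):
        d = rng.integers(0, 2, n)
        p0 = 0.4
        y = (rng.uniform(size=n) < p0 + d * tau).astype(float)
        return aipw_scores_from_arrays(tau, np.full(n, p0), p0 + tau,
                                       y, d, 0.5)

    def test_root_only_tree_recovers_overall_heldout_ate(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 2))
        tau = np.full(300, -0.05)
        tree = fit_pruned_cart(tau[:150], X[:150], cp=1.0, names=["a", "b"])
        scores = self._scores(rng, 150, tau[150:])
        tree = honest_subgroup_ates(tree, scores, X[150:], names=["a", "b"])
        leaf = tree.leaves()[0]
        assert leaf["honest_estimate"] == pytest.approx(scores.gamma.mean())
        assert leaf["honest_n"] == 150

    def test_leaf_without_heldout_support_flagged_not_estimable(self):
        X_train = np.column_stack([np.repeat([0.0, 1.0], 50),
                                   np.zeros(100)])
        tau = np.where(X_train[:, 0] > 0, -0.3, 0.0)
        tree = fit_pruned_cart(tau, X_train, cp=0.1, names=["a", "b"])
        assert tree.leaf_count == 2
        rng = np.random.default_rng(11)
        # held-out rows all fall on one side
        X_held = np.column_stack([np.zeros(60), rng.normal(size=60)])
        scores = self._scores(rng, 60, np.zeros(60))
        tree = honest_subgroup_ates(tree, scores, X_held, names=["a", "b"])
        flags = {leaf["honest_estimable"] for leaf in tree.leaves()}
        assert flags == {True, False}

    def test_training_means_retained_alongside(self):
        rng = np.random.default_rng(12)
        X, tau, names = _step_tau(rng, 300)
        tree = fit_pruned_cart(tau[:150], X[:150], cp=0.2, names=names)
        scores = self._scores(rng, 150, tau[150:])
        tree = honest_subgroup_ates(tree, scores, X[150:], names=names)
        for leaf in tree.leaves():
            assert "mean" in leaf and np.isfinite(leaf["mean"])


class TestBestTree:
    def test_minN_equal_n_gives_root_only(self):
        rng = np.random.default_rng(13)
        X, tau, names = _step_tau(rng, 150)
        tree = best_tree(tau, X, minN=150, num_trees=20, seed=1, names=names)
        assert tree.leaf_count == 1

    def test_returned_tree_attains_max_r2_against_forest(self):
        rng = np.random.default_rng(14)
        X, tau, names = _step_tau(rng, 250)
        tau = tau + rng.normal(scale=0.01, size=250)
        from sklearn.ensemble import RandomForestRegressor
        rf = RandomForestRegressor(n_estimators=30, min_samples_leaf=20,
                                   random_state=2)
        rf.fit(X, tau)
        agg = rf.predict(X)
        best_r2 = max(r2_explained(est.predict(X), agg)
                      for est in rf.estimators_)
        tree = best_tree(tau, X, minN=20, num_trees=30, seed=2, names=names)
        assert tree.r2_vs_forest == pytest.approx(best_r2)

    def test_leaf_count_nonincreasing_in_minN(self):
        ladder = [1, 50, 100, 200]
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(500, 4))
            tau = 0.05 * np.sign(X[:, 0]) + 0.03 * np.tanh(X[:, 1]) \
                + rng.normal(scale=0.02, size=500)
            counts = [best_tree(tau, X, minN=m, num_trees=50, seed=seed,
                                names=list("abcd")).leaf_count
                      for m in ladder]
            assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_explained_variation_ordering_under_nonlinear_truth(self):
        # deepest best tree >= coarse best tree >= linear model (in-sample)
        rng = np.random.default_rng(15)
        a = rng.integers(0, 2, 800)
        c = rng.normal(size=800)
        X = np.column_stack([a, rng.integers(0, 2, 800), c]).astype(float)
        # threshold effect + interaction: representable by a coarse tree
        # (the step group is large enough for minN=200) but not linearly
        step = (c > 0.3).astype(float)
        tau = (-0.08 * step - 0.03 * a * step
               + rng.normal(scale=0.005, size=800))
        names = ["a", "b", "c"]
        deep = best_tree(tau, X, minN=1, num_trees=60, seed=3, names=names)
        coarse = best_tree(tau, X, minN=200, num_trees=60, seed=3,
                           names=names)
        lin = second_stage_ols(tau, X, names=names)
        r2_deep = r2_explained(deep.predict(X), tau)
        r2_coarse = r2_explained(coarse.predict(X), tau)
        r2_lin = lin.r_squared
        assert r2_deep >= r2_coarse >= r2_lin


class TestR2Explained:
    def test_perfect_and_mean_predictors(self):
        rng = np.random.default_rng(16)
        tau = rng.normal(size=50)
        assert r2_explained(tau, tau) == 1.0
        assert r2_explained(np.full(50, tau.mean()), tau) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(17)
        tau = rng.normal(size=80)
        pred = rng.normal(size=80)
        expected = 1 - np.sum((tau - pred) ** 2) / \
            np.sum((tau - tau.mean()) ** 2)
        assert r2_explained(pred, tau) == pytest.approx(expected, abs=1e-12)

    def test_out_of_sample_may_be_negative(self):
        tau = np.array([0.0, 1.0, 2.0])
        assert r2_explained(np.array([5, 5, 5.0]), tau,
                            "out_of_sample") < 0

    def test_zero_sst_is_nan_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="trialhte"):
            out = r2_explained(np.zeros(10), np.ones(10))
        assert np.isnan(out)
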