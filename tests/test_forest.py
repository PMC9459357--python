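"""Honest causal forest: split-oracle equivalence, honesty, importance,
filtering, prediction contracts."""

import numpy as np
import pandas as pd
import pytest

from _designs import homogeneous_design, modifier_noise_design, step_design
from _oracles import (brute_force_best_split, honest_leaf_effect, tree_paths)
from trialhte.forest import (CausalForest, CausalTree, ForestConfig,
                             RegressionForest, fit_causal_forest, load_forest,
                             save_forest, select_variables)
from trialhte.simulate import SimulationConfig, generate_trial


def _binary_fixture(seed, n=30, p=3):
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.normal(size=n) for _ in range(p - 1)]
                        + [rng.integers(0, 2, n).astype(float)])
    y = rng.integers(0, 2, n).astype(float)
    d = np.zeros(n, dtype=np.int64)
    d[rng.permutation(n)[: n // 2]] = 1
    ids = rng.permutation(n)
    return X, y, d, ids[: n // 2], ids[n // 2:]


class TestCausalTree:
    def test_first_split_matches_brute_force(self):
        for seed in range(6):
            X, y, d, sidx, eidx = _binary_fixture(seed, n=34)
            tree = CausalTree(X, y, d, sidx, eidx,
                              config=ForestConfig(min_leaf_per_arm=3),
                              seed=seed)
            oracle = brute_force_best_split(X, y, d, list(sidx), list(eidx),
                                            min_leaf=3)
            if oracle is None:
                assert tree.is_leaf_root
            else:
                f, thr, _ = oracle
                assert tree.root_split() == (f, pytest.approx(thr))

    def test_every_leaf_effect_is_honest_difference_in_means(self):
        for seed in range(4):
            X, y, d, sidx, eidx = _binary_fixture(seed, n=40)
            tree = CausalTree(X, y, d, sidx, eidx,
                              config=ForestConfig(min_leaf_per_arm=2),
                              seed=seed)
            for path, node in tree_paths(tree):
                expected = honest_leaf_effect(X, y, d, list(eidx), path)
                assert tree.value[node] == expected  # exact

    def test_simple_leaf_effect_formula(self):
        # single leaf; estimate half: treated outcomes {1,0}, control {0,0}
        X = np.zeros((8, 2))
        y = np.array([1.0, 0, 0, 0, 1, 1, 0, 0])
        d = np.array([1, 1, 0, 0, 1, 1, 0, 0], dtype=np.int64)
        tree = CausalTree(X, y, d, split_ids=[4, 5, 6, 7],
                          estimate_ids=[0, 1, 2, 3],
                          config=ForestConfig(min_leaf_per_arm=1))
        assert tree.is_leaf_root
        assert tree.value[0] == 0.5

    def test_constant_covariates_yield_single_leaf(self):
        rng = np.random.default_rng(3)
        X = np.ones((40, 3))
        y = rng.integers(0, 2, 40).astype(float)
        d = np.tile([0, 1], 20).astype(np.int64)
        tree = CausalTree(X, y, d, np.arange(20), np.arange(20, 40))
        assert tree.is_leaf_root
        est = np.arange(20, 40)
        expected = (y[est][d[est] == 1].mean() - y[est][d[est] == 0].mean())
        assert tree.value[0] == pytest.approx(expected, abs=1e-15)

    def test_honesty_estimate_half_never_moves_structure(self):
        X, y, d, sidx, eidx = _binary_fixture(11, n=36)
        base = CausalTree(X, y, d, sidx, eidx, seed=11,
                          config=ForestConfig(min_leaf_per_arm=2))
        y2 = y.copy()
        y2[eidx] = 1 - y2[eidx]  # flip every estimate-half outcome
        alt = CausalTree(X, y2, d, sidx, eidx, seed=11,
                         config=ForestConfig(min_leaf_per_arm=2))
        assert np.array_equal(base.feature, alt.feature)
        assert np.array_equal(base.threshold, alt.threshold)

    def test_honesty_split_half_never_moves_leaf_effects(self):
        X, y, d, sidx, eidx = _binary_fixture(12, n=36)
        base = CausalTree(X, y, d, sidx, eidx, seed=12,
                          config=ForestConfig(min_leaf_per_arm=2))
        y2 = y.copy()
        rng = np.random.default_rng(0)
        y2[sidx] = rng.integers(0, 2, len(sidx))
        alt = CausalTree(X, y2, d, sidx, eidx, seed=12,
                         config=ForestConfig(min_leaf_per_arm=2))
        if np.array_equal(base.feature, alt.feature) and \
                np.array_equal(base.threshold, alt.threshold):
            assert np.array_equal(base.value, alt.value)
        else:  # structure moved: compare any leaf shared by both trees
            paths_a = {tuple(p): n for p, n in tree_paths(base)}
            paths_b = {tuple(p): n for p, n in tree_paths(alt)}
            shared = set(paths_a) & set(paths_b)
            for p in shared:
                assert base.value[paths_a[p]] == alt.value[paths_b[p]]

    def test_overlapping_halves_rejected(self):
        X, y, d, sidx, eidx = _binary_fixture(1)
        with pytest.raises(ValueError, match="honesty"):
            CausalTree(X, y, d, sidx, np.concatenate([eidx, sidx[:1]]))

    def test_missing_arm_is_a_fit_error(self):
        X, y, d, sidx, eidx = _binary_fixture(2)
        d2 = d.copy()
        d2[sidx] = 1
        with pytest.raises(ValueError, match="arm"):
            CausalTree(X, y, d2, sidx, eidx)


class TestForestPrediction:
    def test_ensemble_of_one_equals_its_tree(self):
        trial = generate_trial(step_design(200, 21))
        cfg = ForestConfig(num_trees=1, subsample_fraction=1.0, seed=2,
                           center_outcomes=False, ci_group_size=1)
        res = fit_causal_forest(trial, cfg, two_pass=False)
        X = res._fit_matrix()
        preds = res.ensemble.predict_matrix(X)
        assert preds.shape[1] == 1
        frame = res.predict(X)
        np.testing.assert_allclose(frame["tau_hat"], preds[:, 0])

    def test_constant_covariates_give_exchangeable_predictions(self):
        rng = np.random.default_rng(8)
        trial = pd.DataFrame({
            "patient_id": np.arange(300),
            "D": rng.integers(0, 2, 300),
            "Y": rng.integers(0, 2, 300),
            "x": np.ones(300),
        })
        res = fit_causal_forest(trial, ForestConfig(
            num_trees=40, seed=3, center_outcomes=False, ci_group_size=10))
        pred = res.predict(np.ones((25, 1)))
        assert pred["tau_hat"].nunique() == 1

    def test_prediction_invariant_under_row_permutation(self, default_trial,
                                                        tiny_forest_config):
        res = fit_causal_forest(default_trial, tiny_forest_config)
        rows = default_trial.head(60)
        perm = rows.sample(frac=1.0, random_state=4)
        a = res.predict(rows)
        b = res.predict(perm)
        b.index = perm.index
        merged = b.sort_index()
        np.testing.assert_allclose(a["tau_hat"], merged["tau_hat"])

    def test_oob_flag_and_se_present(self, default_trial):
        res = fit_causal_forest(default_trial, ForestConfig(
            num_trees=100, seed=9, ci_group_size=10, center_outcomes=False))
        oob = res.predict_oob()
        assert oob["oob"].mean() > 0.95
        ok = oob["se"].notna()
        assert ok.mean() > 0.95
        np.testing.assert_allclose(
            oob.loc[ok, "ci_high"] - oob.loc[ok, "tau_hat"],
            1.959963984540054 * oob.loc[ok, "se"])

    def test_unseen_categorical_level_routed_with_warning(self, caplog):
        trial = generate_trial(step_design(300, 30))
        res = fit_causal_forest(trial, ForestConfig(
            num_trees=30, seed=1, center_outcomes=False, ci_group_size=10))
        rows = trial.head(5).copy()
        rows["sepsis3"] = pd.Categorical(
            ["martian"] * 5, categories=["martian"])
        import logging
        with caplog.at_level(logging.WARNING, logger="trialhte"):
            pred = res.predict(rows)
        assert len(pred) == 5 and pred["tau_hat"].notna().all()
        assert any("unseen" in r.message for r in caplog.records)

    def test_forest_weights_rows_sum_to_one(self, default_trial,
                                            tiny_forest_config):
        res = fit_causal_forest(default_trial, tiny_forest_config)
        W = res.forest_weights(res._fit_matrix()[:5])
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)
        assert (W >= 0).all()

    def test_save_load_roundtrip(self, default_trial, tiny_forest_config,
                                 tmp_path):
        res = fit_causal_forest(default_trial, tiny_forest_config)
        save_forest(res, tmp_path / "forest.json")
        back = load_forest(tmp_path / "forest.json")
        X = res._fit_matrix()[:50]
        np.testing.assert_allclose(back.predict(X)["tau_hat"],
                                   res.predict(X)["tau_hat"])


class TestImportanceAndSelection:
    def test_selection_arithmetic(self):
        imp = {"a": 0.5, "b": 0.3, "c": 0.1, "d": 0.1}
        assert select_variables(imp, 1.0) == ["a", "b"]

    def test_all_equal_scores_all_retained(self):
        imp = {k: 0.25 for k in "abcd"}
        assert select_variables(imp, 1.0) == list("abcd")

    def test_multiplier_zero_retains_everything(self):
        imp = {"a": 0.9, "b": 0.1, "c": 0.0}
        assert select_variables(imp, 0.0) == ["a", "b", "c"]

    def test_lower_multiplier_retains_superset(self):
        rng = np.random.default_rng(5)
        imp = {f"v{i}": float(w) for i, w in
               enumerate(rng.dirichlet(np.ones(12)))}
        assert set(select_variables(imp, 1.0)) <= \
            set(select_variables(imp, 0.2))

    def test_importance_normalized_and_zero_for_unused(self, default_trial,
                                                       tiny_forest_config):
        res = fit_causal_forest(default_trial, tiny_forest_config,
                                two_pass=False)
        scores = res.importance_
        assert sum(scores.values()) == pytest.approx(1.0)
        ens = res.ensemble
        used = set(ens.feat[ens.feat >= 0].tolist())
        for j, name in enumerate(res.retained_):
            if j not in used:
                assert scores[name] == 0.0

    def test_modifier_survives_importance_filter(self):
        kept = 0
        n_seeds = 20
        for seed in range(n_seeds):
            trial = generate_trial(modifier_noise_design(2000, 700 + seed))
            res = fit_causal_forest(trial, ForestConfig(
                num_trees=150, seed=seed, ci_group_size=10,
                center_outcomes=False))
            kept += "modifier" in res.retained_
        assert kept >= 0.9 * n_seeds

    def test_dominant_modifier_attains_maximum_importance(self):
        dominant = 0
        n_seeds = 20
        for seed in range(n_seeds):
            trial = generate_trial(modifier_noise_design(
                2000, 7700 + seed, tau_in=-0.4, tau_out=0.0))
            res = fit_causal_forest(trial, ForestConfig(
                num_trees=150, seed=seed, ci_group_size=10,
                center_outcomes=False), two_pass=False)
            top = max(res.importance_, key=res.importance_.get)
            dominant += top == "modifier"
        assert dominant >= 0.9 * n_seeds

    def test_multiplier_zero_is_single_pass(self, default_trial):
        res = fit_causal_forest(default_trial, ForestConfig(
            num_trees=30, seed=2, importance_multiplier=0.0,
            center_outcomes=False, ci_group_size=10))
        assert res.single_pass
        assert res.retained_ == res.model.covariate_names


class TestAsymptotics:
    def test_error_decreases_when_n_doubles(self):
        errs = {1000: [], 2000: []}
        for seed in range(3):
            for n in (1000, 2000):
                trial = generate_trial(modifier_noise_design(n, 40 + seed))
                res = fit_causal_forest(trial, ForestConfig(
                    num_trees=200, seed=seed, ci_group_size=10))
                oob = res.predict_oob()
                tau = trial["true_tau"].to_numpy()
                errs[n].append(np.mean(np.abs(oob["tau_hat"] - tau)))
        assert np.mean(errs[2000]) < np.mean(errs[1000])

    def test_null_spread_shrinks_with_n_and_B(self):
        def spread(n, B, seed):
            trial = generate_trial(homogeneous_design(n, 900 + seed))
            res = fit_causal_forest(trial, ForestConfig(
                num_trees=B, seed=seed, ci_group_size=10))
            return res.predict_oob()["tau_hat"].std()

        small = np.mean([spread(700, 80, s) for s in range(2)])
        large = np.mean([spread(2100, 320, s) for s in range(2)])
        assert large < small


def test_config_validation():
    with pytest.raises(ValueError):
        ForestConfig(num_trees=0)
    with pytest.raises(ValueError):
        ForestConfig(honesty_fraction=1.0)
    with pytest.raises(ValueError):
        ForestConfig(mtry="half")
    trial = generate_trial(step_design(60, 1))
    with pytest.raises(ValueError, match="min_leaf"):
        fit_causal_forest(trial, ForestConfig(num_trees=10,
                                              min_leaf_per_arm=30))


def test_grid_search_scores_every_candidate(default_trial):
    from trialhte.forest import grid_search_forest
    base = ForestConfig(num_trees=60, seed=4, ci_group_size=10,
                        center_outcomes=False)
    best, table = grid_search_forest(
        default_trial, {"min_leaf_per_arm": [5, 20], "mtry": ["sqrt", 8]},
        base_config=base)
    assert len(table) == 4
    assert table["oob_aipw_error"].notna().all()
    winner = table.loc[table["oob_aipw_error"].idxmin()]
    assert best.min_leaf_per_arm == winner["min_leaf_per_arm"]


def test_regression_forest_recovers_conditional_mean():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(1500, 3))
    y = (X[:, 0] > 0).astype(float) * 2.0 + rng.normal(scale=0.3, size=1500)
    rf = RegressionForest(ForestConfig(num_trees=150, seed=2,
                                       ci_group_size=10)).fit(X, y)
    pred = rf.predict(np.array([[1.5, 0, 0], [-1.5, 0, 0]]))
    assert pred[0] - pred[1] == pytest.approx(2.0, abs=0.35)
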