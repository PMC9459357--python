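"""Subgroup logistic comparator: saturated-model oracles, recycled
predictions, bootstrap calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from trialhte.baseline import (SeparationError, SubgroupLogit,
                               SubgroupLogitResults, bootstrap_ci,
                               fit_subgroup_model, logistic_group_ate)


def _cell_trial(rng, n, probs):
    """2x2x2 data from known cell probabilities P(Y=1 | d, g)."""
    d = rng.integers(0, 2, n)
    g = rng.integers(0, 2, n)
    p = np.array([[probs[(0, 0)], probs[(0, 1)]],
                  [probs[(1, 0)], probs[(1, 1)]]])[d, g]
    y = (rng.uniform(size=n) < p).astype(int)
    return pd.DataFrame({"Y": y, "D": d, "g": g})


class TestSaturatedOracle:
    def test_fitted_cell_logodds_match_empirical(self):
        rng = np.random.default_rng(0)
        df = _cell_trial(rng, 4000, {(0, 0): 0.30, (0, 1): 0.45,
                                     (1, 0): 0.25, (1, 1): 0.35})
        res = fit_subgroup_model(df, "g")
        for d in (0, 1):
            for g in (0, 1):
                cell = df[(df.D == d) & (df.g == g)]
                emp = logit(cell.Y.mean())
                eta = (res.intercept + res.beta_g * g + res.alpha1 * d
                       + res.alpha2 * d * g)
                assert eta == pytest.approx(emp, abs=1e-8)

    def test_total_effect_equals_contingency_risk_difference(self):
        rng = np.random.default_rng(1)
        df = _cell_trial(rng, 3000, {(0, 0): 0.4, (0, 1): 0.5,
                                     (1, 0): 0.35, (1, 1): 0.42})
        res = fit_subgroup_model(df, "g")
        gc = res.gcomp_effects()
        sub = df[df.g == 1]
        rd = sub.loc[sub.D == 1, "Y"].mean() - sub.loc[sub.D == 0, "Y"].mean()
        assert gc.total_effect == pytest.approx(rd, abs=1e-10)
        assert ((gc.predictions >= 0) & (gc.predictions <= 1)).all().all()

    def test_identity_link_interaction_equals_alpha2(self):
        rng = np.random.default_rng(2)
        df = _cell_trial(rng, 2000, {(0, 0): 0.4, (0, 1): 0.5,
                                     (1, 0): 0.3, (1, 1): 0.55})
        res = fit_subgroup_model(df, "g", link="identity")
        gc = res.gcomp_effects()
        assert gc.interaction_effect == pytest.approx(res.alpha2, abs=1e-12)

    def test_null_coefficients_give_null_effects(self):
        model = SubgroupLogit([0, 1, 0, 1], [0, 1, 0, 1], [0, 0, 1, 1])
        res = SubgroupLogitResults(model, None,
                                   np.array([-0.3, 0.4, 0.0, 0.0]))
        gc = res.gcomp_effects()
        assert gc.total_effect == 0.0
        assert gc.interaction_effect == 0.0


def test_no_interaction_truth_recovered():
    rng = np.random.default_rng(3)
    # alpha2 = 0 truth: same multiplicative treatment effect in both groups
    from scipy.special import expit
    n = 20_000
    d = rng.integers(0, 2, n)
    g = rng.integers(0, 2, n)
    eta = -0.3 + 0.5 * g - 0.4 * d
    y = (rng.uniform(size=n) < expit(eta)).astype(int)
    res = fit_subgroup_model(pd.DataFrame({"Y": y, "D": d, "g": g}), "g")
    assert abs(res.alpha2) <= 0.1


def test_zero_event_cell_raises_separation_error():
    df = pd.DataFrame({
        "Y": [0, 0, 0, 0, 1, 0, 1, 0],
        "D": [1, 1, 0, 0, 1, 1, 0, 0],
        "g": [1, 1, 1, 1, 0, 0, 0, 0],
    })
    with pytest.raises(SeparationError, match="no events"):
        fit_subgroup_model(df, "g")


class TestBootstrap:
    def test_constant_statistic_has_zero_se(self):
        df = pd.DataFrame({"Y": np.ones(200), "D": np.tile([0, 1], 100)})
        res = bootstrap_ci(lambda t: t["Y"].mean(), df, B_boot=150, seed=1)
        assert res.se == 0.0
        assert res.ci_low == res.ci_high == 1.0

    def test_same_seed_same_interval(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"Y": rng.integers(0, 2, 300),
                           "D": rng.integers(0, 2, 300)})
        fn = lambda t: t.loc[t.D == 1, "Y"].mean() - \
            t.loc[t.D == 0, "Y"].mean()
        a = bootstrap_ci(fn, df, B_boot=200, seed=9)
        b = bootstrap_ci(fn, df, B_boot=200, seed=9)
        assert (a.se, a.ci_low, a.ci_high) == (b.se, b.ci_low, b.ci_high)

    def test_bootstrap_se_matches_analytic_two_proportion_se(self):
        rng = np.random.default_rng(6)
        n = 6000
        d = rng.integers(0, 2, n)
        y = (rng.uniform(size=n) < np.where(d == 1, 0.35, 0.45)).astype(int)
        df = pd.DataFrame({"Y": y, "D": d})
        fn = lambda t: t.loc[t.D == 1, "Y"].mean() - \
            t.loc[t.D == 0, "Y"].mean()
        res = bootstrap_ci(fn, df, B_boot=400, seed=2)
        n1, n0 = (d == 1).sum(), (d == 0).sum()
        p1, p0 = y[d == 1].mean(), y[d == 0].mean()
        analytic = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
        assert abs(res.se - analytic) / analytic < 0.15

    def test_unstable_replicates_error(self):
        # fails on (almost) every resample but not on the original data
        df = pd.DataFrame({"Y": np.arange(100), "D": np.tile([0, 1], 50)})

        def flaky(t):
            if t["Y"].duplicated().any():
                raise RuntimeError("duplicate rows")
            return 0.0

        with pytest.raises(RuntimeError, match="unstable"):
            bootstrap_ci(flaky, df, B_boot=100, seed=0)

    def test_minimum_replicates_enforced(self):
        df = pd.DataFrame({"Y": [1, 0], "D": [1, 0]})
        with pytest.raises(ValueError):
            bootstrap_ci(lambda t: 0.0, df, B_boot=50, seed=0)


def test_gcomp_collapsibility_across_saturated_subgroups():
    """Subgroup total effects n-weight-average to the overall recycled ATE."""
    rng = np.random.default_rng(7)
    df = _cell_trial(rng, 5000, {(0, 0): 0.42, (0, 1): 0.5,
                                 (1, 0): 0.36, (1, 1): 0.4})
    eff = {}
    for level in (0, 1):
        res = fit_subgroup_model(df.assign(ind=(df.g == level).astype(int)),
                                 "ind")
        eff[level] = res.gcomp_effects().total_effect
    n1 = (df.g == 1).sum()
    n0 = (df.g == 0).sum()
    weighted = (n1 * eff[1] + n0 * eff[0]) / len(df)
    overall = (df.loc[df.D == 1, "Y"].mean()
               - df.loc[df.D == 0, "Y"].mean())
    # saturated G-computation is collapsible up to randomization imbalance
    # between arms within subgroups; both routes estimate the same marginal
    # risk difference
    assert weighted == pytest.approx(overall, abs=0.02)


def test_null_bootstrap_ci_coverage():
    """95% percentile CIs cover 0 at close to nominal rate under the null."""
    rng = np.random.default_rng(8)
    cover = 0
    sims = 100
    for s in range(sims):
        df = _cell_trial(rng, 500, {(0, 0): 0.4, (0, 1): 0.4,
                                    (1, 0): 0.4, (1, 1): 0.4})

        def fn(t):
            res = SubgroupLogit(t["Y"], t["D"], t["g"]).fit()
            return res.gcomp_effects().total_effect

        try:
            res = bootstrap_ci(fn, df, B_boot=300, seed=s)
        except RuntimeError:
            continue
        cover += res.ci_low <= 0.0 <= res.ci_high
    assert 0.93 <= cover / sims <= 0.97


def test_logistic_group_ate_row():
    rng = np.random.default_rng(9)
    df = _cell_trial(rng, 1500, {(0, 0): 0.45, (0, 1): 0.5,
                                 (1, 0): 0.4, (1, 1): 0.42})
    trial = df.rename(columns={"g": "grp"})
    row = logistic_group_ate(trial, trial["grp"] == 1, "grp=1",
                             B_boot=150, seed=3)
    assert row.method == "logistic_gcomp"
    assert row.n_group == (trial["grp"] == 1).sum()
    assert row.ci_low <= row.estimate <= row.ci_high
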