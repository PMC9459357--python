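"""Honest causal forests: fitting, prediction, importance, and the two-pass
importance-filtered refit.

The forest is an ensemble of honest causal trees.  Each tree takes a
subsample of the data, splits it into a *split half* (which chooses the
recursive partition by maximizing the between-child spread of the
difference-in-means treatment effect) and an *estimate half* (which supplies
the within-leaf effect estimates), so no observation both places and
estimates a split.  Forest predictions average the leaf effects over trees;
out-of-bag (OOB) predictions for training rows use only trees whose
subsample excluded the row.

Standard errors come from a half-sample ensemble ("bootstrap of little
bags") construction: trees are grown in groups that share a random
half-sample of the data, and the variance of a prediction is estimated by
the between-group variance of the group mean predictions.  For a linear
statistic the between-half-sample variance over a fixed dataset equals the
sampling variance of the full-sample mean, which motivates the estimator;
the residual within-group tree noise is deliberately not subtracted, so
the intervals are mildly conservative.  SEs require
``subsample_fraction <= 0.5`` (tree subsamples are drawn inside the
group's half-sample).

Variable importance is a depth-weighted split frequency: splits at depth k
(root = 1) receive weight k**(-decay) over the first few levels, normalized
so scores sum to one.  The two-pass fit ranks covariates by pass-one
importance, retains those at or above ``importance_multiplier`` times the
mean score, and refits on the retained set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .simulate import RESERVED_COLUMNS, encode_covariates

logger = logging.getLogger("trialhte")

__all__ = [
    "ForestConfig",
    "CausalForest",
    "CausalForestResults",
    "CausalTree",
    "RegressionForest",
    "fit_causal_forest",
    "fit_causal_tree",
    "predict_cate",
    "variable_importance",
    "select_variables",
    "grid_search_forest",
    "save_forest",
    "load_forest",
    "ForestPredictor",
]

Z975 = 1.959963984540054


@dataclass(frozen=True)
class ForestConfig:
    """Tuning parameters of the honest forest.

    ``mtry`` may be a positive integer, ``"sqrt"`` (ceil of the square root
    of the number of fitted columns) or ``"default"``
    (min(ceil(sqrt(p)) + 20, p), the generalized-random-forest convention).
    ``max_depth=None`` grows until the per-arm leaf-size constraints bind.
    ``importance_multiplier`` scales the mean-importance retention threshold
    of the two-pass fit (1.0 = the mean; 0 disables filtering).
    """

    num_trees: int = 5000
    subsample_fraction: float = 0.5
    honesty_fraction: float = 0.5
    min_leaf_per_arm: int = 5
    mtry: int | str = "default"
    max_depth: int | None = None
    importance_multiplier: float = 1.0
    seed: int = 0
    #: subtract an out-of-bag marginal-outcome fit before causal splitting
    #: (local centering, as the generalized-random-forest estimator does)
    center_outcomes: bool = True
    #: trees per shared half-sample group (for the variance estimator)
    ci_group_size: int = 25
    #: depth-decay exponent of the importance weighting
    importance_decay: float = 2.0
    #: number of tree levels that contribute to importance
    importance_max_depth: int = 4

    def __post_init__(self) -> None:
        if self.num_trees < 1:
            raise ValueError("num_trees must be positive")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if not 0.0 < self.honesty_fraction < 1.0:
            raise ValueError("honesty_fraction must lie strictly in (0, 1)")
        if self.min_leaf_per_arm < 1:
            raise ValueError("min_leaf_per_arm must be positive")
        if isinstance(self.mtry, str) and self.mtry not in ("sqrt", "default"):
            raise ValueError("mtry must be a positive integer, 'sqrt' or "
                             "'default'")
        if self.importance_multiplier < 0:
            raise ValueError("importance_multiplier must be >= 0")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry == "sqrt":
            return max(1, int(np.ceil(np.sqrt(p))))
        if self.mtry == "default":
            # the generalized-random-forest convention: sqrt(p) + 20, capped
            return min(p, int(np.ceil(np.sqrt(p))) + 20)
        m = int(self.mtry)
        if m < 1:
            raise ValueError("mtry must be positive")
        return min(m, p)


class _TreeEnsemble:
    """Flat storage for a fitted ensemble plus subsample bookkeeping."""

    def __init__(self, feat, thr, left, right, value, depth, leaf_n1, leaf_n0,
                 offsets, inbag, group_size, mode):
        self.feat = feat
        self.thr = thr
        self.left = left
        self.right = right
        self.value = value
        self.depth = depth
        self.leaf_n1 = leaf_n1
        self.leaf_n0 = leaf_n0
        self.offsets = offsets
        self.inbag = inbag          # (n_train, B) bool
        self.group_size = group_size
        self.mode = mode

    @property
    def num_trees(self) -> int:
        return len(self.offsets) - 1

    @property
    def has_bags(self) -> bool:
        return self.group_size >= 2 and self.num_trees >= 2 * self.group_size

    def leaf_nodes(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        out = np.empty((X.shape[0], self.num_trees), dtype=np.int64)
        _kernels.apply_ensemble(self.feat, self.thr, self.left, self.right,
                                self.offsets, X, out)
        return out

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.leaf_nodes(X)]

    # -- aggregation -------------------------------------------------------
    def aggregate(self, preds: np.ndarray, valid: np.ndarray | None):
        """Point estimate and half-sample-ensemble SE from per-tree preds.

        ``valid`` masks usable trees per row (e.g. OOB trees); None = all.
        """
        n, B = preds.shape
        if valid is None:
            valid = np.ones((n, B), dtype=bool)
        cnt = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            point = np.where(cnt > 0,
                             (preds * valid).sum(axis=1) / np.maximum(cnt, 1),
                             np.nan)
        if not self.has_bags:
            return point, np.full(n, np.nan)
        g = self.group_size
        G = B // g
        pv = (preds * valid)[:, :G * g].reshape(n, G, g)
        vv = valid[:, :G * g].reshape(n, G, g)
        full = vv.sum(axis=2) == g          # groups entirely usable
        n_groups = full.sum(axis=1)
        gmean = np.where(full, pv.sum(axis=2) / g, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            overall = gmean.sum(axis=1) / np.maximum(n_groups, 1)
            dev = np.where(full, gmean - overall[:, None], 0.0)
            between = (dev ** 2).sum(axis=1) / np.maximum(n_groups - 1, 1)
        # half-sample ensemble variance: the between-group variance of the
        # group mean predictions.  For a linear statistic the variance of a
        # half-sample mean over a fixed dataset equals the sampling variance
        # of the full-sample mean; the residual tree-level Monte-Carlo noise
        # (within-group variance / group size) is left in, which makes the
        # estimate deliberately conservative.
        var = np.maximum(between, 1e-12)
        se = np.sqrt(var)
        se[n_groups < 2] = np.nan
        return point, se

    def split_counts(self, p: int, max_depth: int) -> np.ndarray:
        """Split counts per (feature, depth level 1..max_depth)."""
        counts = np.zeros((p, max_depth), dtype=np.int64)
        internal = self.feat >= 0
        dep = self.depth[internal]
        f = self.feat[internal]
        keep = dep < max_depth
        np.add.at(counts, (f[keep], dep[keep]), 1)
        return counts


def _fit_ensemble(X: np.ndarray, y: np.ndarray, d: np.ndarray,
                  config: ForestConfig, mode: int, seed: int) -> _TreeEnsemble:
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("covariate matrix contains missing values; "
                         "impute before fitting")
    if mode == _kernels.MODE_CAUSAL:
        d = np.ascontiguousarray(d, dtype=np.int64)
        if d.min() == d.max():
            raise ValueError("both treatment arms must be present")
    else:
        d = np.zeros(n, dtype=np.int64)

    g = max(1, int(config.ci_group_size))
    use_bags = config.subsample_fraction <= 0.5 and g >= 2
    if not use_bags:
        g = 1
        logger.warning("subsample_fraction > 0.5 or ci_group_size < 2: "
                       "half-sample variance groups disabled; SEs unavailable")
    B = int(np.ceil(config.num_trees / g)) * g
    s = max(2, int(round(config.subsample_fraction * n)))
    half = n // 2
    if use_bags:
        s = min(s, half)
    n_split = max(1, int(round(config.honesty_fraction * s)))
    if s - n_split < 1:
        n_split = s - 1
    if config.subsample_fraction * config.honesty_fraction * n \
            < 2 * config.min_leaf_per_arm:
        raise ValueError("subsample_fraction * honesty_fraction * n must be "
                         ">= 2 * min_leaf_per_arm")

    mtry = config.resolve_mtry(p)
    max_depth = -1 if config.max_depth is None else int(config.max_depth)
    min_leaf = int(config.min_leaf_per_arm)

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        0x7265E5]))
    max_nodes = 2 * max(1, n_split // max(1, min_leaf)) + 3

    feats, thrs, lefts, rights, values, depths = [], [], [], [], [], []
    ln1s, ln0s = [], []
    offsets = np.zeros(B + 1, dtype=np.int64)
    inbag = np.zeros((n, B), dtype=bool)

    fbuf = np.empty(max_nodes, dtype=np.int64)
    tbuf = np.empty(max_nodes, dtype=np.float64)
    lbuf = np.empty(max_nodes, dtype=np.int64)
    rbuf = np.empty(max_nodes, dtype=np.int64)
    vbuf = np.empty(max_nodes, dtype=np.float64)
    dbuf = np.empty(max_nodes, dtype=np.int64)
    n1buf = np.empty(max_nodes, dtype=np.int64)
    n0buf = np.empty(max_nodes, dtype=np.int64)

    b = 0
    while b < B:
        if use_bags:
            bag = rng.choice(n, size=half, replace=False)
        else:
            bag = None
        for _ in range(g):
            pool = bag if bag is not None else np.arange(n)
            sub = rng.choice(pool, size=s, replace=False) \
                if s < len(pool) else pool.copy()
            perm = rng.permutation(sub).astype(np.int64)
            sidx = perm[:n_split].copy()
            eidx = perm[n_split:].copy()
            tree_seed = int(rng.integers(0, 2 ** 32 - 1))
            n_nodes = _kernels.build_tree(
                X, y, d, sidx, eidx, min_leaf, mtry, max_depth, mode,
                tree_seed, fbuf, tbuf, lbuf, rbuf, vbuf, dbuf, n1buf, n0buf)
            feats.append(fbuf[:n_nodes].copy())
            thrs.append(tbuf[:n_nodes].copy())
            lefts.append(lbuf[:n_nodes].copy())
            rights.append(rbuf[:n_nodes].copy())
            values.append(vbuf[:n_nodes].copy())
            depths.append(dbuf[:n_nodes].copy())
            ln1s.append(n1buf[:n_nodes].copy())
            ln0s.append(n0buf[:n_nodes].copy())
            inbag[sub, b] = True
            offsets[b + 1] = offsets[b] + n_nodes
            b += 1

    return _TreeEnsemble(
        np.concatenate(feats), np.concatenate(thrs),
        np.concatenate(lefts), np.concatenate(rights),
        np.concatenate(values), np.concatenate(depths),
        np.concatenate(ln1s), np.concatenate(ln0s),
        offsets, inbag, g, mode)


def _importance_scores(ensemble: _TreeEnsemble, p: int,
                       decay: float, max_depth: int) -> np.ndarray:
    counts = ensemble.split_counts(p, max_depth)
    totals = counts.sum(axis=0)
    weights = (np.arange(1, max_depth + 1, dtype=float)) ** (-decay)
    usable = totals > 0
    if not usable.any():
        return np.full(p, 1.0 / p)
    freq = counts[:, usable] / totals[usable]
    score = freq @ weights[usable]
    return score / score.sum()


def variable_importance(results_or_ensemble, names: Sequence[str] | None = None,
                        decay: float | None = None,
                        max_depth: int | None = None) -> dict[str, float]:
    """Depth-weighted split-frequency importances, normalized to sum to 1."""
    if isinstance(results_or_ensemble, CausalForestResults):
        return dict(results_or_ensemble.importance_)
    ens = results_or_ensemble
    if names is None:
        raise ValueError("names required when passing a raw ensemble")
    score = _importance_scores(ens, len(names),
                               decay if decay is not None else 2.0,
                               max_depth if max_depth is not None else 4)
    return dict(zip(names, score.tolist()))


def select_variables(importance: dict[str, float],
                     multiplier: float) -> list[str]:
    """Names whose score is at or above multiplier x mean score (ties kept)."""
    if not importance:
        raise ValueError("importance is empty")
    scores = np.array(list(importance.values()), dtype=float)
    threshold = multiplier * scores.mean()
    keep = [name for name, sc in importance.items() if sc >= threshold]
    if not keep:  # defensive: cannot happen with >= and finite scores
        best = max(importance, key=importance.get)
        logger.warning("importance filter removed every covariate; "
                       "retaining the most important one (%s)", best)
        keep = [best]
    return keep


def _cate_frame(tau, se, oob, ids=None) -> pd.DataFrame:
    tau = np.asarray(tau, dtype=float)
    se = np.asarray(se, dtype=float)
    frame = pd.DataFrame({
        "tau_hat": tau,
        "se": se,
        "ci_low": tau - Z975 * se,
        "ci_high": tau + Z975 * se,
        "oob": np.asarray(oob, dtype=bool),
    })
    if ids is not None:
        frame.insert(0, "patient_id", np.asarray(ids))
    return frame


class CausalForest:
    """Honest causal forest model for a two-arm randomized trial.

    Parameters
    ----------
    outcome, treatment : array-like
        Binary outcome Y and arm indicator D (0/1).
    covariates : ndarray (n, p)
        Numeric covariate matrix (categoricals one-hot encoded).
    covariate_names : sequence of str, optional
    propensity : float
        Design randomization probability P(D=1); fixed, not estimated,
        unless ``estimate_propensity`` is set.
    config : ForestConfig
    """

    def __init__(self, outcome, treatment, covariates,
                 covariate_names: Sequence[str] | None = None,
                 propensity: float = 0.5,
                 config: ForestConfig | None = None,
                 estimate_propensity: bool = False):
        self.y = np.asarray(outcome, dtype=float).ravel()
        self.d = np.asarray(treatment, dtype=np.int64).ravel()
        self.X = np.ascontiguousarray(covariates, dtype=np.float64)
        n = len(self.y)
        if self.X.shape[0] != n or len(self.d) != n:
            raise ValueError("outcome, treatment and covariates disagree on n")
        if n < 50:
            raise ValueError("causal forest requires n >= 50")
        if set(np.unique(self.d)) - {0, 1}:
            raise ValueError("treatment must be coded 0/1")
        if not 0.0 < propensity < 1.0:
            raise ValueError("propensity must lie strictly in (0, 1)")
        if covariate_names is None:
            covariate_names = [f"x{j}" for j in range(self.X.shape[1])]
        if len(covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names length mismatch")
        self.covariate_names = list(covariate_names)
        if estimate_propensity:
            propensity = float(self.d.mean())
        self.propensity = propensity
        self.config = config or ForestConfig()
        self._categorical_levels: dict[str, list] = {}

    @classmethod
    def from_dataframe(cls, trial: pd.DataFrame, outcome: str = "Y",
                       treatment: str = "D",
                       covariates: Sequence[str] | None = None,
                       propensity: float = 0.5,
                       config: ForestConfig | None = None,
                       estimate_propensity: bool = False) -> "CausalForest":
        cov = list(covariates) if covariates is not None else \
            [c for c in trial.columns
             if c not in RESERVED_COLUMNS and c not in (outcome, treatment)]
        X, names = encode_covariates(trial, cov)
        model = cls(trial[outcome], trial[treatment], X, names,
                    propensity=propensity, config=config,
                    estimate_propensity=estimate_propensity)
        model._categorical_levels = {
            c: list(trial[c].cat.categories)
            for c in cov if isinstance(trial[c].dtype, pd.CategoricalDtype)}
        model._covariate_source = cov
        return model

    def encode_new(self, rows: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
        """Design matrix for new rows in the model's column basis.

        Unseen categorical levels contribute all-zero dummies and are routed
        by each split's complementary ("majority") branch; a warning is
        logged when this happens.
        """
        cols = np.zeros((len(rows), len(names)))
        for j, name in enumerate(names):
            if "=" in name and name.split("=", 1)[0] in rows.columns:
                base, lev = name.split("=", 1)
                cols[:, j] = (rows[base].astype(str) == lev).astype(float)
            elif name in rows.columns:
                cols[:, j] = np.asarray(rows[name], dtype=float)
            else:
                raise ValueError(f"rows are missing model covariate {name!r}")
        for base, levels in self._categorical_levels.items():
            if base in rows.columns:
                seen = set(str(v) for v in pd.unique(rows[base].dropna()))
                extra = seen - set(map(str, levels))
                if extra:
                    logger.warning(
                        "unseen level(s) %s in %r routed by the majority "
                        "branch rule", sorted(extra), base)
        return cols

    def marginal_outcome_fit(self) -> np.ndarray:
        """OOB marginal-outcome fit m(x) = E[Y | X=x] (regression forest)."""
        cfg = self.config
        mcfg = replace(cfg, num_trees=max(100, min(cfg.num_trees, 500)),
                       center_outcomes=False)
        ens = _fit_ensemble(self.X, self.y, None, mcfg, _kernels.MODE_REG,
                            cfg.seed + 7)
        preds = ens.predict_matrix(self.X)
        m_oob, _ = ens.aggregate(preds, ~ens.inbag)
        m_all, _ = ens.aggregate(preds, None)
        return np.where(np.isfinite(m_oob), m_oob, m_all)

    def fit(self, two_pass: bool = True) -> "CausalForestResults":
        cfg = self.config
        imp_all = None
        retained = self.covariate_names
        m_hat = self.marginal_outcome_fit() if cfg.center_outcomes else None
        y_fit = self.y - m_hat if m_hat is not None else self.y
        ens1 = _fit_ensemble(self.X, y_fit, self.d, cfg,
                             _kernels.MODE_CAUSAL, cfg.seed)
        imp_all = dict(zip(
            self.covariate_names,
            _importance_scores(ens1, self.X.shape[1], cfg.importance_decay,
                               cfg.importance_max_depth).tolist()))
        single_pass = True
        ensemble = ens1
        cols = np.arange(self.X.shape[1])
        if two_pass and cfg.importance_multiplier > 0:
            retained = select_variables(imp_all, cfg.importance_multiplier)
            if len(retained) < len(self.covariate_names):
                cols = np.array([self.covariate_names.index(r)
                                 for r in retained])
                ensemble = _fit_ensemble(
                    self.X[:, cols], y_fit, self.d, cfg,
                    _kernels.MODE_CAUSAL, cfg.seed + 1)
                single_pass = False
        imp_final = dict(zip(
            retained,
            _importance_scores(ensemble, len(retained), cfg.importance_decay,
                               cfg.importance_max_depth).tolist()))
        return CausalForestResults(self, ensemble, list(retained), cols,
                                   imp_all, imp_final, single_pass,
                                   m_hat=m_hat)


class CausalForestResults:
    """Fitted honest causal forest.

    Attributes
    ----------
    importance_ : dict
        Depth-weighted split importances of the final (retained-covariate)
        forest, summing to 1.
    initial_importance_ : dict
        Pass-one importances over all covariates (the filtering audit trail).
    retained_ : list of str
        Covariates kept by the importance filter.
    single_pass : bool
        True when no refit happened (filter disabled or nothing dropped).
    """

    def __init__(self, model, ensemble, retained, column_index,
                 initial_importance, importance, single_pass, m_hat=None):
        self.model = model
        self.ensemble = ensemble
        self.retained_ = retained
        self._cols = column_index
        self.initial_importance_ = initial_importance
        self.importance_ = importance
        self.single_pass = single_pass
        self._oob_cache = None
        self._outcome_cache = None
        self._m_hat = m_hat

    def marginal_outcome(self) -> np.ndarray:
        """OOB marginal outcome fit m(x) (cached from local centering)."""
        if self._m_hat is None:
            self._m_hat = self.model.marginal_outcome_fit()
        return self._m_hat

    @property
    def config(self) -> ForestConfig:
        return self.model.config

    # -- prediction --------------------------------------------------------
    def _fit_matrix(self) -> np.ndarray:
        return self.model.X[:, self._cols]

    def predict(self, rows=None) -> pd.DataFrame:
        """CATE estimates with SEs and 95% CIs.

        ``rows=None`` returns out-of-bag estimates for the training data;
        otherwise ``rows`` is a DataFrame or an already-encoded matrix in
        the retained-covariate basis.
        """
        if rows is None:
            return self.predict_oob()
        if isinstance(rows, pd.DataFrame):
            X = self.model.encode_new(rows, self.retained_)
        else:
            X = np.asarray(rows, dtype=float)
            if X.shape[1] == len(self.model.covariate_names):
                X = X[:, self._cols]
            elif X.shape[1] != len(self.retained_):
                raise ValueError("rows do not carry the fitted covariates")
        preds = self.ensemble.predict_matrix(X)
        tau, se = self.ensemble.aggregate(preds, None)
        return _cate_frame(tau, se, np.zeros(len(tau), dtype=bool))

    def predict_oob(self) -> pd.DataFrame:
        if self._oob_cache is None:
            X = self._fit_matrix()
            preds = self.ensemble.predict_matrix(X)
            valid = ~self.ensemble.inbag
            tau, se = self.ensemble.aggregate(preds, valid)
            oob = valid.any(axis=1)
            if not oob.all():
                # fall back to the in-bag ensemble for fully covered rows
                tau_all, se_all = self.ensemble.aggregate(preds, None)
                tau = np.where(oob, tau, tau_all)
                se = np.where(oob, se, se_all)
            self._oob_cache = _cate_frame(tau, se, oob)
        return self._oob_cache.copy()

    # -- nuisance fits for AIPW ---------------------------------------------
    def outcome_predictions(self) -> tuple[np.ndarray, np.ndarray]:
        """(m0, m1): arm-wise honest regression-forest outcome fits.

        OOB predictions are used for rows in the forest's own arm.
        """
        if self._outcome_cache is None:
            X = self._fit_matrix()
            y, d = self.model.y, self.model.d
            out = {}
            # regression forests stabilize faster than causal ones; cap size
            ocfg = replace(self.config,
                           num_trees=max(100, min(self.config.num_trees, 500)))
            for arm in (0, 1):
                rows = np.where(d == arm)[0]
                ens = _fit_ensemble(X[rows], y[rows], None, ocfg,
                                    _kernels.MODE_REG,
                                    self.config.seed + 100 + arm)
                preds_all = ens.predict_matrix(X)
                m_all, _ = ens.aggregate(preds_all, None)
                valid = ~ens.inbag
                m_oob, _ = ens.aggregate(preds_all[rows], valid)
                m = m_all
                ok = valid.any(axis=1)
                m[rows[ok]] = m_oob[ok]
                out[arm] = m
            self._outcome_cache = (out[0], out[1])
        return self._outcome_cache

    def forest_weights(self, rows_X: np.ndarray) -> np.ndarray:
        """Adaptive neighbor weights over training rows for query rows.

        weight(x, i) averages, over trees, the indicator that training row i
        lies in x's leaf divided by the leaf's estimate-half size; rows sum
        to 1 for any query point reachable by at least one tree.
        """
        X_train = self._fit_matrix()
        leaves_q = self.ensemble.leaf_nodes(np.asarray(rows_X, dtype=float))
        leaves_t = self.ensemble.leaf_nodes(X_train)
        nq, B = leaves_q.shape
        n = leaves_t.shape[0]
        W = np.zeros((nq, n))
        for b in range(B):
            match = leaves_q[:, b][:, None] == leaves_t[:, b][None, :]
            size = match.sum(axis=1).astype(float)
            W += match / np.maximum(size, 1)[:, None]
        return W / B

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        cate = self.predict_oob()
        lines = [
            "Honest causal forest",
            "=" * 56,
            f"n = {len(self.model.y)}   trees = {self.ensemble.num_trees}"
            f"   propensity = {self.model.propensity:.3f}",
            f"covariates fitted: {len(self.retained_)} of "
            f"{len(self.model.covariate_names)}"
            + ("" if self.single_pass else " (importance-filtered refit)"),
            f"mean CATE (OOB): {cate['tau_hat'].mean():+.4f}",
            f"CATE range (OOB): [{cate['tau_hat'].min():+.4f}, "
            f"{cate['tau_hat'].max():+.4f}]",
            "top importances: " + ", ".join(
                f"{k}={v:.3f}" for k, v in sorted(
                    self.importance_.items(), key=lambda kv: -kv[1])[:5]),
        ]
        return "\n".join(lines)


class RegressionForest:
    """Honest regression forest (used for the arm-wise outcome models)."""

    def __init__(self, config: ForestConfig | None = None):
        self.config = config or ForestConfig()
        self._ens = None
        self._X = None

    def fit(self, X, y) -> "RegressionForest":
        self._X = np.ascontiguousarray(X, dtype=float)
        self._ens = _fit_ensemble(self._X, np.asarray(y, dtype=float), None,
                                  self.config, _kernels.MODE_REG,
                                  self.config.seed)
        return self

    def predict(self, X) -> np.ndarray:
        preds = self._ens.predict_matrix(np.asarray(X, dtype=float))
        mean, _ = self._ens.aggregate(preds, None)
        return mean

    def predict_oob(self) -> np.ndarray:
        preds = self._ens.predict_matrix(self._X)
        mean, _ = self._ens.aggregate(preds, ~self._ens.inbag)
        return mean


class CausalTree:
    """A single honest causal tree with explicit split/estimate samples.

    Mostly a testing and inspection surface; forests build their trees
    through the same kernel.  ``split_ids`` and ``estimate_ids`` must be
    disjoint row indices; the split half chooses the partition, the
    estimate half supplies every leaf effect.
    """

    def __init__(self, X, y, d, split_ids, estimate_ids,
                 config: ForestConfig | None = None, seed: int = 0,
                 mtry: int | None = None):
        config = config or ForestConfig()
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        d = np.ascontiguousarray(d, dtype=np.int64)
        sidx = np.asarray(split_ids, dtype=np.int64).copy()
        eidx = np.asarray(estimate_ids, dtype=np.int64).copy()
        if np.intersect1d(sidx, eidx).size:
            raise ValueError("split and estimate samples must be disjoint "
                             "(honesty)")
        for name, idx in (("split", sidx), ("estimate", eidx)):
            if len(np.unique(d[idx])) < 2:
                raise ValueError(f"an arm is absent from the {name} sample")
        p = X.shape[1]
        m = mtry if mtry is not None else p  # exhaustive by default
        max_depth = -1 if config.max_depth is None else int(config.max_depth)
        max_nodes = 2 * max(1, len(sidx) // max(1, config.min_leaf_per_arm)) + 3
        self.feature = np.empty(max_nodes, dtype=np.int64)
        self.threshold = np.empty(max_nodes, dtype=np.float64)
        self.left = np.empty(max_nodes, dtype=np.int64)
        self.right = np.empty(max_nodes, dtype=np.int64)
        self.value = np.empty(max_nodes, dtype=np.float64)
        self.depth = np.empty(max_nodes, dtype=np.int64)
        self.leaf_n1 = np.empty(max_nodes, dtype=np.int64)
        self.leaf_n0 = np.empty(max_nodes, dtype=np.int64)
        n_nodes = _kernels.build_tree(
            X, y, d, sidx, eidx, int(config.min_leaf_per_arm), m,
            max_depth, _kernels.MODE_CAUSAL, int(seed) % (2 ** 32 - 1),
            self.feature, self.threshold, self.left, self.right, self.value,
            self.depth, self.leaf_n1, self.leaf_n0)
        for arr in ("feature", "threshold", "left", "right", "value",
                    "depth", "leaf_n1", "leaf_n0"):
            setattr(self, arr, getattr(self, arr)[:n_nodes].copy())
        self.n_nodes = n_nodes
        self.split_ids = sidx
        self.estimate_ids = eidx

    @property
    def is_leaf_root(self) -> bool:
        return self.feature[0] < 0

    def root_split(self):
        """(feature index, threshold) of the first split, or None."""
        if self.is_leaf_root:
            return None
        return int(self.feature[0]), float(self.threshold[0])

    def apply(self, X) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        out = np.empty((X.shape[0], 1), dtype=np.int64)
        _kernels.apply_ensemble(self.feature, self.threshold, self.left,
                                self.right, np.array([0, self.n_nodes]),
                                X, out)
        return out[:, 0]

    def predict(self, X) -> np.ndarray:
        return self.value[self.apply(X)]

    def leaves(self) -> list[dict]:
        out = []
        for i in range(self.n_nodes):
            if self.feature[i] < 0:
                out.append({"node": i, "effect": float(self.value[i]),
                            "n_treated": int(self.leaf_n1[i]),
                            "n_control": int(self.leaf_n0[i]),
                            "depth": int(self.depth[i])})
        return out


def fit_causal_tree(trial: pd.DataFrame, config: ForestConfig | None,
                    split_ids, estimate_ids, seed: int = 0,
                    covariates: Sequence[str] | None = None) -> CausalTree:
    """One honest causal tree on a trial table with explicit honest halves."""
    cov = list(covariates) if covariates is not None else \
        [c for c in trial.columns if c not in RESERVED_COLUMNS]
    X, names = encode_covariates(trial, cov)
    tree = CausalTree(X, trial["Y"], trial["D"], split_ids, estimate_ids,
                      config=config, seed=seed)
    tree.covariate_names = names
    return tree


# ---------------------------------------------------------------------------
# functional wrappers over the model classes

def fit_causal_forest(trial: pd.DataFrame,
                      config: ForestConfig | None = None,
                      covariates: Sequence[str] | None = None,
                      propensity: float = 0.5,
                      two_pass: bool = True) -> CausalForestResults:
    """Two-pass importance-filtered honest causal forest on a trial table."""
    model = CausalForest.from_dataframe(trial, covariates=covariates,
                                        propensity=propensity, config=config)
    return model.fit(two_pass=two_pass)


def predict_cate(results: CausalForestResults, rows=None) -> pd.DataFrame:
    """Per-patient CATE estimates (OOB for training rows when rows is None)."""
    return results.predict(rows)


def grid_search_forest(trial: pd.DataFrame,
                       param_grid: dict[str, Sequence],
                       base_config: ForestConfig | None = None,
                       covariates: Sequence[str] | None = None,
                       propensity: float = 0.5,
                       num_trees: int | None = None):
    """Optional tuning: score candidate configurations by OOB AIPW error.

    ``param_grid`` maps ForestConfig field names (typically
    ``min_leaf_per_arm``, ``mtry``, ``subsample_fraction``) to candidate
    values; the full cross product is fitted and scored by the mean squared
    difference between the doubly robust scores and the out-of-bag
    predictions (an R-loss proxy for CATE error).  Returns
    ``(best_config, table)`` where table lists every candidate and score.
    No automatic tuning happens anywhere else; this is strictly opt-in.
    """
    from itertools import product

    from .aggregate import aipw_scores

    base = base_config or ForestConfig()
    if num_trees is not None:
        base = replace(base, num_trees=num_trees)
    keys = list(param_grid)
    rows = []
    best = (np.inf, base)
    for combo in product(*(param_grid[k] for k in keys)):
        cfg = replace(base, **dict(zip(keys, combo)))
        res = fit_causal_forest(trial, cfg, covariates=covariates,
                                propensity=propensity)
        scores = aipw_scores(res)
        err = float(np.mean((scores.gamma - scores.tau_oob) ** 2))
        rows.append({**dict(zip(keys, combo)), "oob_aipw_error": err})
        if err < best[0]:
            best = (err, cfg)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization: tree arrays + config + importances to structured JSON

def save_forest(results: CausalForestResults, path) -> None:
    import dataclasses as _dc
    import json
    from pathlib import Path

    ens = results.ensemble
    payload = {
        "format": "trialhte-causal-forest-v1",
        "config": _dc.asdict(results.config),
        "covariate_names": results.retained_,
        "all_covariate_names": results.model.covariate_names,
        "propensity": results.model.propensity,
        "importance": results.importance_,
        "initial_importance": results.initial_importance_,
        "single_pass": results.single_pass,
        "group_size": ens.group_size,
        "trees": {
            "feature": ens.feat.tolist(),
            "threshold": ens.thr.tolist(),
            "left": ens.left.tolist(),
            "right": ens.right.tolist(),
            "value": ens.value.tolist(),
            "depth": ens.depth.tolist(),
            "leaf_n1": ens.leaf_n1.tolist(),
            "leaf_n0": ens.leaf_n0.tolist(),
            "offsets": ens.offsets.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


class ForestPredictor:
    """Deserialized forest: prediction only (no OOB bookkeeping)."""

    def __init__(self, ensemble: _TreeEnsemble, names: list[str],
                 importance: dict, propensity: float):
        self.ensemble = ensemble
        self.covariate_names = names
        self.importance_ = importance
        self.propensity = propensity

    def predict(self, X) -> pd.DataFrame:
        X = np.asarray(X, dtype=float)
        preds = self.ensemble.predict_matrix(X)
        tau, se = self.ensemble.aggregate(preds, None)
        return _cate_frame(tau, se, np.zeros(len(tau), dtype=bool))


def load_forest(path) -> ForestPredictor:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    if d.get("format") != "trialhte-causal-forest-v1":
        raise ValueError("not a serialized trialhte causal forest")
    t = d["trees"]
    offsets = np.asarray(t["offsets"], dtype=np.int64)
    ens = _TreeEnsemble(
        np.asarray(t["feature"], dtype=np.int64),
        np.asarray(t["threshold"], dtype=np.float64),
        np.asarray(t["left"], dtype=np.int64),
        np.asarray(t["right"], dtype=np.int64),
        np.asarray(t["value"], dtype=np.float64),
        np.asarray(t["depth"], dtype=np.int64),
        np.asarray(t["leaf_n1"], dtype=np.int64),
        np.asarray(t["leaf_n0"], dtype=np.int64),
        offsets,
        np.zeros((0, len(offsets) - 1), dtype=bool),
        int(d["group_size"]), _kernels.MODE_CAUSAL)
    return ForestPredictor(ens, d["covariate_names"], d["importance"],
                           float(d["propensity"]))
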