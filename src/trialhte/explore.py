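"""Post-hoc description of estimated individual CATEs.

Once a forest has produced per-patient effect estimates tau_hat_i, three
summaries describe which covariate combinations drive them:

* a second-stage linear model E[tau_hat | X] = da + sum_j db_j X_j (the
  "effect explained by observables"),
* a cp-pruned CART on tau_hat (a split is kept only if it reduces error by
  at least cp times the root error — the convention of the standard
  recursive-partitioning software, implemented here as cost-complexity
  pruning with alpha = cp x root variance), and
* the "best tree" of a regression forest grown on tau_hat: the member tree
  whose predictions have the highest R^2 against the forest's aggregate
  predictions, with leaf depth controlled by a minimum leaf size minN.

CART leaf effects estimated on the same data that chose the splits are
optimistic, so honest re-estimation is supported: held-out AIPW scores are
dropped down the tree and each leaf's effect becomes the held-out group ATE
with a valid SE.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from .aggregate import AIPWScores, Z975

logger = logging.getLogger("trialhte")

__all__ = [
    "SecondStageLinearFit",
    "SubgroupTree",
    "second_stage_ols",
    "fit_pruned_cart",
    "honest_subgroup_ates",
    "best_tree",
    "r2_explained",
]


def _tau_array(cate) -> np.ndarray:
    if hasattr(cate, "columns"):
        return cate["tau_hat"].to_numpy(dtype=float)
    return np.asarray(cate, dtype=float).ravel()


def _design(covariates, names: Sequence[str] | None):
    if isinstance(covariates, pd.DataFrame):
        from .simulate import encode_covariates
        return encode_covariates(covariates,
                                 [c for c in covariates.columns])
    X = np.asarray(covariates, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


# ---------------------------------------------------------------------------
# second-stage linear model

@dataclass
class SecondStageLinearFit:
    """OLS of estimated CATEs on covariates."""

    intercept: float
    slopes: dict[str, float]
    r_squared: float
    dropped: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray, names: Sequence[str]) -> np.ndarray:
        out = np.full(X.shape[0], self.intercept)
        for j, name in enumerate(names):
            if name in self.slopes:
                out = out + self.slopes[name] * X[:, j]
        return out


def second_stage_ols(cate, covariates,
                     names: Sequence[str] | None = None
                     ) -> SecondStageLinearFit:
    """Least-squares fit of tau_hat on covariates with an intercept.

    Rank-deficient designs are handled by greedily dropping aliased columns
    (warned by name).
    """
    tau = _tau_array(cate)
    X, cols = _design(covariates, names)
    if len(np.unique(X, axis=0)) < 2:
        raise ValueError("need at least 2 distinct covariate rows")

    keep: list[int] = []
    dropped: list[str] = []
    base = np.ones((X.shape[0], 1))
    rank = 1
    for j in range(X.shape[1]):
        cand = np.column_stack([base, X[:, keep + [j]]])
        r = np.linalg.matrix_rank(cand)
        if r > rank + len(keep):
            keep.append(j)
        else:
            dropped.append(cols[j])
    if dropped:
        logger.warning("second-stage OLS dropped aliased columns: %s",
                       ", ".join(dropped))
    exog = sm.add_constant(X[:, keep], has_constant="add")
    fit = sm.OLS(tau, exog).fit()
    slopes = {cols[j]: float(b) for j, b in zip(keep, fit.params[1:])}
    return SecondStageLinearFit(float(fit.params[0]), slopes,
                                float(fit.rsquared), dropped)


# ---------------------------------------------------------------------------
# subgroup trees

@dataclass
class SubgroupTree:
    """Recursive-partition summary of CATEs.

    ``root`` is a nested node dict: internal nodes carry ``feature`` /
    ``feature_index`` / ``threshold`` / ``left`` / ``right``; every node has
    ``n`` and ``mean`` (training-sample mean tau_hat), and leaves carry a
    ``leaf_id``.  Honest re-estimation adds ``honest_estimate``/``honest_se``/
    ``honest_ci_low``/``honest_ci_high``/``honest_n`` (or
    ``honest_estimable: false``) to each leaf.
    """

    root: dict
    feature_names: list[str]
    cp: float | None = None
    min_leaf: int | None = None
    source: str = "cart"

    # -- structure ---------------------------------------------------------
    @property
    def leaf_count(self) -> int:
        return len(self.leaves())

    def leaves(self) -> list[dict]:
        out: list[dict] = []

        def rec(node):
            if "left" in node:
                rec(node["left"])
                rec(node["right"])
            else:
                out.append(node)

        rec(self.root)
        return out

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Leaf id for every row of X (routing rule: x <= threshold left)."""
        X = np.asarray(X, dtype=float)
        ids = np.empty(X.shape[0], dtype=np.int64)
        for i in range(X.shape[0]):
            node = self.root
            while "left" in node:
                if X[i, node["feature_index"]] <= node["threshold"]:
                    node = node["left"]
                else:
                    node = node["right"]
            ids[i] = node["leaf_id"]
        return ids

    def predict(self, X: np.ndarray) -> np.ndarray:
        by_id = {leaf["leaf_id"]: leaf["mean"] for leaf in self.leaves()}
        return np.array([by_id[i] for i in self.assign(X)])

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "cp": self.cp,
            "min_leaf": self.min_leaf,
            "source": self.source,
            "leaf_count": self.leaf_count,
            "root": self.root,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SubgroupTree":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(d["root"], d["feature_names"], d.get("cp"),
                   d.get("min_leaf"), d.get("source", "cart"))

    def to_text(self) -> str:
        """Indented plain-text rendering of the partition."""
        lines: list[str] = []

        def rec(node, indent, label):
            pad = "  " * indent
            stats = f"n={node['n']} mean_cate={node['mean']:+.4f}"
            if "honest_estimate" in node:
                stats += (f" honest={node['honest_estimate']:+.4f}"
                          f" (se {node['honest_se']:.4f})")
            elif node.get("honest_estimable") is False:
                stats += " honest=not-estimable"
            if "left" in node:
                lines.append(f"{pad}{label}{node['feature']} <= "
                             f"{node['threshold']:.6g} ? [{stats}]")
                rec(node["left"], indent + 1, "yes: ")
                rec(node["right"], indent + 1, "no:  ")
            else:
                lines.append(f"{pad}{label}leaf#{node['leaf_id']} [{stats}]")

        rec(self.root, 0, "")
        return "\n".join(lines)

    def leaf_table(self) -> pd.DataFrame:
        """One row per leaf: path, n, training mean, honest estimate/CI."""
        rows = []

        def rec(node, path):
            if "left" in node:
                cond = f"{node['feature']}<={node['threshold']:.6g}"
                rec(node["left"], path + [cond])
                rec(node["right"], path + [f"{node['feature']}>"
                                           f"{node['threshold']:.6g}"])
            else:
                rows.append({
                    "leaf_id": node["leaf_id"],
                    "path": " & ".join(path) if path else "(root)",
                    "n": node["n"],
                    "mean_cate": node["mean"],
                    "honest_estimate": node.get("honest_estimate", np.nan),
                    "honest_se": node.get("honest_se", np.nan),
                    "honest_ci_low": node.get("honest_ci_low", np.nan),
                    "honest_ci_high": node.get("honest_ci_high", np.nan),
                    "honest_n": node.get("honest_n", 0),
                    "honest_estimable": node.get("honest_estimable", None),
                })

        rec(self.root, [])
        return pd.DataFrame(rows).sort_values("leaf_id").reset_index(drop=True)


def _tree_from_sklearn(sk_tree, names: list[str], X: np.ndarray,
                       tau: np.ndarray, cp=None, min_leaf=None,
                       source="cart") -> SubgroupTree:
    """Convert a fitted sklearn tree, recomputing node stats on (X, tau)."""
    t = sk_tree.tree_
    assign = sk_tree.apply(X)
    leaf_counter = [0]

    def rec(node_id, rows):
        n = int(rows.sum())
        mean = float(tau[rows].mean()) if n else float("nan")
        if t.children_left[node_id] == -1:
            leaf = {"n": n, "mean": mean, "leaf_id": leaf_counter[0]}
            leaf_counter[0] += 1
            return leaf
        f = int(t.feature[node_id])
        thr = float(t.threshold[node_id])
        go_left = rows & (X[:, f] <= thr)
        return {
            "n": n, "mean": mean,
            "feature": names[f], "feature_index": f, "threshold": thr,
            "left": rec(t.children_left[node_id], go_left),
            "right": rec(t.children_right[node_id], rows & ~go_left),
        }

    _ = assign  # assignment recomputed from thresholds for exactness
    root = rec(0, np.ones(len(tau), dtype=bool))
    return SubgroupTree(root, names, cp=cp, min_leaf=min_leaf, source=source)


def fit_pruned_cart(cate, covariates, cp: float = 0.2,
                    names: Sequence[str] | None = None,
                    min_leaf: int = 1,
                    max_leaves: int | None = None,
                    weights=None) -> SubgroupTree:
    """Variance-reduction CART on tau_hat, pruned at complexity cp.

    A split survives pruning only if it reduces the tree's error by more
    than cp times the root error (cost-complexity pruning with
    alpha = cp x root variance; boundary-equality splits are pruned, so
    cp = 1 always collapses to the root).  ``weights`` optionally
    inverse-variance-weights the fit; ``max_leaves`` searches for the
    smallest cp at or above the requested one that yields at most that
    many leaves.
    """
    if cp < 0:
        raise ValueError("cp must be >= 0")
    tau = _tau_array(cate)
    X, cols = _design(covariates, names)
    root_err = float(np.var(tau))
    # nudge above the boundary so equality-improvement splits are pruned
    # (cp = 1 always collapses to the root even for a perfect split)
    alpha = cp * root_err * (1.0 + 1e-9)
    sk = DecisionTreeRegressor(min_samples_leaf=min_leaf, ccp_alpha=alpha,
                               random_state=0)
    sk.fit(X, tau, sample_weight=weights)
    if max_leaves is not None and sk.get_n_leaves() > max_leaves:
        path = DecisionTreeRegressor(
            min_samples_leaf=min_leaf, random_state=0
        ).cost_complexity_pruning_path(X, tau, sample_weight=weights)
        for a in np.unique(path.ccp_alphas):
            if a <= alpha:
                continue
            sk = DecisionTreeRegressor(min_samples_leaf=min_leaf,
                                       ccp_alpha=a, random_state=0)
            sk.fit(X, tau, sample_weight=weights)
            if sk.get_n_leaves() <= max_leaves:
                break
    return _tree_from_sklearn(sk, cols, X, tau, cp=cp, min_leaf=min_leaf)


def honest_subgroup_ates(tree: SubgroupTree, scores: AIPWScores,
                         covariates, names: Sequence[str] | None = None,
                         min_per_arm: int = 2) -> SubgroupTree:
    """Re-estimate each leaf's effect on held-out AIPW scores.

    The held-out rows must be disjoint from the rows that grew the tree.
    A leaf receiving fewer than ``min_per_arm`` held-out rows in either arm
    is flagged not-estimable (no exception).  Training-sample leaf means are
    retained alongside for comparison.
    """
    X, cols = _design(covariates, names)
    if cols != tree.feature_names:
        # allow a superset design as long as indices line up by name
        index = {c: j for j, c in enumerate(cols)}
        missing = [c for c in tree.feature_names if c not in index]
        if missing:
            raise ValueError(f"held-out design lacks columns {missing}")
    ids = tree.assign(_reindex(X, cols, tree.feature_names))
    gamma = np.asarray(scores.gamma, dtype=float)
    d = scores.d if scores.d is not None else None

    for leaf in tree.leaves():
        mask = ids == leaf["leaf_id"]
        n_g = int(mask.sum())
        ok = n_g >= 2
        if ok and d is not None:
            ok = (int(d[mask].sum()) >= min_per_arm
                  and int((1 - d[mask]).sum()) >= min_per_arm)
        if not ok:
            leaf["honest_estimable"] = False
            leaf["honest_n"] = n_g
            continue
        vals = gamma[mask]
        est = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(n_g))
        leaf.update({
            "honest_estimable": True,
            "honest_n": n_g,
            "honest_estimate": est,
            "honest_se": se,
            "honest_ci_low": est - Z975 * se,
            "honest_ci_high": est + Z975 * se,
        })
    return tree


def _reindex(X: np.ndarray, cols: list[str], want: list[str]) -> np.ndarray:
    if cols == want:
        return X
    index = {c: j for j, c in enumerate(cols)}
    return X[:, [index[c] for c in want]]


def best_tree(cate, covariates, minN: int = 50, num_trees: int = 200,
              seed: int = 0, names: Sequence[str] | None = None
              ) -> SubgroupTree:
    """Most-representative member tree of a regression forest on tau_hat.

    Fits a forest with per-leaf minimum ``minN`` and returns the member tree
    whose predictions have the highest R^2 against the forest's aggregate
    predictions (ties to the lowest tree index).
    """
    if minN < 1:
        raise ValueError("minN must be >= 1")
    tau = _tau_array(cate)
    X, cols = _design(covariates, names)
    rf = RandomForestRegressor(n_estimators=num_trees,
                               min_samples_leaf=min(minN, len(tau)),
                               random_state=seed & 0x7FFFFFFF)
    rf.fit(X, tau)
    agg = rf.predict(X)
    best_idx, best_r2 = 0, -np.inf
    for i, est in enumerate(rf.estimators_):
        r2 = r2_explained(est.predict(X), agg)
        if np.isnan(r2):
            r2 = -np.inf
        if r2 > best_r2:
            best_idx, best_r2 = i, r2
    tree = _tree_from_sklearn(rf.estimators_[best_idx], cols, X, tau,
                              min_leaf=minN, source="best_tree")
    tree.r2_vs_forest = best_r2
    return tree


def r2_explained(predictions, cate, which: str = "in_sample") -> float:
    """Proportion of variation in tau_hat explained: 1 - SSE/SST.

    SST is taken against the mean of the evaluation set, so out-of-sample
    values can be negative.  Zero SST returns NaN with a warning.
    """
    if which not in ("in_sample", "out_of_sample"):
        raise ValueError("which must be 'in_sample' or 'out_of_sample'")
    pred = np.asarray(predictions, dtype=float).ravel()
    tau = _tau_array(cate)
    if len(pred) != len(tau):
        raise ValueError("predictions and CATEs disagree on length")
    sst = float(np.sum((tau - tau.mean()) ** 2))
    if sst == 0.0:
        logger.warning("zero variance in evaluation CATEs; R^2 undefined")
        return float("nan")
    sse = float(np.sum((tau - pred) ** 2))
    return 1.0 - sse / sst
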