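"""Chained-equation multiple imputation and Rubin's-rules pooling.

Baseline covariates with missing cells are imputed by iterative chained
regressions: linear models with predictive-mean matching (5 donors) for
continuous variables, logistic draws for binaries, multinomial draws for
categoricals, initialized from observed-value draws.  Treatment, outcome and
the synthetic truth columns are never touched (the emulated trial had no
missing outcomes).

Estimates computed on each of the m completed datasets are pooled with
Rubin's rules: pooled estimate Q_bar = mean of the per-imputation estimates,
within-variance W = mean of the per-imputation variances, between-variance
B = sample variance of the estimates, total variance T = W + (1 + 1/m) B,
degrees of freedom (m - 1)(1 + W / ((1 + 1/m) B))^2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, LogisticRegression

from .simulate import covariate_columns

logger = logging.getLogger("trialhte")

__all__ = ["ImputationSet", "RubinCombined", "mice_impute", "rubin_combine",
           "pool_cate_frames"]

_PMM_DONORS = 5


@dataclass
class ImputationSet:
    """m completed trial tables plus the imputation audit record."""

    tables: list[pd.DataFrame]
    methods: dict[str, str]
    seed: int
    iterations: int

    @property
    def m(self) -> int:
        return len(self.tables)

    def write(self, directory: str | Path, stem: str = "imputed") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for j, tab in enumerate(self.tables, start=1):
            tab.to_csv(directory / f"{stem}_{j}.csv", index=False, na_rep="")
        manifest = {"m": self.m, "seed": self.seed,
                    "iterations": self.iterations, "methods": self.methods}
        (directory / f"{stem}_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))


@dataclass
class RubinCombined:
    """Rubin's-rules pooled estimate across imputations."""

    estimate: float          # Q_bar
    within: float            # W
    between: float           # B
    total_variance: float    # T = W + (1 + 1/m) B
    df: float
    ci_low: float
    ci_high: float
    m: int

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate, "within": self.within,
            "between": self.between, "total_variance": self.total_variance,
            "df": self.df, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "m": self.m,
        }


def _column_kind(s: pd.Series) -> str:
    if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
        return "multinomial"
    vals = pd.unique(s.dropna())
    if len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
        return "logistic"
    return "pmm"


def _predictor_matrix(df: pd.DataFrame, cols: list[str],
                      exclude: str) -> np.ndarray:
    parts = []
    for c in cols:
        if c == exclude:
            continue
        s = df[c]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            dummies = pd.get_dummies(s.astype(str))
            parts.append(dummies.to_numpy(dtype=float)[:, 1:])
        else:
            v = np.asarray(s, dtype=float)
            sd = v.std()
            if sd > 0:  # standardized predictors keep the solvers stable
                v = (v - v.mean()) / sd
            parts.append(v[:, None])
    return np.hstack(parts) if parts else np.zeros((len(df), 0))


def mice_impute(trial: pd.DataFrame, m: int = 5, iterations: int = 10,
                seed: int = 0) -> ImputationSet:
    """Multiply impute missing covariate cells by chained equations."""
    if m < 1:
        raise ValueError("m must be >= 1")
    cov_cols = covariate_columns(trial)
    if trial["D"].isna().any() or trial["Y"].isna().any():
        raise ValueError("missingness must be confined to covariates")
    fully_missing = [c for c in cov_cols if trial[c].isna().all()]
    if fully_missing:
        raise ValueError(
            f"variable(s) 100% missing, cannot impute: {fully_missing}")
    incomplete = [c for c in cov_cols if trial[c].isna().any()]
    methods = {c: _column_kind(trial[c]) for c in incomplete}

    if not incomplete:
        return ImputationSet([trial.copy() for _ in range(m)], {},
                             seed, iterations)

    tables = []
    for j in range(m):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, j]))
        work = trial.copy()
        # initialize from observed-value draws
        for c in incomplete:
            miss = work[c].isna()
            obs = work.loc[~miss, c].to_numpy()
            fill = obs[rng.integers(0, len(obs), size=int(miss.sum()))]
            work.loc[miss, c] = fill
        for _ in range(iterations):
            for c in incomplete:
                miss = trial[c].isna().to_numpy()
                Xp = _predictor_matrix(work, cov_cols, exclude=c)
                _impute_column(work, c, Xp, miss, methods[c], rng)
        tables.append(work)
    return ImputationSet(tables, methods, seed, iterations)


def _impute_column(work: pd.DataFrame, c: str, Xp: np.ndarray,
                   miss: np.ndarray, kind: str,
                   rng: np.random.Generator) -> None:
    obs = ~miss
    if kind == "pmm":
        y_obs = work.loc[obs, c].to_numpy(dtype=float)
        if np.ptp(y_obs) == 0:
            work.loc[miss, c] = y_obs[0]
            return
        reg = LinearRegression().fit(Xp[obs], y_obs)
        pred_obs = reg.predict(Xp[obs])
        pred_mis = reg.predict(Xp[miss])
        # type-1 PMM: draw one of the nearest donors by predicted value
        order = np.argsort(pred_obs)
        pos = np.searchsorted(pred_obs[order], pred_mis)
        filled = np.empty(len(pred_mis))
        for i, p in enumerate(pos):
            lo = max(0, p - _PMM_DONORS)
            hi = min(len(order), p + _PMM_DONORS)
            donors = order[lo:hi]
            dist = np.abs(pred_obs[donors] - pred_mis[i])
            near = donors[np.argsort(dist)[:_PMM_DONORS]]
            filled[i] = y_obs[near[rng.integers(0, len(near))]]
        work.loc[miss, c] = filled
    elif kind == "logistic":
        y_obs = work.loc[obs, c].to_numpy(dtype=float)
        if len(np.unique(y_obs)) < 2:
            work.loc[miss, c] = y_obs[0]
            return
        clf = LogisticRegression(max_iter=1000).fit(Xp[obs], y_obs)
        p1 = clf.predict_proba(Xp[miss])[:, 1]
        draws = (rng.uniform(size=len(p1)) < p1).astype(work[c].dtype
                                                        if work[c].dtype.kind == "i"
                                                        else float)
        work.loc[miss, c] = draws
    else:  # multinomial
        y_obs = work.loc[obs, c].astype(str).to_numpy()
        classes = np.unique(y_obs)
        if len(classes) < 2:
            work.loc[miss, c] = y_obs[0]
            return
        clf = LogisticRegression(max_iter=1000).fit(Xp[obs], y_obs)
        probs = clf.predict_proba(Xp[miss])
        cum = probs.cumsum(axis=1)
        u = rng.uniform(size=len(probs))[:, None]
        idx = (u > cum).sum(axis=1)
        work.loc[miss, c] = clf.classes_[idx]


def rubin_combine(estimates, variances) -> RubinCombined:
    """Pool m estimates and their variances with Rubin's formulae."""
    q = np.asarray(estimates, dtype=float).ravel()
    w = np.asarray(variances, dtype=float).ravel()
    m = len(q)
    if m < 2:
        raise ValueError("rubin_combine needs m >= 2 estimates")
    if len(w) != m:
        raise ValueError("estimates and variances disagree on m")
    if np.any(w < 0):
        raise ValueError("variances must be nonnegative")
    qbar = float(q.mean())
    W = float(w.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
    else:
        df = float("inf")
    half = stats.t.ppf(0.975, df) * np.sqrt(T) if T > 0 else 0.0
    return RubinCombined(qbar, W, B, T, float(df),
                         qbar - float(half), qbar + float(half), m)


def pool_cate_frames(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Rubin-pool per-patient CATE estimates across imputations.

    Frames are matched on ``patient_id`` (or row order when absent); each
    must carry ``tau_hat`` and ``se``.  Returns a frame with pooled tau_hat,
    se = sqrt(T), and 95% CI.
    """
    if len(frames) < 2:
        raise ValueError("pooling needs at least 2 imputations")
    keyed = []
    for f in frames:
        g = f.copy()
        if "patient_id" not in g.columns:
            g["patient_id"] = np.arange(len(g))
        keyed.append(g.sort_values("patient_id").reset_index(drop=True))
    ids = keyed[0]["patient_id"].to_numpy()
    for g in keyed[1:]:
        if not np.array_equal(g["patient_id"].to_numpy(), ids):
            raise ValueError("imputations disagree on patient ids")
    m = len(keyed)
    taus = np.column_stack([g["tau_hat"].to_numpy() for g in keyed])
    ses = np.column_stack([g["se"].to_numpy() for g in keyed])
    qbar = taus.mean(axis=1)
    W = (ses ** 2).mean(axis=1)
    B = taus.var(axis=1, ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    se = np.sqrt(T)
    z = 1.959963984540054
    return pd.DataFrame({
        "patient_id": ids,
        "tau_hat": qbar,
        "se": se,
        "ci_low": qbar - z * se,
        "ci_high": qbar + z * se,
        "m": m,
    })
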