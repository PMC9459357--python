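"""Fixed-parametric comparator: subgroup logistic models with recycled
predictions (G-computation) and nonparametric-bootstrap uncertainty.

For a binary subgroup indicator G the model is the standard subgroup
logistic regression

    logit P(Y=1) = b0 + bG G + a1 D + a2 D G

(an intercept is included; without it this is not the subgroup model trial
analyses fit).  Recycled predictions evaluate every patient's predicted
outcome under each (treatment, subgroup) combination; the subgroup total
effect is mean[Yhat(1,1) - Yhat(0,1)] and the interaction contrast
mean[Yhat(1,1) - (Yhat(0,1) + Yhat(1,0) - Yhat(0,0))], both on the
risk-difference scale.  Multi-level subgroups are handled by one-vs-rest
indicator fits per level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .aggregate import GroupATEResult

logger = logging.getLogger("trialhte")

__all__ = [
    "SeparationError",
    "SubgroupLogit",
    "SubgroupLogitResults",
    "GComputationContrasts",
    "BootstrapResult",
    "fit_subgroup_model",
    "gcomp_effects",
    "bootstrap_ci",
    "logistic_group_ate",
]


class SeparationError(RuntimeError):
    """Raised when a (treatment x subgroup) cell separates the outcome."""


@dataclass
class GComputationContrasts:
    """Recycled predictions under each (d, g) and the derived contrasts."""

    predictions: pd.DataFrame  # columns y_d0_g0, y_d1_g0, y_d0_g1, y_d1_g1
    total_effect: float
    interaction_effect: float


@dataclass
class BootstrapResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_replicates: int
    n_failed: int


class SubgroupLogit:
    """Subgroup logistic model of a binary outcome in a two-arm trial.

    ``link="logit"`` is the maximum-likelihood logistic fit; ``link="identity"``
    fits the linear-probability variant (for which the interaction contrast
    equals a2 exactly).
    """

    def __init__(self, outcome, treatment, group, link: str = "logit"):
        self.y = np.asarray(outcome, dtype=float).ravel()
        self.d = np.asarray(treatment, dtype=float).ravel()
        self.g = np.asarray(group, dtype=float).ravel()
        if link not in ("logit", "identity"):
            raise ValueError("link must be 'logit' or 'identity'")
        self.link = link
        if not (len(self.y) == len(self.d) == len(self.g)):
            raise ValueError("outcome, treatment, group disagree on n")
        for name, v in (("treatment", self.d), ("group", self.g)):
            if set(np.unique(v)) - {0.0, 1.0}:
                raise ValueError(f"{name} must be coded 0/1")

    @classmethod
    def from_dataframe(cls, trial: pd.DataFrame, group,
                       outcome: str = "Y", treatment: str = "D",
                       link: str = "logit") -> "SubgroupLogit":
        g = trial[group] if isinstance(group, str) else group
        return cls(trial[outcome], trial[treatment], g, link=link)

    def _check_cells(self) -> None:
        msgs = []
        for dv in (0, 1):
            for gv in (0, 1):
                cell = (self.d == dv) & (self.g == gv)
                n = int(cell.sum())
                ev = int(self.y[cell].sum())
                if n == 0:
                    msgs.append(f"(D={dv}, G={gv}) empty")
                elif ev == 0:
                    msgs.append(f"(D={dv}, G={gv}) has no events")
                elif ev == n:
                    msgs.append(f"(D={dv}, G={gv}) has no non-events")
        if msgs:
            raise SeparationError(
                "separated/degenerate cells: " + "; ".join(msgs))

    def fit(self) -> "SubgroupLogitResults":
        if self.link == "logit":
            self._check_cells()
        exog = np.column_stack([np.ones_like(self.y), self.g, self.d,
                                self.d * self.g])
        if self.link == "logit":
            fit = sm.Logit(self.y, exog).fit(disp=False, maxiter=200)
            if not fit.mle_retvals.get("converged", True):
                raise SeparationError("logistic fit failed to converge")
        else:
            fit = sm.OLS(self.y, exog).fit()
        params = np.asarray(fit.params, dtype=float)
        if not np.all(np.isfinite(params)):
            raise SeparationError("non-finite coefficients in subgroup fit")
        return SubgroupLogitResults(self, fit, params)


class SubgroupLogitResults:
    """Fitted subgroup model; coefficients (b0, bG, a1, a2)."""

    def __init__(self, model: SubgroupLogit, fit, params: np.ndarray):
        self.model = model
        self._fit = fit
        self.intercept = float(params[0])
        self.beta_g = float(params[1])
        self.alpha1 = float(params[2])
        self.alpha2 = float(params[3])
        self.params = params

    def _predict(self, d: float, g: float) -> float:
        eta = (self.intercept + self.beta_g * g + self.alpha1 * d
               + self.alpha2 * d * g)
        if self.model.link == "logit":
            return float(1.0 / (1.0 + np.exp(-eta)))
        return float(eta)

    def gcomp_effects(self) -> GComputationContrasts:
        """Recycled-prediction contrasts on the risk-difference scale."""
        n = len(self.model.y)
        cells = {f"y_d{d}_g{g}": np.full(n, self._predict(d, g))
                 for d in (0, 1) for g in (0, 1)}
        preds = pd.DataFrame(cells)
        total = float(np.mean(cells["y_d1_g1"] - cells["y_d0_g1"]))
        interaction = float(np.mean(
            cells["y_d1_g1"]
            - (cells["y_d0_g1"] + cells["y_d1_g0"] - cells["y_d0_g0"])))
        return GComputationContrasts(preds, total, interaction)

    def summary(self) -> str:
        gc = self.gcomp_effects()
        return "\n".join([
            f"Subgroup {self.model.link} model (n = {len(self.model.y)})",
            "=" * 48,
            f"intercept  {self.intercept:+.4f}",
            f"beta_G     {self.beta_g:+.4f}",
            f"alpha1 (D) {self.alpha1:+.4f}",
            f"alpha2 (DxG) {self.alpha2:+.4f}",
            f"subgroup total effect (risk diff): {gc.total_effect:+.4f}",
            f"interaction contrast:              {gc.interaction_effect:+.4f}",
        ])


def fit_subgroup_model(trial: pd.DataFrame, group_indicator,
                       link: str = "logit") -> SubgroupLogitResults:
    return SubgroupLogit.from_dataframe(trial, group_indicator,
                                        link=link).fit()


def gcomp_effects(results: SubgroupLogitResults) -> GComputationContrasts:
    return results.gcomp_effects()


def bootstrap_ci(effect_fn, trial: pd.DataFrame, B_boot: int = 1000,
                 seed: int = 0, max_failure_rate: float = 0.2
                 ) -> BootstrapResult:
    """Case-resampling bootstrap of a full fit-and-contrast procedure.

    ``effect_fn(trial) -> float`` runs the whole procedure on one resample.
    Returns the SD of the replicates and the 2.5/97.5 percentile CI.
    Replicates that raise (e.g. separation in a small cell) are counted;
    more than ``max_failure_rate`` of them is an error.
    """
    if B_boot < 100:
        raise ValueError("B_boot must be at least 100")
    n = len(trial)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        0xB007]))
    estimate = float(effect_fn(trial))
    reps = []
    failed = 0
    for _ in range(B_boot):
        idx = rng.integers(0, n, size=n)
        sample = trial.iloc[idx].reset_index(drop=True)
        try:
            reps.append(float(effect_fn(sample)))
        except Exception:
            failed += 1
    if failed > max_failure_rate * B_boot:
        raise RuntimeError(
            f"bootstrap unstable: {failed}/{B_boot} replicates failed")
    reps = np.asarray(reps)
    se = float(reps.std(ddof=1)) if len(reps) > 1 else 0.0
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapResult(estimate, se, float(lo), float(hi),
                           len(reps), failed)


def logistic_group_ate(trial: pd.DataFrame, group_indicator, label: str,
                       B_boot: int = 1000, seed: int = 0) -> GroupATEResult:
    """Forest-plot row for one subgroup from the logistic comparator."""
    g = np.asarray(group_indicator, dtype=float)

    def _effect(df: pd.DataFrame) -> float:
        gg = np.asarray(df["_g"], dtype=float)
        if gg.min() == gg.max():
            # constant indicator (e.g. the overall row): treatment-only model
            exog = np.column_stack([np.ones(len(df)), df["D"]])
            fitres = sm.Logit(np.asarray(df["Y"], dtype=float),
                              exog).fit(disp=False)
            b0, a1 = map(float, fitres.params)
            p1 = 1.0 / (1.0 + np.exp(-(b0 + a1)))
            p0 = 1.0 / (1.0 + np.exp(-b0))
            return p1 - p0
        res = SubgroupLogit(df["Y"], df["D"], gg).fit()
        return res.gcomp_effects().total_effect

    work = trial[["Y", "D"]].copy()
    work["_g"] = g
    boot = bootstrap_ci(_effect, work, B_boot=B_boot, seed=seed)
    return GroupATEResult(label, int(g.sum()), boot.estimate, boot.se,
                          boot.ci_low, boot.ci_high, method="logistic_gcomp")
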