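"""Omnibus calibration / heterogeneity test for forest CATE estimates.

Best-linear-predictor construction: regress the doubly robust scores
Gamma_i on two regressors without an intercept —

* the mean out-of-bag forest prediction tau_bar (a constant regressor), and
* the demeaned out-of-bag prediction tau_hat_i - tau_bar,

with heteroskedasticity-robust (HC3) standard errors.  A coefficient of 1 on
the first ("ATE") regressor means the mean forest prediction is correct; a
coefficient of 1 on the second ("heterogeneity") regressor means the spread
of the forest's predictions matches the spread of the true effects.  The ATE
coefficient is tested two-sided against 1; the heterogeneity coefficient is
tested one-sided against 0, so a small p-value is evidence that the forest
found real heterogeneity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .aggregate import AIPWScores

logger = logging.getLogger("trialhte")

__all__ = ["OmnibusResult", "omnibus_test"]


@dataclass
class OmnibusResult:
    """Outcome of the omnibus calibration/heterogeneity test."""

    ate_coefficient: float
    ate_se: float
    ate_p: float
    het_coefficient: float | None
    het_se: float | None
    het_p_one_sided: float
    n: int
    het_estimable: bool = True

    def to_dict(self) -> dict:
        return {
            "ate_coefficient": self.ate_coefficient,
            "ate_se": self.ate_se,
            "ate_p": self.ate_p,
            "het_coefficient": self.het_coefficient,
            "het_se": self.het_se,
            "het_p": self.het_p_one_sided,
            "het_estimable": self.het_estimable,
            "n": self.n,
        }


def omnibus_test(scores: AIPWScores, oob_cate=None) -> OmnibusResult:
    """Run the omnibus test on AIPW scores and out-of-bag CATEs.

    ``oob_cate`` may be a CATE DataFrame (column ``tau_hat``) or an array;
    by default the predictions stored in ``scores`` are used.
    """
    gamma = np.asarray(scores.gamma, dtype=float)
    if oob_cate is None:
        tau = np.asarray(scores.tau_oob, dtype=float)
    elif hasattr(oob_cate, "columns"):
        tau = oob_cate["tau_hat"].to_numpy(dtype=float)
    else:
        tau = np.asarray(oob_cate, dtype=float)
    n = len(gamma)
    if len(tau) != n:
        raise ValueError("scores and predictions disagree on n")

    tau_bar = tau.mean()
    demeaned = tau - tau_bar
    if np.allclose(demeaned, 0.0):
        logger.info("forest predictions are constant; heterogeneity "
                    "coefficient not estimable")
        fit = sm.OLS(gamma, np.full((n, 1), tau_bar)).fit(cov_type="HC3")
        ate_b = float(fit.params[0])
        ate_se = float(fit.bse[0])
        ate_p = _two_sided_against_one(ate_b, ate_se, fit.df_resid)
        return OmnibusResult(ate_b, ate_se, ate_p, None, None, 1.0, n,
                             het_estimable=False)

    exog = np.column_stack([np.full(n, tau_bar), demeaned])
    fit = sm.OLS(gamma, exog).fit(cov_type="HC3")
    ate_b, het_b = (float(fit.params[0]), float(fit.params[1]))
    ate_se, het_se = (float(fit.bse[0]), float(fit.bse[1]))
    ate_p = _two_sided_against_one(ate_b, ate_se, fit.df_resid)
    t_het = het_b / het_se
    het_p = float(stats.t.sf(t_het, df=fit.df_resid))
    return OmnibusResult(ate_b, ate_se, ate_p, het_b, het_se, het_p, n)


def _two_sided_against_one(b: float, se: float, df: float) -> float:
    if se == 0 or not np.isfinite(se):
        return float("nan")
    t = (b - 1.0) / se
    return float(2.0 * stats.t.sf(abs(t), df=df))
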