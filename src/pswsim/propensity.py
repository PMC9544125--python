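"""Propensity-score estimation and discrimination diagnostics.

The propensity model is a main-effects logistic regression of treatment
on the ten baseline covariates, fit by iteratively reweighted least
squares (IRLS).  The fit is re-run thousands of times inside the
bootstrap, so the solver is a small, fast Newton loop with a tiny ridge
fallback on the Hessian for the rare degenerate resample; any fallback
use is recorded on the returned fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .errors import FitFailureError

__all__ = ["PropensityFit", "fit_propensity", "c_statistic"]

logger = logging.getLogger(__name__)

_MAX_ITER = 50
_SCORE_TOL = 1e-8
_RIDGE = 1e-8
_COEF_LIMIT = 100.0


@dataclass
class PropensityFit:
    """Result of a logistic propensity-model fit.

    ``coefficients`` holds the intercept followed by the ten slopes;
    ``fitted_ps`` are the in-sample predicted treatment probabilities.
    """

    coefficients: np.ndarray
    fitted_ps: np.ndarray
    converged: bool
    used_ridge: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted propensity for a (possibly new) covariate matrix."""
        return expit(self.coefficients[0] + X @ self.coefficients[1:])


def fit_propensity(X: np.ndarray, Z: np.ndarray) -> PropensityFit:
    """Maximum-likelihood logistic regression of Z on X (with intercept).

    Raises :class:`FitFailureError` on perfect separation (diverging
    coefficients) or non-convergence; callers in the replication engine
    record the failure and move on.
    """
    Z = np.asarray(Z, dtype=float)
    n1 = Z.sum()
    if n1 == 0 or n1 == Z.shape[0]:
        raise FitFailureError("one treatment group is empty")
    n = X.shape[0]
    Xd = np.empty((n, X.shape[1] + 1))
    Xd[:, 0] = 1.0
    Xd[:, 1:] = X

    beta = np.zeros(Xd.shape[1])
    # start from the null model: intercept = logit of the prevalence
    beta[0] = np.log(n1 / (n - n1))
    used_ridge = False
    converged = False
    for _ in range(_MAX_ITER):
        p = expit(Xd @ beta)
        score = Xd.T @ (Z - p)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        w = p * (1.0 - p)
        H = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            used_ridge = True
            logger.warning("singular Hessian in IRLS; applying ridge %g", _RIDGE)
            H.flat[:: H.shape[0] + 1] += _RIDGE
            step = np.linalg.solve(H, score)
        # dampen overly aggressive Newton steps
        step_max = np.max(np.abs(step))
        if step_max > 10.0:
            step *= 10.0 / step_max
        beta = beta + step
        if np.max(np.abs(beta)) > _COEF_LIMIT:
            raise FitFailureError("coefficients diverged (likely separation)")
    if not converged:
        p = expit(Xd @ beta)
        score = Xd.T @ (Z - p)
        if np.max(np.abs(score)) >= 1e-6:
            raise FitFailureError("IRLS did not converge")
    fitted = expit(Xd @ beta)
    eps = np.finfo(float).tiny
    fitted = np.clip(fitted, eps, 1.0 - eps)
    return PropensityFit(beta, fitted, converged, used_ridge)


def c_statistic(ps: np.ndarray, Z: np.ndarray) -> float:
    """Concordance (AUC) between a score and treatment status.

    Rank-based Mann-Whitney form over all treated x control pairs; ties
    count one half.
    """
    ps = np.asarray(ps, dtype=float)
    Z = np.asarray(Z)
    n1 = int(np.sum(Z == 1))
    n0 = int(np.sum(Z == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic requires both treatment groups")
    ranks = rankdata(ps)
    u = ranks[Z == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
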