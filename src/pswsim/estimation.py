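"""Weighted effect estimation with asymptotic and bootstrap standard errors.

Point estimates are Hajek (normalized-weight) contrasts of weighted group
means: the difference in means for the continuous outcome, and the risk
difference and log relative risk for the binary outcome.

The asymptotic standard error comes from M-estimation: the logistic score
equations for the propensity parameters beta are stacked with the two
weighted-mean equations

    sum_i w1(x_i; beta) Z_i (Y_i - mu1) = 0
    sum_i w0(x_i; beta) (1 - Z_i) (Y_i - mu0) = 0

and the empirical sandwich Var(theta) = A^{-1} B A^{-T} / n is evaluated
with analytic derivatives, including d w / d beta through e(x; beta).
Because the propensity parameters are part of the stack, the uncertainty
from estimating the propensity score propagates into the effect SE.

The bootstrap SE re-runs the entire pipeline (propensity fit, optional
trimming, weighting, point estimation) on each resample and takes the
standard deviation of the point estimates across resamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .dgp import Sample, TrimSpec
from .errors import EstimateUndefinedError, FitFailureError, TrimmingError
from .propensity import PropensityFit, fit_propensity
from .weighting import FAMILIES, WeightVector, apply_trimming_workflow, compute_weights

__all__ = [
    "EffectEstimate",
    "weighted_group_means",
    "point_estimates",
    "sandwich_variance",
    "bootstrap_estimates",
    "bootstrap_se",
    "normal_ci",
]


@dataclass
class EffectEstimate:
    """Point estimate with both standard errors and a normal-theory CI."""

    estimand: str
    family: str
    point: float
    se_asymptotic: float
    se_bootstrap: float | None
    ci_low: float
    ci_high: float
    n_bootstrap_used: int = 0
    bootstrap_warning: bool = False


def weighted_group_means(
    Y: np.ndarray, Z: np.ndarray, w: WeightVector | np.ndarray
) -> tuple[float, float]:
    """Hajek weighted mean of Y in the treated and control groups."""
    values = w.values if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    Y = np.asarray(Y, dtype=float)
    treated = np.asarray(Z) == 1
    s1 = values[treated].sum()
    s0 = values[~treated].sum()
    if s1 <= 0.0 or s0 <= 0.0:
        raise EstimateUndefinedError("zero total weight in a treatment group")
    mu1 = float(values[treated] @ Y[treated] / s1)
    mu0 = float(values[~treated] @ Y[~treated] / s0)
    return mu1, mu0


def point_estimates(mu1: float, mu0: float, outcome_type: str) -> dict[str, float]:
    """Map group means to estimands.

    ``outcome_type='continuous'`` yields the difference in means;
    ``'binary'`` yields the risk difference and the log relative risk.
    """
    if outcome_type == "continuous":
        return {"mean_diff": mu1 - mu0}
    if outcome_type == "binary":
        out = {"risk_diff": mu1 - mu0}
        if mu1 <= 0.0 or mu0 <= 0.0:
            raise EstimateUndefinedError(
                "log relative risk undefined: a group has zero event proportion"
            )
        out["log_rr"] = float(np.log(mu1 / mu0))
        return out
    raise ValueError(f"unknown outcome_type {outcome_type!r}")


def _weights_and_derivative(
    e: np.ndarray, Z: np.ndarray, family: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject (w1, w0, dw1/de, dw0/de) for the stacked equations.

    Derivatives are with respect to the propensity e.  The matching-weight
    function has a kink at e = 0.5; the one-sided derivative is used there,
    which affects a measure-zero set.
    """
    one = np.ones_like(e)
    zero = np.zeros_like(e)
    if family == "ATE":
        w1, dw1 = 1.0 / e, -1.0 / e**2
        w0, dw0 = 1.0 / (1.0 - e), 1.0 / (1.0 - e) ** 2
    elif family == "ATT":
        w1, dw1 = one, zero
        w0 = e / (1.0 - e)
        dw0 = 1.0 / (1.0 - e) ** 2
    elif family == "MW":
        low = e < 0.5
        w1 = np.where(low, 1.0, (1.0 - e) / e)
        dw1 = np.where(low, 0.0, -1.0 / e**2)
        w0 = np.where(low, e / (1.0 - e), 1.0)
        dw0 = np.where(low, 1.0 / (1.0 - e) ** 2, 0.0)
    elif family == "OW":
        w1, dw1 = 1.0 - e, -one
        w0, dw0 = e, one
    else:
        raise ValueError(f"unknown weight family {family!r}")
    return w1, w0, dw1, dw0


def stacked_estimating_equations(
    theta: np.ndarray, X: np.ndarray, Z: np.ndarray, Y: np.ndarray, family: str
) -> np.ndarray:
    """Evaluate the n x (p+2) matrix of per-subject estimating functions.

    theta = (beta_0, ..., beta_p, mu1, mu0).  Exposed for the
    finite-difference cross-checks of the analytic bread matrix.
    """
    p = X.shape[1] + 1
    beta, mu1, mu0 = theta[:p], theta[p], theta[p + 1]
    Xd = np.column_stack([np.ones(X.shape[0]), X])
    e = expit(Xd @ beta)
    Z = np.asarray(Z, dtype=float)
    w1, w0, _, _ = _weights_and_derivative(e, Z, family)
    psi = np.empty((X.shape[0], p + 2))
    psi[:, :p] = (Z - e)[:, None] * Xd
    psi[:, p] = w1 * Z * (Y - mu1)
    psi[:, p + 1] = w0 * (1.0 - Z) * (Y - mu0)
    return psi


def _mu_covariance(
    X: np.ndarray, Z: np.ndarray, Y: np.ndarray, family: str, fit: PropensityFit
) -> tuple[float, float, np.ndarray]:
    """Hajek means and their 2x2 sandwich covariance for one outcome."""
    n = X.shape[0]
    p = X.shape[1] + 1
    Xd = np.column_stack([np.ones(n), X])
    e = fit.fitted_ps
    Z = np.asarray(Z, dtype=float)
    Y = np.asarray(Y, dtype=float)
    w1, w0, dw1, dw0 = _weights_and_derivative(e, Z, family)

    s1 = (w1 * Z).sum()
    s0 = (w0 * (1.0 - Z)).sum()
    if s1 <= 0.0 or s0 <= 0.0:
        raise EstimateUndefinedError("zero total weight in a treatment group")
    mu1 = float((w1 * Z) @ Y / s1)
    mu0 = float((w0 * (1.0 - Z)) @ Y / s0)

    # bread A = -(1/n) sum d psi_i / d theta
    A = np.zeros((p + 2, p + 2))
    v = e * (1.0 - e)  # d e / d eta
    A[:p, :p] = (Xd * v[:, None]).T @ Xd / n
    A[p, :p] = -(Z * (Y - mu1) * dw1 * v) @ Xd / n
    A[p + 1, :p] = -((1.0 - Z) * (Y - mu0) * dw0 * v) @ Xd / n
    A[p, p] = s1 / n
    A[p + 1, p + 1] = s0 / n

    theta = np.concatenate([fit.coefficients, [mu1, mu0]])
    psi = stacked_estimating_equations(theta, X, Z, Y, family)
    B = psi.T @ psi / n

    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise EstimateUndefinedError("singular bread matrix in sandwich variance") from exc
    V = Ainv @ B @ Ainv.T / n
    return mu1, mu0, V[p:, p:]


def sandwich_variance(
    X: np.ndarray,
    Z: np.ndarray,
    Y: np.ndarray,
    family: str,
    fit: PropensityFit,
    outcome_type: str = "continuous",
) -> dict[str, float]:
    """Asymptotic SE of each estimand from the stacked-equation sandwich.

    Delta-method gradients on (mu1, mu0): (1, -1) for the mean or risk
    difference and (1/mu1, -1/mu0) for the log relative risk.
    """
    mu1, mu0, cov = _mu_covariance(X, Z, Y, family, fit)
    out: dict[str, float] = {}
    g_diff = np.array([1.0, -1.0])
    var_diff = float(g_diff @ cov @ g_diff)
    if outcome_type == "continuous":
        out["mean_diff"] = float(np.sqrt(max(var_diff, 0.0)))
        return out
    out["risk_diff"] = float(np.sqrt(max(var_diff, 0.0)))
    if mu1 > 0.0 and mu0 > 0.0:
        g_lrr = np.array([1.0 / mu1, -1.0 / mu0])
        out["log_rr"] = float(np.sqrt(max(float(g_lrr @ cov @ g_lrr), 0.0)))
    return out


def _pipeline_points(sample: Sample, trim: TrimSpec, families) -> dict[tuple[str, str], float]:
    """Full pipeline on one (re)sample: fit, trim, weight, point estimates."""
    analysed, fit, _ = apply_trimming_workflow(sample, trim)
    out: dict[tuple[str, str], float] = {}
    for family in families:
        w = compute_weights(fit.fitted_ps, analysed.Z, family)
        mu1c, mu0c = weighted_group_means(analysed.y_cont, analysed.Z, w)
        out[(family, "mean_diff")] = mu1c - mu0c
        mu1b, mu0b = weighted_group_means(analysed.y_bin, analysed.Z, w)
        out[(family, "risk_diff")] = mu1b - mu0b
        if mu1b > 0.0 and mu0b > 0.0:
            out[(family, "log_rr")] = float(np.log(mu1b / mu0b))
        else:
            raise EstimateUndefinedError("zero event proportion in resample")
    return out


def bootstrap_estimates(
    sample: Sample,
    B: int,
    seed: int | np.random.Generator,
    trim: TrimSpec = "none",
    families=FAMILIES,
) -> tuple[dict[tuple[str, str], np.ndarray], int]:
    """Point estimates across B bootstrap resamples, all families at once.

    Each resample draws n subjects with replacement (unstratified) and
    re-runs the full pipeline, so propensity-estimation and trimming
    uncertainty propagate into the bootstrap distribution.  Degenerate
    resamples (separation, an empty or event-free group) are dropped;
    the number of successful resamples is returned alongside.
    """
    if B < 2:
        raise ValueError("need at least two bootstrap resamples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws: dict[tuple[str, str], list[float]] = {}
    n_used = 0
    for _ in range(B):
        idx = rng.integers(0, sample.n, size=sample.n)
        resample = sample.subset(idx)
        try:
            points = _pipeline_points(resample, trim, families)
        except (FitFailureError, EstimateUndefinedError, TrimmingError, ValueError):
            continue
        n_used += 1
        for key, value in points.items():
            draws.setdefault(key, []).append(value)
    if n_used == 0:
        raise EstimateUndefinedError("all bootstrap resamples failed")
    arrays = {k: np.asarray(v) for k, v in draws.items()}
    return arrays, n_used


def bootstrap_se(
    sample: Sample,
    family: str,
    B: int = 200,
    seed: int | np.random.Generator = 0,
    trim: TrimSpec = "none",
) -> tuple[dict[str, float], int]:
    """Bootstrap SE (SD across resamples, divisor B-1) for one family."""
    draws, n_used = bootstrap_estimates(sample, B, seed, trim, families=(family,))
    ses = {est: float(np.std(v, ddof=1)) for (_, est), v in draws.items()}
    return ses, n_used


def normal_ci(point: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory confidence interval point +/- z * se."""
    if se < 0:
        raise ValueError("se must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = norm.ppf(0.5 * (1.0 + level))
    return point - z * se, point + z * se
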