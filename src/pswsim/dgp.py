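"""Data-generating process for the weighting simulation study.

A super-population of (by default) one million subjects carries ten
baseline covariates: five standard normals and five binary indicators
obtained by thresholding standard normals at fixed quantiles so their
prevalences are 10%, 20%, 30%, 40% and 50%.  All ten latent normals are
equicorrelated with pairwise correlation 0.2.

Treatment is assigned by a logistic model on the ten covariates whose
intercept is calibrated by bisection to hit a target marginal prevalence.
Two outcomes are generated per subject, each as a pair of potential
outcomes (under control and under treatment):

* a continuous outcome from a linear model with a homogeneous treatment
  effect of +2 and an error variance calibrated so the covariates explain
  25% of the outcome variance among untreated subjects;
* a binary outcome from a logistic model whose intercept is calibrated to
  a control-arm prevalence of 0.2 and whose treatment log-odds ratio is
  calibrated so the population-average risk difference is -0.02.

An optional ``sigma_scale`` multiplies every treatment-model slope,
weakening (<1) or strengthening (>1) confounding and thereby the overlap
of the propensity distributions; an optional ``interactions`` flag adds
treatment-by-covariate product terms to both outcome models with
coefficients equal to one quarter of the corresponding main effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import CalibrationError, EstimateUndefinedError

__all__ = [
    "TREATMENT_COEFS",
    "CONTINUOUS_OUTCOME_COEFS",
    "BINARY_OUTCOME_COEFS",
    "BINARY_PREVALENCES",
    "CONTINUOUS_TREATMENT_EFFECT",
    "CalibrationResult",
    "ScenarioConfig",
    "Sample",
    "SuperPopulation",
    "generate_covariates",
    "treatment_linear_predictor",
    "calibrate_treatment_intercept",
    "assign_treatment",
    "outcome_linear_predictor",
    "calibrate_error_variance",
    "generate_continuous_potential_outcomes",
    "binary_outcome_linear_predictor",
    "calibrate_outcome_intercept",
    "calibrate_treatment_log_odds",
    "generate_binary_potential_outcomes",
    "build_super_population",
    "draw_sample",
    "true_estimands",
]

#: log-odds ratios of the ten covariates in the treatment-selection model
TREATMENT_COEFS = np.log(
    [1.1, 1.2, 1.5, 1.75, 2.0, 1.25, 1.5, 2.0, 0.8, 0.5]
)

#: slopes of the ten covariates in the linear (continuous) outcome model
CONTINUOUS_OUTCOME_COEFS = np.array(
    [2.5, 2.0, 1.5, 1.0, 0.5, 2.0, 1.0, 5.0, 4.0, 3.0]
)

#: log-odds ratios of the ten covariates in the logistic (binary) outcome model
BINARY_OUTCOME_COEFS = np.log(
    [2.0, 1.75, 1.1, 1.5, 1.2, 2.0, 1.5, 1.1, 1.25, 2.0]
)

#: target prevalences of the five dichotomized covariates (columns 6-10)
BINARY_PREVALENCES = np.array([0.10, 0.20, 0.30, 0.40, 0.50])

#: homogeneous treatment effect on the continuous outcome
CONTINUOUS_TREATMENT_EFFECT = 2.0

#: ratio of interaction to main-effect coefficients in the sensitivity DGP
INTERACTION_RATIO = 0.25

_COVARIATE_CORRELATION = 0.2
_BISECTION_BRACKET = (-20.0, 20.0)
_BISECTION_TOL = 1e-4
_BISECTION_MAX_ITER = 200

TrimSpec = Union[float, Literal["none", "crump"]]


@dataclass(frozen=True)
class CalibrationResult:
    """Model constants determined by bisection on the super-population."""

    alpha0_treat: float
    alpha0_outcome: float
    alpha_treat: float
    sigma2_error: float


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario of the factorial design."""

    n_sample: int
    target_prevalence: float
    sigma_scale: float = 1.0
    interactions: bool = False
    trim: TrimSpec = "none"
    n_replicates: int = 1000
    n_bootstrap: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if self.sigma_scale <= 0:
            raise ValueError("sigma_scale must be positive")
        if isinstance(self.trim, (int, float)) and not isinstance(self.trim, bool):
            if not 0.0 <= float(self.trim) < 0.5:
                raise ValueError("fixed trimming threshold must lie in [0, 0.5)")
        elif self.trim not in ("none", "crump"):
            raise ValueError("trim must be a float, 'none' or 'crump'")


@dataclass
class Sample:
    """One analysis sample drawn from the super-population."""

    X: np.ndarray
    Z: np.ndarray
    y_cont: np.ndarray
    y_bin: np.ndarray

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    def subset(self, idx: np.ndarray) -> "Sample":
        return Sample(self.X[idx], self.Z[idx], self.y_cont[idx], self.y_bin[idx])


@dataclass
class SuperPopulation:
    """Fixed synthetic population with both potential outcomes per subject."""

    covariates: np.ndarray
    true_ps: np.ndarray
    treatment: np.ndarray
    y_cont_0: np.ndarray
    y_cont_1: np.ndarray
    y_bin_0: np.ndarray
    y_bin_1: np.ndarray
    calibration: CalibrationResult
    config: ScenarioConfig | None = None

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def y_cont(self) -> np.ndarray:
        """Observed continuous outcome (potential outcome selected by Z)."""
        return np.where(self.treatment == 1, self.y_cont_1, self.y_cont_0)

    @property
    def y_bin(self) -> np.ndarray:
        return np.where(self.treatment == 1, self.y_bin_1, self.y_bin_0)


def _rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_covariates(n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Generate the n x 10 covariate matrix.

    Latent covariates are equicorrelated standard normals (rho = 0.2),
    realised as ``sqrt(rho) * g + sqrt(1 - rho) * e_j`` with a shared
    factor ``g``.  Columns 6-10 are dichotomized at the fixed normal
    quantiles 1 - p for p = 0.10 ... 0.50, so their prevalences hold in
    expectation regardless of the sample drawn.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = _rng(seed)
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, 10))
    X = np.sqrt(_COVARIATE_CORRELATION) * shared + np.sqrt(1 - _COVARIATE_CORRELATION) * unique
    thresholds = norm.ppf(1.0 - BINARY_PREVALENCES)
    X[:, 5:] = (X[:, 5:] > thresholds).astype(float)
    return X


def treatment_linear_predictor(
    X: np.ndarray, alpha0: float, sigma_scale: float = 1.0
) -> np.ndarray:
    """Linear predictor of the treatment-selection logistic model.

    Every slope is multiplied by ``sigma_scale``; the intercept is not.
    """
    return alpha0 + sigma_scale * (X @ TREATMENT_COEFS)


def _bisect(f, target: float, tol: float = _BISECTION_TOL) -> float:
    """Bisection for the root of ``f(x) - target`` with f nondecreasing.

    Converges on the target scale: stops when |f(mid) - target| <= tol.
    """
    lo, hi = _BISECTION_BRACKET
    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo <= target <= f_hi):
        raise CalibrationError(
            f"target {target} outside bracket response [{f_lo}, {f_hi}]"
        )
    for _ in range(_BISECTION_MAX_ITER):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid - target) <= tol:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach tolerance {tol} in {_BISECTION_MAX_ITER} iterations"
    )


def calibrate_treatment_intercept(
    X: np.ndarray,
    target_prevalence: float,
    sigma_scale: float = 1.0,
    tol: float = _BISECTION_TOL,
) -> float:
    """Find the treatment-model intercept giving the target prevalence.

    Calibrates against the mean of the subject-level treatment
    probabilities (not realised Bernoulli draws), which removes one layer
    of Monte Carlo noise.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie in (0, 1)")
    slope_part = sigma_scale * (X @ TREATMENT_COEFS)
    return _bisect(lambda a0: expit(a0 + slope_part).mean(), target_prevalence, tol)


def assign_treatment(ps: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Draw independent Bernoulli treatment indicators with parameters ``ps``."""
    ps = np.asarray(ps)
    if np.any((ps <= 0.0) | (ps >= 1.0)):
        raise ValueError("all propensities must lie strictly in (0, 1)")
    rng = _rng(seed)
    return (rng.random(ps.shape) < ps).astype(np.int8)


def outcome_linear_predictor(X: np.ndarray) -> np.ndarray:
    """Covariate part of the continuous-outcome model (no intercept, Z = 0)."""
    return X @ CONTINUOUS_OUTCOME_COEFS


def calibrate_error_variance(X: np.ndarray) -> float:
    """Error variance giving R^2 = 0.25 among untreated subjects.

    With Y(0) = LP + eps, R^2 = Var(LP) / (Var(LP) + sigma^2) = 1/4
    requires sigma^2 = 3 Var(LP).
    """
    if X.shape[0] < 2:
        raise ValueError("need at least two subjects")
    v = float(np.var(outcome_linear_predictor(X)))
    if v <= 0.0:
        raise CalibrationError("outcome linear predictor has zero variance")
    return 3.0 * v


def generate_continuous_potential_outcomes(
    X: np.ndarray,
    sigma2: float,
    interactions: bool = False,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous potential outcomes (Y(0), Y(1)) with a shared error draw.

    The same N(0, sigma^2) error enters both potential outcomes, so without
    interactions the subject-level effect Y(1) - Y(0) is exactly 2.  With
    interactions the effect is 2 + 0.25 * LP(x) where LP is the covariate
    linear predictor.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = _rng(seed)
    lp = outcome_linear_predictor(X)
    eps = rng.normal(0.0, np.sqrt(sigma2), size=X.shape[0])
    y0 = lp + eps
    effect = CONTINUOUS_TREATMENT_EFFECT + (INTERACTION_RATIO * lp if interactions else 0.0)
    y1 = y0 + effect
    return y0, y1


def binary_outcome_linear_predictor(X: np.ndarray) -> np.ndarray:
    """Covariate part of the binary-outcome logistic model (no intercept, Z = 0)."""
    return X @ BINARY_OUTCOME_COEFS


def calibrate_outcome_intercept(
    X: np.ndarray, target_prev: float = 0.2, tol: float = _BISECTION_TOL
) -> float:
    """Intercept of the binary-outcome model giving the control-arm prevalence."""
    if not 0.0 < target_prev < 1.0:
        raise ValueError("target_prev must lie in (0, 1)")
    lp = binary_outcome_linear_predictor(X)
    return _bisect(lambda a0: expit(a0 + lp).mean(), target_prev, tol)


def calibrate_treatment_log_odds(
    X: np.ndarray,
    alpha0_outcome: float,
    target_rd: float = -0.02,
    interactions: bool = False,
    tol: float = _BISECTION_TOL,
) -> float:
    """Treatment log-odds ratio giving the target average risk difference.

    Bisects on the super-population mean of p(1) - p(0), the event
    probabilities under treatment and control, rather than on realised
    potential outcomes.
    """
    lp = binary_outcome_linear_predictor(X)
    p0 = expit(alpha0_outcome + lp)
    inter = INTERACTION_RATIO * lp if interactions else 0.0

    def mean_rd(alpha_treat: float) -> float:
        p1 = expit(alpha0_outcome + alpha_treat + lp + inter)
        return float((p1 - p0).mean())

    return _bisect(mean_rd, target_rd, tol)


def generate_binary_potential_outcomes(
    X: np.ndarray,
    calib: CalibrationResult,
    interactions: bool = False,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary potential outcomes realised from one shared uniform per subject.

    The comonotone coupling (same uniform thresholded against p(0) and
    p(1)) leaves all marginal means and hence all estimands untouched;
    only subject-level joint contrasts depend on it.
    """
    rng = _rng(seed)
    lp = binary_outcome_linear_predictor(X)
    inter = INTERACTION_RATIO * lp if interactions else 0.0
    p0 = expit(calib.alpha0_outcome + lp)
    p1 = expit(calib.alpha0_outcome + calib.alpha_treat + lp + inter)
    u = rng.random(X.shape[0])
    return (u < p0).astype(np.int8), (u < p1).astype(np.int8)


def build_super_population(
    n: int,
    target_prevalence: float,
    sigma_scale: float = 1.0,
    interactions: bool = False,
    seed: int | np.random.SeedSequence = 0,
) -> SuperPopulation:
    """Generate and fully calibrate a super-population.

    Calibration order: treatment intercept -> error variance -> outcome
    intercept -> treatment log-odds ratio; each step conditions on the
    previous ones, mirroring the two-stage bisection of the study design.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cov, s_treat, s_cont, s_bin = ss.spawn(4)
    X = generate_covariates(n, np.random.default_rng(s_cov))
    alpha0_treat = calibrate_treatment_intercept(X, target_prevalence, sigma_scale)
    true_ps = expit(treatment_linear_predictor(X, alpha0_treat, sigma_scale))
    Z = assign_treatment(true_ps, np.random.default_rng(s_treat))

    sigma2 = calibrate_error_variance(X)
    y_cont_0, y_cont_1 = generate_continuous_potential_outcomes(
        X, sigma2, interactions, np.random.default_rng(s_cont)
    )

    alpha0_outcome = calibrate_outcome_intercept(X, 0.2)
    alpha_treat = calibrate_treatment_log_odds(
        X, alpha0_outcome, -0.02, interactions=interactions
    )
    calib = CalibrationResult(alpha0_treat, alpha0_outcome, alpha_treat, sigma2)
    y_bin_0, y_bin_1 = generate_binary_potential_outcomes(
        X, calib, interactions, np.random.default_rng(s_bin)
    )
    return SuperPopulation(
        covariates=X,
        true_ps=true_ps,
        treatment=Z,
        y_cont_0=y_cont_0,
        y_cont_1=y_cont_1,
        y_bin_0=y_bin_0,
        y_bin_1=y_bin_1,
        calibration=calib,
    )


def draw_sample(
    pop: SuperPopulation, n: int, seed: int | np.random.Generator
) -> Sample:
    """Draw a simple random sample (without replacement) of size n."""
    if n > pop.n:
        raise ValueError("sample size exceeds super-population size")
    rng = _rng(seed)
    idx = rng.choice(pop.n, size=n, replace=False)
    Z = pop.treatment[idx]
    y_cont = np.where(Z == 1, pop.y_cont_1[idx], pop.y_cont_0[idx])
    y_bin = np.where(Z == 1, pop.y_bin_1[idx], pop.y_bin_0[idx])
    return Sample(pop.covariates[idx], Z, y_cont, y_bin.astype(np.int8))


_TILTING = {
    "ATE": lambda e: np.ones_like(e),
    "ATT": lambda e: e,
    "MW": lambda e: np.minimum(e, 1.0 - e),
    "OW": lambda e: e * (1.0 - e),
}


def true_estimands(pop: SuperPopulation, family: str) -> dict[str, float]:
    """True target estimands of a weight family via its tilting function.

    Each family estimates the contrast E[h(X) (Y(1) - Y(0))] / E[h(X)]
    with h = 1 (ATE), e (ATT), min(e, 1-e) (matching weights) or e(1-e)
    (overlap weights), evaluated on the super-population with the *true*
    propensity score.  Returns the mean difference (continuous outcome)
    and the risk difference and log relative risk (binary outcome).
    """
    if family not in _TILTING:
        raise ValueError(f"unknown weight family {family!r}")
    h = _TILTING[family](pop.true_ps)
    total = h.sum()
    if total <= 0 or not np.isfinite(total):
        raise EstimateUndefinedError("tilting function sums to zero")
    m1 = float(h @ pop.y_cont_1 / total)
    m0 = float(h @ pop.y_cont_0 / total)
    r1 = float(h @ pop.y_bin_1 / total)
    r0 = float(h @ pop.y_bin_0 / total)
    return {
        "mean_diff": m1 - m0,
        "risk_diff": r1 - r0,
        "log_rr": float(np.log(r1 / r0)),
    }
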