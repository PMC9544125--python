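"""Covariate balance, effective sample size and overlap diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .errors import EstimateUndefinedError
from .weighting import WeightVector

__all__ = [
    "BalanceReport",
    "weighted_smd",
    "balance_report",
    "effective_sample_size",
    "overlapping_coefficient",
]


@dataclass
class BalanceReport:
    """Weighted balance and effective-sample-size summary for one family."""

    smd_per_covariate: np.ndarray
    max_abs_smd: float
    ess_treated: float
    ess_control: float
    ess_total: float

    def to_row(self) -> dict[str, float]:
        row = {f"smd_x{j + 1}": float(s) for j, s in enumerate(self.smd_per_covariate)}
        row.update(
            max_abs_smd=self.max_abs_smd,
            ess_treated=self.ess_treated,
            ess_control=self.ess_control,
            ess_total=self.ess_total,
        )
        return row


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    mean = float(w @ x / sw)
    # reliability-weight denominator: reduces to n-1 at unit weights
    denom = sw - float(w @ w) / sw
    if denom <= 0.0:
        return mean, 0.0
    var = float(w @ (x - mean) ** 2 / denom)
    return mean, var


def weighted_smd(x: np.ndarray, Z: np.ndarray, w: WeightVector | np.ndarray) -> float:
    """Weighted standardized mean difference of one covariate.

    (xbar_1w - xbar_0w) / sqrt((s1w^2 + s0w^2) / 2) with weighted group
    means and variances.  A zero pooled variance returns 0 when the means
    agree and +/-inf otherwise.
    """
    values = w.values if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    treated = np.asarray(Z) == 1
    if values[treated].sum() <= 0 or values[~treated].sum() <= 0:
        raise EstimateUndefinedError("zero total weight in a treatment group")
    m1, v1 = _weighted_mean_var(x[treated], values[treated])
    m0, v0 = _weighted_mean_var(x[~treated], values[~treated])
    pooled = 0.5 * (v1 + v0)
    if pooled == 0.0:
        return 0.0 if m1 == m0 else float(np.sign(m1 - m0) * np.inf)
    return (m1 - m0) / float(np.sqrt(pooled))


def balance_report(X: np.ndarray, Z: np.ndarray, w: WeightVector | np.ndarray) -> BalanceReport:
    """Per-covariate weighted SMDs plus Kish effective sample sizes."""
    smds = np.array([weighted_smd(X[:, j], Z, w) for j in range(X.shape[1])])
    ess1, ess0, ess_total = effective_sample_size(w, Z)
    return BalanceReport(smds, float(np.max(np.abs(smds))), ess1, ess0, ess_total)


def effective_sample_size(
    w: WeightVector | np.ndarray, Z: np.ndarray
) -> tuple[float, float, float]:
    """Kish effective sample size (sum w)^2 / sum w^2 per group and total."""
    values = w.values if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    treated = np.asarray(Z) == 1
    out = []
    for grp in (treated, ~treated):
        wg = values[grp]
        out.append(float(wg.sum() ** 2 / (wg**2).sum()) if wg.size else 0.0)
    return out[0], out[1], out[0] + out[1]


def overlapping_coefficient(
    ps_treated: np.ndarray, ps_control: np.ndarray, grid_size: int = 512
) -> float:
    """Complement of the overlap between two propensity densities.

    Kernel density estimates (Gaussian kernel, Silverman bandwidth) of the
    two groups' propensity scores are evaluated on a common grid over
    [0, 1] and 1 - integral of min(f1, f0) is returned: 0 means the
    densities coincide, 1 means they do not overlap at all.
    """
    ps_treated = np.asarray(ps_treated, dtype=float)
    ps_control = np.asarray(ps_control, dtype=float)
    if ps_treated.size < 2 or ps_control.size < 2:
        raise ValueError("each group needs at least two subjects")
    if np.std(ps_treated) == 0.0 or np.std(ps_control) == 0.0:
        raise EstimateUndefinedError("degenerate (zero-variance) propensity group")
    grid = np.linspace(0.0, 1.0, grid_size)
    f1 = gaussian_kde(ps_treated, bw_method="silverman")(grid)
    f0 = gaussian_kde(ps_control, bw_method="silverman")(grid)
    ovl = float(np.trapezoid(np.minimum(f1, f0), grid))
    return float(np.clip(1.0 - ovl, 0.0, 1.0))
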