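"""Balancing weights and propensity-score trimming.

Four weight families are supported, each defined by the estimated
propensity score e and treatment indicator Z:

========  ==================  ==================  =======================
family    treated weight      control weight      target population
========  ==================  ==================  =======================
ATE       1 / e               1 / (1 - e)         whole population
ATT       1                   e / (1 - e)         the treated
MW        min(e, 1-e) / e     min(e, 1-e)/(1-e)   equipoise (matching)
OW        1 - e               e                   equipoise (overlap)
========  ==================  ==================  =======================

Trimming removes subjects whose estimated propensity falls outside
[delta, 1 - delta], either for a fixed delta or for the sample-optimal
threshold of Crump et al., after which the propensity model is re-fit on
the retained subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .dgp import Sample, TrimSpec
from .errors import TrimmingError
from .propensity import PropensityFit, fit_propensity

__all__ = [
    "FAMILIES",
    "WeightVector",
    "TrimResult",
    "compute_weights",
    "trim_fixed",
    "crump_threshold",
    "apply_trimming_workflow",
]

FAMILIES = ("ATE", "ATT", "MW", "OW")


@dataclass
class WeightVector:
    """Subject-level balancing weights for one family."""

    values: np.ndarray
    family: str
    source_ps: np.ndarray


@dataclass
class TrimResult:
    """Outcome of a trimming step."""

    kept_indices: np.ndarray
    threshold: float
    method: Literal["none", "fixed", "crump"]


def compute_weights(ps: np.ndarray, Z: np.ndarray, family: str) -> WeightVector:
    """Evaluate one weight family at the given propensity scores."""
    ps = np.asarray(ps, dtype=float)
    if np.any((ps <= 0.0) | (ps >= 1.0)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    Z = np.asarray(Z)
    treated = Z == 1
    w = np.empty_like(ps)
    if family == "ATE":
        w[treated] = 1.0 / ps[treated]
        w[~treated] = 1.0 / (1.0 - ps[~treated])
    elif family == "ATT":
        w[treated] = 1.0
        w[~treated] = ps[~treated] / (1.0 - ps[~treated])
    elif family == "MW":
        m = np.minimum(ps, 1.0 - ps)
        w[treated] = m[treated] / ps[treated]
        w[~treated] = m[~treated] / (1.0 - ps[~treated])
    elif family == "OW":
        w[treated] = 1.0 - ps[treated]
        w[~treated] = ps[~treated]
    else:
        raise ValueError(f"unknown weight family {family!r}")
    return WeightVector(w, family, ps)


def trim_fixed(ps: np.ndarray, delta: float) -> TrimResult:
    """Keep subjects with delta <= ps <= 1 - delta (closed interval)."""
    if not 0.0 <= delta < 0.5:
        raise ValueError("delta must lie in [0, 0.5)")
    ps = np.asarray(ps, dtype=float)
    kept = np.flatnonzero((ps >= delta) & (ps <= 1.0 - delta))
    return TrimResult(kept, float(delta), "none" if delta == 0.0 else "fixed")


def crump_threshold(ps: np.ndarray) -> float:
    """Sample-optimal trimming threshold of Crump et al.

    Solves for the smallest alpha in [0, 0.5] with

        1 / (alpha (1 - alpha))
            = 2 * mean{ 1 / (e_i (1 - e_i)) : e_i (1 - e_i) >= alpha (1 - alpha) }.

    Writing u_i = 1 / (e_i (1 - e_i)) and gamma = 1 / (alpha (1 - alpha)),
    the condition becomes the fixed point gamma = 2 * mean{u_i : u_i <= gamma};
    the retained-set boundary only moves at sample values of u, so the fixed
    point is found exactly by scanning the sorted u_i as candidate cut levels.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.shape[0] < 2:
        raise ValueError("need at least two subjects")
    if np.any((ps <= 0.0) | (ps >= 1.0)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    u = np.sort(1.0 / (ps * (1.0 - ps)))
    prefix_mean = np.cumsum(u) / np.arange(1, u.shape[0] + 1)
    g = 2.0 * prefix_mean
    # fixed point lies in [u_(k), u_(k+1)) for the largest k where it fits
    upper = np.append(u[1:], np.inf)
    feasible = (g >= u) & (g < upper)
    if not np.any(feasible):
        raise TrimmingError("no admissible Crump threshold found")
    gamma = g[np.flatnonzero(feasible)[-1]]
    # invert gamma = 1 / (alpha (1 - alpha)) on alpha in [0, 0.5]
    return float(0.5 * (1.0 - np.sqrt(1.0 - 4.0 / gamma)))


def apply_trimming_workflow(
    sample: Sample, trim: TrimSpec, initial_fit: PropensityFit | None = None
) -> tuple[Sample, PropensityFit, TrimResult]:
    """Trim a sample on its fitted propensity and re-fit the model.

    The propensity model is first fit on the full sample (unless an
    initial fit is supplied); subjects outside the retention interval are
    dropped and the model is re-estimated on the retained subjects.  All
    downstream weighting uses the re-fitted propensity.  With
    ``trim='none'`` the sample and fit pass through unchanged.
    """
    if initial_fit is None:
        initial_fit = fit_propensity(sample.X, sample.Z)
    if trim == "none":
        keep = TrimResult(np.arange(sample.n), 0.0, "none")
        return sample, initial_fit, keep

    if trim == "crump":
        delta = crump_threshold(initial_fit.fitted_ps)
        method = "crump"
    else:
        delta = float(trim)
        method = "fixed" if delta > 0 else "none"
    result = trim_fixed(initial_fit.fitted_ps, delta)
    result = TrimResult(result.kept_indices, delta, method)
    if result.kept_indices.shape[0] == sample.n:
        return sample, initial_fit, result

    trimmed = sample.subset(result.kept_indices)
    if trimmed.Z.sum() == 0 or trimmed.Z.sum() == trimmed.n:
        raise TrimmingError("trimming removed an entire treatment group")
    refit = fit_propensity(trimmed.X, trimmed.Z)
    return trimmed, refit, result
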