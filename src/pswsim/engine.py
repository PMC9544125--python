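"""Replication engine: scenario grids, performance metrics, reports.

One *replicate* draws a sample from the super-population, optionally
trims it, fits the propensity model, computes the four weight families,
the three estimands, both standard errors and their normal-theory
confidence intervals, and the balance/ESS diagnostics.  A *scenario*
repeats this (by default 1000 times with 200 bootstrap resamples each)
and is summarized by the ratio of the mean estimated SE to the empirical
SD of the point estimates, the empirical coverage of nominal 95%
intervals, and mean balance/ESS.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import dgp
from .dgp import ScenarioConfig, SuperPopulation
from .errors import EstimateUndefinedError, FitFailureError, TrimmingError
from .estimation import (
    bootstrap_estimates,
    normal_ci,
    sandwich_variance,
    weighted_group_means,
)
from .diagnostics import balance_report
from .propensity import fit_propensity
from .weighting import FAMILIES, apply_trimming_workflow, compute_weights

__all__ = [
    "ESTIMANDS",
    "SAMPLE_SIZES",
    "PREVALENCES",
    "SIGMA_SCALES",
    "TRIM_DELTAS",
    "scenario_id",
    "grid_scenarios",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "summarize_records",
    "se_ratio",
    "coverage_rate",
    "coverage_significance_band",
]

ESTIMANDS = ("mean_diff", "risk_diff", "log_rr")
SAMPLE_SIZES = (250, 500, 1000, 5000, 10000)
PREVALENCES = tuple(round(0.1 * k, 1) for k in range(1, 10))
SIGMA_SCALES = (0.4, 0.5, 0.6, 0.7, 0.8, 1.0, 1.2, 1.4, 1.6)
TRIM_DELTAS = (0.0, 0.01, 0.02, 0.05, 0.10, "crump")

_ESTIMAND_OUTCOME = {"mean_diff": "continuous", "risk_diff": "binary", "log_rr": "binary"}


def scenario_id(config: ScenarioConfig) -> str:
    trim = config.trim if isinstance(config.trim, str) else f"{config.trim:g}"
    return (
        f"n{config.n_sample}_p{config.target_prevalence:g}_s{config.sigma_scale:g}"
        f"_i{int(config.interactions)}_t{trim}"
    )


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def grid_scenarios(
    grid: str, n_replicates: int = 1000, n_bootstrap: int = 200
) -> list[ScenarioConfig]:
    """Scenario list for one of the named factorial grids.

    ``main``: 5 sample sizes x 9 treatment prevalences (45 scenarios).
    ``interactions``: the main grid with treatment-covariate interactions
    in both outcome models.  ``overlap``: 9 coefficient scalars at
    n = 1000, prevalence 0.5.  ``trimming``: 9 scalars x 6 trimming rules
    (54 scenarios) at n = 1000, prevalence 0.5.
    """
    base = dict(n_replicates=n_replicates, n_bootstrap=n_bootstrap)
    if grid in ("main", "interactions"):
        inter = grid == "interactions"
        return [
            ScenarioConfig(n_sample=n, target_prevalence=p, interactions=inter, **base)
            for n in SAMPLE_SIZES
            for p in PREVALENCES
        ]
    if grid == "overlap":
        return [
            ScenarioConfig(n_sample=1000, target_prevalence=0.5, sigma_scale=s, **base)
            for s in SIGMA_SCALES
        ]
    if grid == "trimming":
        return [
            ScenarioConfig(
                n_sample=1000, target_prevalence=0.5, sigma_scale=s, trim=d, **base
            )
            for s in SIGMA_SCALES
            for d in TRIM_DELTAS
        ]
    raise ValueError(f"unknown grid {grid!r}; expected main/interactions/overlap/trimming")


def population_for(
    config: ScenarioConfig, master_seed: int, size: int = 1_000_000
) -> SuperPopulation:
    """Build the super-population for a scenario.

    The population seed depends only on (master seed, prevalence,
    sigma_scale, interactions), so scenarios differing only in sample
    size or trimming share one population.
    """
    key = f"pop_p{config.target_prevalence:g}_s{config.sigma_scale:g}_i{int(config.interactions)}"
    ss = np.random.SeedSequence([master_seed, _stable_hash(key)])
    return dgp.build_super_population(
        size,
        config.target_prevalence,
        config.sigma_scale,
        config.interactions,
        seed=ss,
    )


def run_replicate(
    pop: SuperPopulation,
    config: ScenarioConfig,
    replicate_seed: int | np.random.SeedSequence,
    truths: dict[str, dict[str, float]] | None = None,
) -> dict:
    """One full simulation replicate; returns a flat record.

    Unrecoverable failures (separation, empty arm after trimming, ...)
    produce a record with ``failed=1`` rather than an exception, so grid
    runs always complete.
    """
    if truths is None:
        truths = {fam: dgp.true_estimands(pop, fam) for fam in FAMILIES}
    ss = (
        replicate_seed
        if isinstance(replicate_seed, np.random.SeedSequence)
        else np.random.SeedSequence(replicate_seed)
    )
    s_sample, s_boot = ss.spawn(2)
    record: dict = {"failed": 0, "failure_reason": ""}
    sample = dgp.draw_sample(pop, config.n_sample, np.random.default_rng(s_sample))
    try:
        analysed, fit, trim_res = apply_trimming_workflow(sample, config.trim)
        record["n_analysed"] = analysed.n
        record["trim_threshold"] = trim_res.threshold

        boot_draws, n_boot_used = bootstrap_estimates(
            sample, config.n_bootstrap, np.random.default_rng(s_boot), trim=config.trim
        )
        record["n_bootstrap_used"] = n_boot_used

        for family in FAMILIES:
            w = compute_weights(fit.fitted_ps, analysed.Z, family)
            bal = balance_report(analysed.X, analysed.Z, w)
            record[f"{family}_max_abs_smd"] = bal.max_abs_smd
            record[f"{family}_ess_total"] = bal.ess_total

            se_cont = sandwich_variance(
                analysed.X, analysed.Z, analysed.y_cont, family, fit, "continuous"
            )
            se_bin = sandwich_variance(
                analysed.X, analysed.Z, analysed.y_bin, family, fit, "binary"
            )
            se_asym = {**se_cont, **se_bin}

            mu1c, mu0c = weighted_group_means(analysed.y_cont, analysed.Z, w)
            mu1b, mu0b = weighted_group_means(analysed.y_bin, analysed.Z, w)
            points = {"mean_diff": mu1c - mu0c, "risk_diff": mu1b - mu0b}
            if mu1b > 0 and mu0b > 0:
                points["log_rr"] = float(np.log(mu1b / mu0b))

            for est in ESTIMANDS:
                prefix = f"{family}_{est}"
                if est not in points:
                    record[f"{prefix}_failed"] = 1
                    continue
                point = points[est]
                truth = truths[family][est]
                record[f"{prefix}_point"] = point
                sa = se_asym.get(est, np.nan)
                record[f"{prefix}_se_asym"] = sa
                lo, hi = normal_ci(point, sa)
                record[f"{prefix}_cov_asym"] = int(lo <= truth <= hi)
                draws = boot_draws.get((family, est))
                if draws is not None and draws.size >= 2:
                    sb = float(np.std(draws, ddof=1))
                    record[f"{prefix}_se_boot"] = sb
                    lo, hi = normal_ci(point, sb)
                    record[f"{prefix}_cov_boot"] = int(lo <= truth <= hi)
    except (FitFailureError, EstimateUndefinedError, TrimmingError) as exc:
        record["failed"] = 1
        record["failure_reason"] = f"{type(exc).__name__}: {exc}"
    return record


def run_scenario(
    pop: SuperPopulation, config: ScenarioConfig, master_seed: int | None = None
) -> pd.DataFrame:
    """All replicates of one scenario as a DataFrame of records."""
    seed = config.seed if master_seed is None else master_seed
    scen = scenario_id(config)
    truths = {fam: dgp.true_estimands(pop, fam) for fam in FAMILIES}
    records = []
    for r in range(config.n_replicates):
        ss = np.random.SeedSequence([seed, _stable_hash(scen), r])
        rec = run_replicate(pop, config, ss, truths)
        rec["scenario"] = scen
        rec["replicate"] = r
        records.append(rec)
    return pd.DataFrame.from_records(records)


def se_ratio(se_values: np.ndarray, points: np.ndarray) -> float:
    """Mean estimated SE divided by the empirical SD of the point estimates.

    A value of one means the SE estimator correctly tracks the sampling
    variability; below one it is anti-conservative.
    """
    se_values = np.asarray(se_values, dtype=float)
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least two successful replicates")
    sd = float(np.std(points, ddof=1))
    if sd == 0.0:
        raise EstimateUndefinedError("zero empirical SD across replicates")
    return float(np.mean(se_values)) / sd


def coverage_rate(covered: np.ndarray) -> float:
    """Proportion of confidence intervals containing the true value."""
    covered = np.asarray(covered, dtype=float)
    if covered.shape[0] < 1:
        raise ValueError("need at least one successful replicate")
    return float(np.mean(covered))


def coverage_significance_band(R: int, nominal: float = 0.95) -> tuple[float, float]:
    """Normal-theory band outside which empirical coverage differs from
    nominal at the 5% level, given R simulation replicates."""
    if R < 1:
        raise ValueError("R must be positive")
    half = norm.ppf(0.975) * np.sqrt(nominal * (1.0 - nominal) / R)
    return nominal - half, nominal + half


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-scenario summary: one row per family x estimand x method."""
    rows = []
    for scen, grp in records.groupby("scenario"):
        ok = grp[grp["failed"] == 0]
        for family in FAMILIES:
            for est in ESTIMANDS:
                prefix = f"{family}_{est}"
                if f"{prefix}_point" not in ok.columns:
                    continue
                sub = ok.dropna(subset=[f"{prefix}_point"])
                for method, se_col, cov_col in (
                    ("asymptotic", f"{prefix}_se_asym", f"{prefix}_cov_asym"),
                    ("bootstrap", f"{prefix}_se_boot", f"{prefix}_cov_boot"),
                ):
                    if se_col not in sub.columns:
                        continue
                    pair = sub.dropna(subset=[se_col])
                    if len(pair) < 2:
                        continue
                    rows.append(
                        {
                            "scenario": scen,
                            "family": family,
                            "estimand": est,
                            "method": method,
                            "se_ratio": se_ratio(
                                pair[se_col].to_numpy(), pair[f"{prefix}_point"].to_numpy()
                            ),
                            "coverage": coverage_rate(pair[cov_col].to_numpy()),
                            "mean_max_abs_smd": float(ok[f"{family}_max_abs_smd"].mean()),
                            "mean_ess": float(ok[f"{family}_ess_total"].mean()),
                            "n_replicates_used": int(len(pair)),
                            "n_failed": int(grp["failed"].sum()),
                        }
                    )
    return pd.DataFrame(rows)


def run_grid(
    grid: str,
    master_seed: int = 0,
    n_replicates: int = 1000,
    n_bootstrap: int = 200,
    population_size: int = 1_000_000,
    out_records: str | None = None,
) -> pd.DataFrame:
    """Run a named grid end to end and return the tidy summary table.

    Super-populations are cached across scenarios that share a
    (prevalence, sigma_scale, interactions) combination.  When
    ``out_records`` is given, per-replicate records are appended to that
    CSV as each scenario finishes, so long runs are inspectable midway.
    """
    scenarios = grid_scenarios(grid, n_replicates, n_bootstrap)
    pops: dict[tuple, SuperPopulation] = {}
    summaries = []
    for config in scenarios:
        key = (config.target_prevalence, config.sigma_scale, config.interactions)
        if key not in pops:
            pops[key] = population_for(config, master_seed, population_size)
        records = run_scenario(pops[key], config, master_seed)
        if out_records is not None:
            header = not bool(summaries)
            records.to_csv(out_records, mode="w" if header else "a", header=header, index=False)
        summaries.append(summarize_records(records))
    return pd.concat(summaries, ignore_index=True)
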