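# pswsim

Monte Carlo toolkit for evaluating **asymptotic (M-estimation sandwich)
versus bootstrap standard errors** of propensity-score-weighted treatment
effect estimates — differences in means, risk differences, and relative
risks — under four weight families: inverse-probability (ATE) weights,
ATT weights, matching weights (MW), and overlap weights (OW).

It is aimed at biostatisticians and epidemiologists who want to study,
or teach, when the closed-form sandwich variance for weighting
estimators can be trusted and when the bootstrap should be preferred,
in fully controlled synthetic settings with known estimands.

## The statistics in brief

For a binary treatment `Z` and estimated propensity score `e(X)`, the
weight families are

```
w_ATE = Z/e + (1-Z)/(1-e)              w_ATT = Z + (1-Z) e/(1-e)
w_MW  = min(e,1-e) [Z/e + (1-Z)/(1-e)] w_OW  = Z(1-e) + (1-Z) e
```

Effects are Hájek contrasts of normalized weighted group means,
`μ̂₁ − μ̂₀` (mean/risk difference) and `log(μ̂₁/μ̂₀)` (log relative
risk).  Two standard errors are computed for every estimate:

* **Asymptotic**: the empirical sandwich `A⁻¹BA⁻ᵀ/n` from stacking the
  logistic score equations for the propensity parameters β with the two
  weighted-mean estimating equations, using analytic `∂w/∂β` — so the
  uncertainty of the estimated propensity score is propagated.
* **Bootstrap**: the SD of the point estimate across 200 resamples, with
  the propensity model (and any trimming) re-estimated in each resample.

A simulation scenario draws repeated samples from a calibrated
1,000,000-subject super-population (10 equicorrelated covariates, five
dichotomized; treatment prevalence calibrated by bisection; a continuous
outcome with R² = 0.25 in controls and uniform effect +2; a binary
outcome with control prevalence 0.2 and average risk difference −0.02)
and summarizes each estimator by the **SE ratio** (mean estimated SE /
empirical SD of the estimates; 1 = correct) and the **empirical
coverage** of nominal 95% normal-theory intervals.  Propensity trimming
to `[δ, 1−δ]`, including the sample-optimal threshold of Crump et al.,
and overlap-varying designs (all treatment-model slopes scaled by a
scalar σ) are built in.

## Worked example

```python
import numpy as np
from pswsim import (build_super_population, draw_sample, fit_propensity,
                    compute_weights, weighted_group_means, sandwich_variance,
                    bootstrap_se, true_estimands)

pop = build_super_population(200_000, target_prevalence=0.5, seed=3)
print(true_estimands(pop, "OW"))
# {'mean_diff': 2.0, 'risk_diff': -0.0195..., 'log_rr': -0.1107...}

s = draw_sample(pop, 1000, np.random.default_rng(7))
fit = fit_propensity(s.X, s.Z)
w = compute_weights(fit.fitted_ps, s.Z, "ATE")
mu1, mu0 = weighted_group_means(s.y_cont, s.Z, w)
se_asym = sandwich_variance(s.X, s.Z, s.y_cont, "ATE", fit)["mean_diff"]
se_boot, _ = bootstrap_se(s, "ATE", B=200, seed=5)
print(round(mu1 - mu0, 3), round(se_asym, 3), round(se_boot["mean_diff"], 3))
# 2.555 1.22 1.395
```

The point estimate 2.555 targets the true mean difference of 2; at
n = 1000 the asymptotic SE (1.22) is visibly smaller than the bootstrap
SE (1.395) under ATE weighting — exactly the regime where the bootstrap
is the safer choice.

A full factorial grid runs from the command line:

```bash
pswsim calibrate -p 0.1 -p 0.5 -p 0.9          # print model constants
pswsim simulate --grid overlap --replicates 200 --bootstraps 200 \
    --seed 1 --out overlap_summary.csv
pswsim diagnose mydata.csv --treatment treated  # balance/ESS/overlap
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from a fresh super-population: the bisection-calibrated
treatment-model intercepts at prevalences 0.1/0.5/0.9, the propensity
model c-statistics in the main and weak-association (σ = 0.4) designs,
the maximum weighted standardized difference under overlap weights, the
median Crump trimming threshold across 200 replicates at σ = 0.4 and
σ = 1.6, the percent of untreated outcome variance explained by the
covariates, and the achieved population risk difference.  Results are
written as JSON keyed by target id.
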