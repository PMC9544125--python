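# Methods

## Synthetic super-population

Each scenario draws its samples from a fixed super-population of
1,000,000 subjects (configurable).  Ten latent covariates are standard
normal with every pairwise correlation 0.2, realised through a
one-factor construction `x_j = √0.2·g + √0.8·e_j`, which gives the
equicorrelated covariance exactly.  Covariates 1–5 stay continuous;
covariates 6–10 are dichotomized by thresholding the latent normal at
its fixed theoretical (1−p) quantile for p = 0.10, 0.20, 0.30, 0.40,
0.50.  Using theoretical rather than empirical quantiles makes the
thresholds sample-independent; prevalences then hold in expectation.

**Treatment selection** is logistic with slopes
log(1.1, 1.2, 1.5, 1.75, 2, 1.25, 1.5, 2, 0.8, 0.5) on x1…x10.  (The
source design lists x8 twice and x9 never in all three models; we read
the second occurrence as x9 so that all ten covariates enter each
model, which the design states.)  The intercept is calibrated by
bisection so the mean of the subject-level treatment probabilities
equals the target prevalence: bracket [−20, 20], tolerance 1e−4 on the
prevalence scale, at most 200 iterations.  Calibrating against expected
probabilities rather than realised Bernoulli draws removes one layer of
Monte Carlo noise.  An overlap scalar σ (default 1) multiplies every
slope; the nine-value grid 0.4–1.6 moves the propensity-model
c-statistic between ≈0.64 and ≈0.87.

**Continuous outcome**: `Y = 2Z + βᵀx + ε` with
β = (2.5, 2, 1.5, 1, 0.5, 2, 1, 5, 4, 3) and ε ~ N(0, σ²ε), where
σ²ε = 3·Var(βᵀx) so that the covariates explain exactly 25% of the
outcome variance in controls.  **Binary outcome**: logistic with slopes
log(2, 1.75, 1.1, 1.5, 1.2, 2, 1.5, 1.1, 1.25, 2); the intercept is
bisected to a control-arm prevalence of 0.2, then the treatment
log-odds ratio is bisected until the population mean of p(1) − p(0)
equals −0.02.  An optional interaction flag adds Z×x_j terms at one
quarter of each main effect to both outcome models; under it the
risk-difference bisection uses the interaction-augmented p(1).

Both potential outcomes are generated for every subject with a shared
noise draw (one ε for the continuous pair, one uniform thresholded
against p(0) and p(1) for the binary pair).  This coupling leaves every
mean-level estimand untouched — only subject-level joint contrasts
depend on it — and makes the uniform continuous effect exactly 2 for
each subject.

**True estimands** are tilting-function averages over the
super-population with the true propensity: h = 1 (ATE), e (ATT),
min(e, 1−e) (MW), e(1−e) (OW), applied to the stored potential
outcomes.  With a uniform continuous effect all four mean-difference
estimands equal 2 exactly; the binary estimands differ slightly by
family because the effect is uniform on the odds-ratio, not the
risk-difference, scale.

## What the generator does and does not emulate

It reproduces the stated correlation structure, measured confounding,
and calibrated marginals.  It does not include unmeasured confounding,
covariate measurement error, model misspecification of the propensity
or outcome form (beyond the optional interactions), or survival
outcomes.  A green simulation result therefore speaks to variance
estimation under a correctly specified main-effects propensity model,
not to robustness against misspecification.

## Estimation

The propensity model is always main-effects logistic regression fit by
Newton/IRLS (score tolerance 1e−8, damped steps, at most 50
iterations).  On a singular Hessian a ridge of 1e−8 is added to the
Hessian only and the event is logged; coefficients exceeding 100 in
absolute value raise a separation failure.  Failures inside the
replication engine mark the replicate (or bootstrap resample) as failed
rather than aborting the run.

Point estimates are Hájek contrasts.  The relative risk is analysed on
the log scale throughout (its sampling distribution is closer to
normal), and coverage for the relative risk is assessed against the
true log relative risk.

**Sandwich variance.** The estimating equations for
θ = (β, μ₁, μ₀) stack the logistic score `(Z − e(x;β))x` with
`w₁(x;β)Z(Y − μ₁)` and `w₀(x;β)(1−Z)(Y − μ₀)`.  The bread matrix uses
analytic derivatives, including ∂w/∂β through e(x;β) for every family
(matching weights have a kink at e = 0.5; the one-sided derivative is
used there, a measure-zero event).  Var(θ̂) = A⁻¹BA⁻ᵀ/n, delta-mapped
with gradient (1, −1) for differences and (1/μ₁, −1/μ₀) for the log
relative risk.  The analytic bread is verified against central finite
differences in the test suite (relative error < 1e−5).

**Bootstrap.** 200 resamples by default, drawn with replacement and
*unstratified* by treatment — the design leaves stratification
unstated, and simple resampling also propagates prevalence uncertainty.
Each resample re-runs the full pipeline (trimming included when
configured).  Degenerate resamples are dropped and counted, never
imputed.  The SE is the SD (divisor B−1) across successful resamples.

**Trimming.** Retention interval is closed, [δ, 1−δ] (the design
excludes subjects strictly outside it).  The Crump-optimal threshold
solves `1/(α(1−α)) = 2·mean{1/(e(1−e)) : e(1−e) ≥ α(1−α)}` exactly by
scanning the sorted sample values of e(1−e) as candidate cut levels
(smallest admissible α, i.e. the least trimming consistent with the
condition); it is recomputed inside every bootstrap resample, matching
the re-estimation of the propensity score after trimming.

## Diagnostics

Weighted standardized differences use weighted means and
reliability-weight variances `Σw(x−x̄)²/(Σw − Σw²/Σw)` (reduces to the
n−1 divisor at unit weights).  Overlap weights from a fitted logistic
model balance every modeled covariate exactly — the score equations
force identical weighted means — so their maximum |SMD| is zero to
float precision, a useful end-to-end identity check.  Effective sample
size is Kish's `(Σw)²/Σw²` per group.  The overlapping coefficient is
one minus the integrated minimum of Gaussian-kernel (Silverman
bandwidth) density estimates on a 512-point grid over [0, 1]; note the
convention: 0 = identical densities, 1 = disjoint.

## Engine and reproducibility

Scenario grids: `main` (5 sample sizes × 9 prevalences), `interactions`
(same, with outcome interactions), `overlap` (9 σ values at n = 1000,
prevalence 0.5), `trimming` (9 σ × 6 trimming rules).  Defaults are
1000 replicates × 200 bootstraps.  Seeds derive from
`SeedSequence([master, crc32(scenario), replicate])`, so every summary
is a pure function of (grid, master seed, replicate and bootstrap
counts), scenarios are decoupled, and super-populations are shared
across scenarios that differ only in sample size or trimming rule.
Replicate failures are excluded pairwise from metrics with counts
reported.

## Numerical choices and limitations

* Bisection tolerance 1e−4 on the target scale; achieved constants are
  reported to full precision.
* Fitted propensities are clipped away from 0/1 by the smallest
  positive float only; weights reject exact 0/1 inputs.
* SE ratios use the empirical SD with divisor R−1; the coverage
  significance band is `nominal ± z₀.₉₇₅·√(nominal(1−nominal)/R)`.
* The acceptance checks run the headline scenarios at a reduced scale
  (200 replicates) to stay within a CPU-minute budget; the band and
  ratio tolerances used there are the ones appropriate to that scale.
* Percentile bootstrap intervals, survival outcomes, multi-category
  treatments and weight truncation (as opposed to trimming) are out of
  scope.
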