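# Methods

## Scope and data model

The package analyses *aggregate* longitudinal data: one record per placebo
arm per follow-up visit, carrying the arm's mean change from baseline in
ESSDAI, the number of subjects contributing at that visit, and trial-level
covariates (baseline ESSDAI, age, % male, treatment duration, time since
diagnosis, % on background therapy). The analysis unit is the trial arm, not
the subject; no subject-level data are supported. Baseline ESSDAI and
treatment duration are mandatory (the first is the retained covariate and the
simulation input, the second a design quantity every report states); all
other covariates may be missing. A per-visit sample size missing from the
file is carried forward from the previous visit, since attrition is rarely
reported per visit in publications.

Covariate preparation follows two rules before any covariate modelling: a
covariate missing in ≥ 40% of trials (inclusive, computed per trial because
the trial is the analysis unit) is flagged unusable; remaining missing values
are imputed with the across-trial median. The operation is idempotent and
never touches observation records.

## Structural and stochastic model

The mean change for arm *i* at week *t* is `−Emax_i · t/(ET50_i + t)`: zero
at randomization, saturating at `−Emax_i`. `ET50` is the onset half-time —
the response reaches half its maximum at `t = ET50` by construction. Emax is
stored positive; the leading minus produces negative changes (improvement).
Covariates act linearly on Emax around fixed centring constants stored inside
the parameter object (not recomputed from data), so a fitted model is
portable; the pooled-model centring is 10.1 ESSDAI points, the corpus median
baseline. Emax is deliberately not clamped at zero: the covariate model is
linear and very low baselines legitimately produce near-zero maxima.

Trial-level heterogeneity enters additively on Emax (`η1 ~ N(0, ω²_Emax)`,
ESSDAI points) and exponentially on ET50 (`η2 ~ N(0, ω²_ET50)`, log scale,
keeping ET50 positive); the two effects are independent (no correlation
parameter is identifiable from 13 arms). Residual error acts on the observed
*mean* change with SD `σ/√N_ij` — aggregate-level noise, which is exactly the
sampling error of a mean, not per-subject noise. The ω parameters are
interpreted as standard deviations; because reported inter-trial-variability
magnitudes are sometimes variances, the simulator exposes an
`omega_as_variance` switch for sensitivity analysis.

Reference parameter values used throughout as simulation truth and as the
desk inputs for the typical-response surface: `θ_Emax = 4.44` points at
baseline 10.1, baseline coefficient `0.552` points/point, `θ_ET50 = 12.2`
weeks, `ω_Emax = 0.563`, `ω_ET50 = 0.794`, `σ = 1.661`.

## Synthetic corpus generator

`sample_design` draws trial designs matching the published corpus summaries:
arm sizes log-uniform on [4, 95] (median ≈ √(4·95) ≈ 19.5, matching the
reported median of 19), durations uniform over {12, 16, 24, 28, 48} weeks,
baseline ESSDAI uniform on [2.5, 13.1], and the remaining covariates uniform
over their reported ranges. Uniform rather than triangular baselines were
chosen for simplicity — only median/min/max are known. Visit schedules
always include the final week and keep each earlier protocol week
(4, 8, 12, 16, 24, 28, 36, 48, truncated at the duration) with probability
1/2, giving the 1–5 visits per arm typical of these reports.

What the generator does *not* emulate: dropout/attrition (N is constant
within an arm), active-arm data, correlation between design variables (real
corpora pair, e.g., long durations with larger arms), non-normal residuals,
and publication-driven selection of which visits get reported. Passing tests
therefore demonstrate that the estimator and diagnostics are correct *under
the model's own assumptions* at realistic sizes — not that the model is
correct for any particular real corpus.

## Estimation

Each trial contributes a 2-D integral over (η1, η2) of a Gaussian likelihood.
The fitting objective is the Laplace approximation at the per-trial mode of
the joint log-density — the behaviour of conditional-estimation (FOCE-type)
algorithms for this model class. The reported OFV is −2× the approximate log
marginal likelihood with the `n·log 2π` constant dropped; every decision in
the pipeline uses OFV *differences*, so the constant convention only needs to
be fixed, which it is.

An adaptive Gauss–Hermite quadrature routine over the same per-trial modes
serves as the brute-force oracle: with one node it reproduces the Laplace
value exactly (same mode, same Hessian scaling), and node counts of 21+ are
converged to ~1e-4 on corpus-sized fixtures. At the reference variability
(ω_ET50 = 0.794 on the log scale) the intrinsic Laplace error is ~0.03–0.07
per trial against the converged quadrature — a known property of
Laplace-family estimators for strongly skewed random-effect integrands, and
the reason ΔOFV-based decisions, which cancel most of the bias, are preferred
over absolute OFV comparisons.

Numerical details:

- **Inner problem** (per-trial mode): damped Newton with the exact 2×2
  Hessian when positive definite, otherwise the Gauss–Newton surrogate
  (always PSD, hence always a descent direction); gradient tolerance 1e-8.
  The Laplace determinant uses the exact Hessian when PD, else the surrogate.
  The OFV is a pure deterministic function of its arguments — no warm-start
  state — which makes it trial-order invariant and keeps the outer
  finite-difference gradients clean.
- **Outer problem**: L-BFGS-B on a transformed scale (log for ET50, the ωs
  and σ; identity for θ_Emax and covariate coefficients), finite-difference
  step 1e-6, with one restart from the terminal point and a Nelder–Mead
  fallback on line-search aborts. Optional seeded multi-start.
- **Initial values**: θ_Emax = −(mean last-visit change); θ_ET50 = half the
  median follow-up; ωs = 0.3; σ = the SD of √N-scaled residuals from the
  initial curve (floored at 0.3).
- **Uncertainty**: covariance = 2·(inverse of the central finite-difference
  OFV Hessian) on the transformed scale; natural-scale SEs by the delta
  method (for log-parameters RSE% = 100·SE on the log scale).
- **Empirical Bayes effects**: per-trial posterior modes at the final
  estimates; dimensions with ω = 0 are pinned at zero. Failures degrade to
  zeros with a warning rather than raising.
- **Degenerate inputs**: ω = 0 collapses the integral to the closed-form
  weighted least-squares deviance; σ = 0 is a valid simulation setting but is
  rejected for likelihood evaluation; non-finite joint densities at extreme
  parameter points return a large penalty OFV so the optimizer retreats.

## Covariate selection

A univariate screen adds each candidate alone to the base model (significant
iff ΔOFV > 3.84, the χ²(1) 5% point); the search proper runs forward
inclusion (repeatedly add the largest ΔOFV > 3.84, ties broken by listed
order for determinism) followed by backward elimination (repeatedly remove
the covariate whose removal costs least, while that cost is < 6.63, the 1%
point). Continuous covariates are centred at their corpus median,
percentage-type covariates at zero; only linear-centred effects on Emax are
searched by default (effects on ET50 are supported but must be requested).
A candidate whose fit fails to converge counts as ΔOFV = 0 — conservative,
and the search always terminates. The step log records every fit and is
sufficient to replay the search decision by decision.

## Validation

- **CWRES** uses the first-order conditional linearization about the
  empirical Bayes effects: `V = F Ω F' + diag(σ²/N)` with `F` the Jacobian of
  the prediction in η, residuals decorrelated by the Cholesky inverse of `V`
  around the linearized conditional mean. With ω = 0 this reduces exactly to
  `(obs − pred)·√N/σ`. Under a correctly specified model CWRES is
  approximately standard normal, which the suite checks by simulation.
- **Jackknife** refits once per omitted trial (≥ 3 trials required) and
  reports estimates plus relative deviations from the all-data fit — ranges,
  not pseudo-value variances, since the diagnostic is qualitative.
- **VPC** simulates replicate corpora at the estimates under the original
  design and summarizes 2.5/50/97.5 percentiles per nominal visit week
  (no smoothing: the corpus shares a sparse protocol grid). Percentiles pool
  across trials within a bin, the overall-study presentation; with a
  heterogeneous corpus the band therefore reflects between-trial covariate
  spread as well as the model's stochastic terms.
- **SIR** is single-iteration: a multivariate-normal proposal at the
  estimates on the transformed scale with covariance inflated ×1.5 (default),
  importance weights ∝ exp(−ΔOFV/2)/proposal density, resampling without
  replacement. The effective sample size is reported and values below 50
  raise with advice to increase the inflation. On an exactly quadratic OFV
  surface SIR reproduces the analytic Wald intervals, which is the suite's
  correctness anchor. Proposal size and inflation are package defaults, not
  reported values.

## Typical-response simulation and single-arm evaluation

The *typical* response is the population curve (η = 0). Its 95% CI reflects
fixed-effect uncertainty only — inter-trial variability describes how a new
trial deviates, not how uncertain the typical value is. Draws come from the
asymptotic normal of the fit on the estimation scale (so ET50 stays
positive); a fallback uses independent normals built from per-parameter RSEs,
with ET50 lognormal. An externally published parameter table plus RSEs can be
wrapped via `fit_result_from_estimates` when the underlying corpus is
unavailable; published RSEs carry no correlation information, so CI bounds
built that way are order-of-magnitude reproductions, not exact ones.

Single-arm evaluation builds that band at the trial's own baseline over the
trial's visit weeks and compares observed mean changes as points (their SEs
are displayed, not used). The efficacy verdict is one-sided by design: only a
point *below* the lower band edge (more improvement than placebo explains)
yields `exceeds-placebo`; a point above the upper edge is flagged separately
as possible harm rather than folded into the efficacy conclusion. An option
adds η draws to form a wider new-trial prediction band, clearly labelled and
off by default.

## Problem sizes and defaults

Defaults follow the sizes used in this kind of analysis: 1000 VPC
replicates, 10,000 typical-response draws, 5000 SIR proposals / 1000
resamples, 13-trial corpora in simulation studies. The test suite and
examples scale some Monte-Carlo sizes down (e.g. hundreds of VPC replicates,
20 recovery corpora) — these are the package's own verification sizes, chosen
so the full suite stays convenient to run while the Monte-Carlo error remains
well below the tolerances asserted.

## Known limitations

- The Laplace OFV carries an irreducible approximation error (~0.05/trial at
  the reference variability); absolute OFVs from different implementations
  should not be compared, only differences.
- ET50 is weakly identified by sparse visit schedules: single-corpus ML
  estimates scatter widely (relative errors of ±50% are unremarkable at 13
  trials), consistent with its large reported RSE. Median behaviour across
  replicates is well calibrated.
- CI bands built from published RSEs ignore parameter correlations.
- The generator's independence assumptions (between design variables, and
  between η1 and η2) are simplifications; real corpora may violate both.
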