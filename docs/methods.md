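# Methods

## Structural model

Piperacillin disposition is described by a one-compartment linear model
with zero-order infusion input, written in amount space:

    dX/dt = R(t) − (CL/Vc)·X,      C(t) = X(t)/Vc

with `X` the amount in the central compartment (mg), `R(t)` the summed
rate of all active infusions (mg/h), `Vc` the central volume (L) and
clearance a linear function of creatinine clearance,

    CL = intercept + slope · CrCl        (CrCl in L/h).

CrCl is handled in L/h throughout the model; the single conversion
constant (1 mL/min = 0.06 L/h) lives in `pippk.renal`. Because the system
is linear, the response to any event schedule is the superposition of
single-event closed forms — during an infusion the contribution is
`(R/CL)(1 − e^(−ke·t))` with `ke = CL/Vc`, afterwards it decays
exponentially. The analytic engine is exact and fast enough for
2000-patient Monte Carlo; a numerical integrator (`ode_oracle`,
segment-wise LSODA at tolerance 1e−10) exists solely as an independent
test oracle. Between event boundaries each concentration segment is
monotone (`C(τ) = P + (C0 − P)e^(−ke·τ)`), so time-above-threshold is
computed from logarithmic crossing times and window minima are evaluated
exactly at segment boundaries; no profile gridding is involved anywhere
in the pipeline. Time zero is the start of the first infusion and all
analysis windows are half-open `[a, b)`.

Two- and three-compartment structures, nonlinear elimination and
tazobactam kinetics are out of scope.

## Residual-error model

Observation noise is normal with concentration-dependent SD

    SD(C) = γ · (0.4388 + 0.027 · C)   mg/L,

the inter-day assay-variance polynomial of the HPLC assay, inflated by a
process-noise multiplier γ (default 1, estimated during fitting by
bounded golden-section/Brent search on [0.05, 20]). Observations below
the 1 mg/L lower limit of quantification are excluded from the
likelihood by default; LLOQ/2 substitution is available as a config
option.

## Nonparametric estimation

The population law over (intercept, slope, Vc) is estimated as a discrete
mixing distribution maximising `Σᵢ log Σⱼ wⱼ L(yᵢ | θⱼ, γ)`. The
algorithm follows the published NPAG outline at reduced sophistication:

1. **Initial grid** — a scrambled Sobol sequence of 2048 points (default)
   in a bounding box (defaults: intercept [0.01, 50] L/h, slope
   [0.001, 10], Vc [1, 200] L — generous boxes around the published adult
   estimates).
2. **Weight sub-problem** — the weights are the solution of a concave
   program on the simplex, solved by EM multiplicative updates
   accelerated SQUAREM-style (two EM maps plus a projected extrapolation,
   keeping whichever iterate has the higher objective, so the objective
   is monotone). Because extrapolation can clip a weight to exactly zero
   that the multiplicative map cannot revive, convergence is certified
   with the KKT condition `gⱼ = (1/N)Σᵢ L_ij/(Lw)ᵢ ≤ 1`: any zero-weight
   column with `gⱼ > 1` is reactivated and iteration continues. On small
   instances the solution matches dense simplex grid search to 1e−6.
3. **Adaptive refinement** — points with weight below 1e−8 of the
   maximum are pruned; each survivor proposes ±δ per-dimension
   perturbations (δ from 20% of each range, halving to 0.1%); a proposal
   set is kept only if it raises the marginal likelihood. When a full
   sweep from the coarsest to the finest δ gains less than `sweep_tol`
   (default 0.01 log-likelihood units) the fit is declared converged;
   otherwise δ re-expands and the sweep repeats, which makes the
   optimum markedly more reproducible between the full and reduced
   (covariate-free) models at modest extra cost.
4. **γ step** — after each cycle γ is re-optimised with cached
   predictions; every accepted move (expansion, γ) increases the
   likelihood, so the reported trace is non-decreasing by construction.

Per-subject posterior estimates weight the support points by
`prior weight × subject likelihood` and report the posterior mean.
Covariate screening fits the model with and without the CrCl slope
(slope pinned to 0, search over the remaining two dimensions) and
reports `ΔLL = 2·(LL_full − LL_reduced)`; the accept/reject threshold is
left to the analyst. No model-selection criterion beyond ΔLL is applied,
and no covariates other than CrCl-on-CL are built in — screening other
candidates reuses the same mechanism.

**A note on ΔLL under sparse, low-noise designs.** With four
observations per subject and assay-level noise, each subject's (CL, Vc)
is nearly exactly identified and the unrestricted mixing distribution
can place one support atom per subject under both the covariate and the
covariate-free model — each subject effectively has two free parameters
either way, so the maximised nonparametric likelihood moves little when
the covariate is added, and the reduced model can occasionally do
relatively better or worse by several units through atom-sharing
accidents. Large covariate ΔLL values of the kind seen with parametric
estimators (or with real, noisier data) should not be expected from
NPML on this synthetic design; the covariate-screen acceptance checks
record this honestly.

## Diagnostics

* **Predictions** — population prediction is the prior-weighted mean
  prediction over support points; individual prediction is the profile
  at the posterior mean; weighted residual is
  `(obs − population pred)/SD(population pred)`.
* **Metrics** — R² from least-squares regression of observed on
  predicted at both levels; bias = mean weighted residual; imprecision =
  variance of weighted residuals.
* **NPDE** — per subject, 1000 replicate observation vectors (default)
  are simulated under the fitted model (semi-parametric parameter draws
  plus assay noise); observation and simulations are decorrelated by the
  inverse Cholesky factor of the empirical simulation covariance (with a
  marginal fallback when singular); the prediction discrepancy gets a
  1/(2·nsim) continuity correction before the normal-quantile transform.
  Normality of the pooled NPDE is summarised with the Shapiro–Wilk test
  (a library routine; the test choice, not its implementation, is the
  contract).
* **VPC** — replicate datasets at the observed design; bins default to
  the distinct sampling offsets within the dosing interval (the fixed
  1/4/6/8 h design), with explicit edges available. Plain VPC only; no
  prediction correction.

All diagnostics are pure functions of (fit, data, seed).

## Simulation of dosing regimens

Six 4 g piperacillin regimens are built once (`standard_dosages`): 0.5 h
and 4 h infusions q8h (D1, D2) and q12h (D4, D5), plus loading variants
(D3, D6: 4 g/0.5 h at t=0 immediately followed by 4 g/4 h at t=0.5,
then maintenance from the next scheduled slot). The horizon is 48 h,
covering both analysis windows.

* **Efficacy** — PTA is the percentage of virtual patients with unbound
  concentration (fixed unbound fraction 0.7) above the MIC for ≥ 50% of
  the first 24 h of therapy (this window makes loading doses matter);
  MICs run over the 13-step doubling grid 0.0625–256 mg/L; PTA ≥ 90% is
  labelled optimal, 50–90% intermediate, < 50% poor. The threshold
  comparison is strict (> MIC), which is measure-zero in the analytic
  engine.
* **Toxicodynamics** — the minimum unbound concentration over day 2
  ([24, 48) h) is compared with neurotoxicity thresholds 157.2 and
  361.4 mg/L and the nephrotoxicity threshold 452.65 mg/L; exceedance is
  reported per threshold as a percentage of patients.
* **Virtual patients** — 2000 per scenario (default). Each patient pairs
  one parameter draw with a CrCl drawn uniformly within the renal
  category: normal 90–129 mL/min; severe impairment and kidney failure
  pooled as 5–29 mL/min (they are reported as one merged column; the
  lower edge of 5 keeps clearance away from the intercept-only
  degeneracy). Category ranges quoted per 1.73 m² are treated as
  absolute mL/min — the simulation carries no body-surface data.

Because the support points of the originally fitted model are not
published, population sampling for reproduction runs offers two routes:
semi-parametric sampling from any fitted `NonparametricDistribution`
(mixture of normals centred at support points, covariance = full-model
covariance / number of points, rejection of non-positive draws capped at
1000 rounds), and a **parametric fallback** of independent log-normals
moment-matched to the published means and SDs (intercept 4.556 ± 5.035
L/h, slope 1.353 ± 1.032, Vc 30.68 ± 23.349 L). Log-normal was chosen
over a zero-truncated normal to avoid a point mass of near-zero
clearances given SDs larger than the means; truncated-normal sampling
remains available. Independence across the three parameters is an
approximation — no correlations are published.

**Known limitation of the fallback.** The independent log-normals have
heavier tails than a 13-support-point mixture: a ~1% upper tail of
clearance (CL 40–70 L/h) and a small low-clearance tail. Consequently
PTA at MIC 8 for the extended q8h regimen in normal renal function
simulates at ≈ 99% where the original model reports 100%, and the
day-2 neurotoxicity-low exceedance for the q12h loading regimen in
severe impairment simulates at ≈ 0.7–1.4% against an original 0.3%.
These are distribution-shape artefacts (verified against a 0.001 h
brute-force grid), not engine errors.

## Synthetic cohorts

The generator emulates the study design rather than any patient:
age uniform on 48–86 y, sex 63% male, weight normal(75, 12) kg truncated
above 40 kg, serum creatinine log-normal (median 1.2 mg/dL, σ = 0.5)
chosen so Cockcroft–Gault CrCl spans roughly 15–255 mL/min; regimen
assignment gives 4 g/0.5 h q12h below CrCl 20 mL/min and 4 g/4 h q8h
otherwise; four samples at 1/4/6/8 h into the dosing interval containing
t = 40 h (≥ 5 half-lives of accumulation for typical parameters — an
adequate steady-state approximation given the analytic engine simulates
from t = 0 anyway); assay noise per the error model, negatives clamped
to zero, values below 1 mg/L flagged below-LLOQ. True parameters come
from any configured population (nonparametric or the parametric
fallback). These marginals are stated assumptions, not estimates — the
real cohort's weight/creatinine marginals are unpublished — so passing
tests show internal consistency of the pipeline, not fidelity to any
particular hospital population; clinical outcomes, isolate MIC
distributions and tazobactam are not simulated.

## Numerical choices and problem sizes

* Relative comparisons against the ODE oracle use a denominator floored
  at 1e−6 of the profile peak: the deep exponential tail sits below the
  integrator's absolute tolerance and carries no information.
* EM tolerance 1e−10 on the objective; KKT tolerance 1e−9; weight
  pruning at 1e−8 of the maximum weight.
* Default seeds: fitting 20210348; simulation seeds are recorded in
  every report header. All randomness flows through
  `numpy.random.Generator`.
* The test-suite fits use Sobol grids of 256–512 points with cycle caps
  of 40–60 and `sweep_tol` 0.05–0.1 — sizes at which a 27–40-subject fit
  takes seconds while recovering population means well inside the stated
  tolerances; the library defaults (2048 points, 200 cycles,
  `sweep_tol` 0.01) are sized for analysis runs.
* Estimating γ from noiseless data is degenerate (γ collapses to its
  lower bound and needles the likelihood); exact-recovery checks
  therefore fix γ = 1.

## Limitations

* One compartment only; the estimator assumes every subject's schedule
  and covariates are known exactly and CrCl is constant over the fitted
  interval (no daily covariate updates, no interoccasion variability).
* The NPAG implementation omits D-optimality candidate generation and
  support condensation beyond weight pruning; very large cohorts would
  benefit from both.
* NPDE/VPC simulation counts default to 1000; the originally reported
  diagnostic values (e.g. R² after the Bayesian step) depend on the real
  dataset, which is not deposited — the diagnostics here check patterns
  (individual R² above population R², NPDE calibration under the true
  model), not those numbers.
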