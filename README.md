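# pippk — population pharmacokinetics of piperacillin

`pippk` models the pharmacokinetics of piperacillin in adult,
non-critically ill patients with Gram-negative bloodstream infection and
asks the two questions that drive beta-lactam dosing: **does a regimen keep
free drug above the pathogen's MIC long enough to work**, and **does renal
impairment let trough concentrations climb into the toxic range**.

The package covers the full analysis pipeline:

* **Structural model** — one-compartment kinetics with zero-order
  infusions, solved in closed form by superposition:
  `dX/dt = R(t) − (CL/Vc)·X`, `C = X/Vc`, with clearance a linear function
  of creatinine clearance, `CL = θ₀ + θ₁·CrCl` (L/h).
* **Nonparametric population estimation** — an adaptive-grid
  nonparametric maximum-likelihood (NPAG-style) estimator of the mixing
  distribution over (θ₀, θ₁, Vc): Sobol initial grid, EM solution of the
  convex weight sub-problem with a KKT optimality screen,
  shrink-and-perturb grid refinement, and a residual-error model
  `SD(C) = γ·(0.4388 + 0.027·C)` mg/L with the process-noise multiplier γ
  profiled by bounded 1-D search. Includes forward-inclusion screening of
  the CrCl covariate and per-subject posterior (Bayesian) estimates.
* **Diagnostics** — observed-vs-predicted R² before/after the Bayesian
  step, weighted-residual bias and imprecision, normalised prediction
  distribution errors (NPDE) with a Shapiro–Wilk normality check, and
  visual-predictive-check (VPC) percentile bands.
* **Monte Carlo simulation** — probability of target attainment
  (fT>MIC ≥ 50% of the first 24 h, unbound fraction 0.7) and
  toxicodynamic exceedance (unbound day-2 Cmin vs neurotoxicity
  157.2 / 361.4 mg/L and nephrotoxicity 452.65 mg/L thresholds) for six
  4 g regimens — q8h and q12h, short (0.5 h) and extended (4 h)
  infusions, with and without a loading sequence — across renal-function
  categories.
* **Renal arithmetic** — Cockcroft–Gault CrCl, 2009 CKD-EPI eGFR, KDIGO
  GFR categories.
* **Synthetic data** — a virtual-cohort generator reproducing the
  study design (sparse 1/4/6/8 h sampling at steady state, LLOQ 1 mg/L,
  q12h dosing below CrCl 20 mL/min) so the whole pipeline is testable
  without patient data.

## Worked example

Attainment of the 50% fT>MIC target for a typical patient
(population-median parameters θ₀ = 3.503 L/h, θ₁ = 1.39, Vc = 20.0 L;
CrCl 109.5 mL/min):

```text
$ python examples/concentration_profile.py
typical patient: CL = 12.64 L/h, Vc = 20.0 L

regimen   peak 0-24h  trough d1  fT>MIC8
D1          172.3 mg/L     1.5 mg/L     0.60
D2           73.3 mg/L     5.8 mg/L     0.85
D3          171.2 mg/L     5.9 mg/L     0.89
D4          171.3 mg/L     0.1 mg/L     0.40
D5           72.8 mg/L     0.5 mg/L     0.56
D6          171.2 mg/L     0.5 mg/L     0.60
```

D1/D4 are 0.5 h infusions, D2/D5 extended 4 h infusions, D3/D6 add a
loading sequence; D1–D3 are q8h, D4–D6 q12h. The short q8h infusion
spends 60% of the first day above the 8 mg/L susceptibility breakpoint
(free drug), while the extended infusion reaches 85–89% — the
pharmacokinetic rationale for extended infusion. At population level,
`examples/pta_table.py` runs the 2000-patient Monte Carlo version and
prints the full PTA-by-MIC table with optimal / intermediate / poor
banding; `examples/toxicity_analysis.py` reports day-2 trough exceedance
of the toxicity thresholds; `examples/fit_synthetic_cohort.py` and
`examples/model_diagnostics.py` demonstrate estimation and diagnostics on
a synthetic cohort.

A command-line pipeline wraps the same functions:

```sh
pippk synth --out data.csv --seed 3
pippk fit --data data.csv --out model/
pippk diagnose --model model/ --data data.csv --out diag/
pippk simulate-pta --model model/ --out pta.csv --tox-out tox.csv
```

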