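"""Fit the nonparametric population model to a synthetic sparse cohort.

Generates a 27-subject virtual cohort (ages 48-86, CrCl from normal function
to kidney failure, 4 samples/subject at 1/4/6/8 h into a steady-state
interval), fits it with the adaptive-grid nonparametric estimator, and
compares the fitted population summary with the generating truth.
"""

import warnings

import numpy as np

from pippk import (
    CohortConfig,
    NpagConfig,
    generate_cohort,
    npag_fit,
    simulate_dataset,
    weighted_summary,
)

cohort = generate_cohort(CohortConfig(n_subjects=27, seed=11))
data = simulate_dataset(cohort, seed=12)
print(f"cohort: {cohort.n} subjects, "
      f"{sum(len(s.times) for s in data)} observations, "
      f"CrCl {cohort.crcl_mL_min.min():.0f}-{cohort.crcl_mL_min.max():.0f} mL/min")

with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    fit = npag_fit(data, config=NpagConfig(n_grid=512, max_cycles=60,
                                           sweep_tol=0.05, seed=1))

print(f"\nlog-likelihood {fit.log_likelihood:.2f}, "
      f"gamma {fit.gamma:.2f}, "
      f"{len(fit.distribution.points)} support points, "
      f"{fit.cycles} cycles\n")
print("fitted population (weighted over support points):")
print(weighted_summary(fit.distribution).round(3))

med_crcl_Lh = float(np.median(cohort.crcl_mL_min)) * 0.06
pm = fit.distribution.param_matrix
w = fit.distribution.weights
cl_fit = float((pm[:, 0] + pm[:, 1] * med_crcl_Lh) @ w)
cl_true = float((cohort.true_params.intercept
                 + cohort.true_params.slope * med_crcl_Lh).mean())
print(f"\nmean clearance at the median CrCl: fitted {cl_fit:.2f} L/h "
      f"vs simulated truth {cl_true:.2f} L/h")
print("gamma < 1 means part of the assay-error budget was not needed to"
      "\nexplain the data once between-subject variability is modelled.")
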