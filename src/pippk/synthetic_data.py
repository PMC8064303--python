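"""Synthetic cohorts with the statistical structure of a sparse-sampled
piperacillin therapeutic-drug-monitoring study.

The generator emulates an adult, non-critically ill bacteraemia cohort:
ages in the late-adult range, mixed sex, creatinine spanning normal
function to kidney failure, 4 g piperacillin infusions (extended 4 h
infusions q8h; short 0.5 h infusions q12h when CrCl < 20 mL/min), and
four plasma samples per subject at 1, 4, 6 and 8 h after the start of a
steady-state infusion, with proportional-polynomial assay noise and a
1 mg/L lower limit of quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .npag_fit import AssayErrorModel, LLOQ_MG_L, SubjectDataset, assay_sd
from .pk_model import InfusionEvent, InfusionSchedule, PKParameters, predict_concentrations
from .population import (
    NonparametricDistribution,
    ParameterSample,
    REFERENCE_MEANS,
    REFERENCE_SDS,
    parametric_sample,
    semiparametric_sample,
)
from .renal import ML_MIN_TO_L_PER_H, PatientCovariates, cockcroft_gault

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "simulate_dataset"]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for the virtual cohort.

    Covariate marginals are loose emulations of a real late-adult cohort
    (age 48-86 y, ~63% male, CrCl spanning roughly 15-255 mL/min); the
    regimen rule assigns q12h short infusions below 20 mL/min CrCl, as
    dosing guidance for severe renal impairment recommends.
    """

    n_subjects: int = 27
    age_range: tuple[float, float] = (48.0, 86.0)
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 12.0
    weight_min_kg: float = 40.0
    p_male: float = 0.63
    scr_log_median: float = 1.2     # mg/dL, log-normal median
    scr_log_sigma: float = 0.5
    q12h_crcl_cutoff_mL_min: float = 20.0
    sampling_times_h: tuple[float, ...] = (1.0, 4.0, 6.0, 8.0)
    steady_state_h: float = 40.0    # sample the interval containing this time
    horizon_h: float = 48.0
    population: NonparametricDistribution | None = None
    population_means: dict = field(default_factory=lambda: dict(REFERENCE_MEANS))
    population_sds: dict = field(default_factory=lambda: dict(REFERENCE_SDS))
    gamma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        interval = 8.0  # shortest dosing interval used
        if any(not 0 <= t <= interval + 4.0 for t in self.sampling_times_h):
            raise ValueError("sampling times must fall within a dosing interval")


@dataclass(frozen=True)
class SyntheticCohort:
    covariates: tuple[PatientCovariates, ...]
    crcl_mL_min: np.ndarray
    true_params: ParameterSample
    schedules: tuple[InfusionSchedule, ...]
    sample_interval_starts: np.ndarray  # h, start of the sampled interval
    config: CohortConfig

    @property
    def n(self) -> int:
        return len(self.covariates)


def _regimen(crcl_mL_min: float, config: CohortConfig) -> tuple[InfusionSchedule, float]:
    """Assigned schedule plus the start of the sampled steady interval."""
    if crcl_mL_min < config.q12h_crcl_cutoff_mL_min:
        interval, infusion = 12.0, 0.5
    else:
        interval, infusion = 8.0, 4.0
    events, t = [], 0.0
    while t + infusion <= config.horizon_h + 1e-9:
        events.append(InfusionEvent(t, infusion, 4000.0))
        t += interval
    starts = np.array([e.start_time for e in events])
    sample_start = float(starts[starts <= config.steady_state_h].max())
    return InfusionSchedule(tuple(events), horizon=config.horizon_h), sample_start


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Sample covariates, derive CrCl (Cockcroft-Gault), draw true PK
    parameters from the configured population, and assign regimens."""
    rng = np.random.default_rng(config.seed)
    age = rng.uniform(*config.age_range, size=config.n_subjects)
    sex = np.where(rng.random(config.n_subjects) < config.p_male, "male", "female")
    weight = rng.normal(config.weight_mean_kg, config.weight_sd_kg,
                        size=config.n_subjects)
    while np.any(weight <= config.weight_min_kg):
        bad = weight <= config.weight_min_kg
        weight[bad] = rng.normal(config.weight_mean_kg, config.weight_sd_kg,
                                 size=bad.sum())
    scr = rng.lognormal(np.log(config.scr_log_median), config.scr_log_sigma,
                        size=config.n_subjects)

    covs, crcls, schedules, starts = [], [], [], []
    for i in range(config.n_subjects):
        cov = PatientCovariates(
            age_years=float(age[i]),
            sex=str(sex[i]),
            weight_kg=float(weight[i]),
            serum_creatinine_mg_dl=float(scr[i]),
        )
        crcl = cockcroft_gault(cov)
        sched, start = _regimen(crcl, config)
        covs.append(cov)
        crcls.append(crcl)
        schedules.append(sched)
        starts.append(start)

    if config.population is not None:
        params = semiparametric_sample(config.population, config.n_subjects,
                                       seed=rng)
    else:
        params = parametric_sample(config.population_means, config.population_sds,
                                   config.n_subjects, seed=rng)
    return SyntheticCohort(
        covariates=tuple(covs),
        crcl_mL_min=np.array(crcls),
        true_params=params,
        schedules=tuple(schedules),
        sample_interval_starts=np.array(starts),
        config=config,
    )


def simulate_dataset(
    cohort: SyntheticCohort,
    error: AssayErrorModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[SubjectDataset]:
    """Noisy sparse observations for every subject in the cohort.

    Sampling times sit at the configured offsets into the steady-state
    dosing interval (the one containing `steady_state_h`, i.e. after
    roughly five half-lives of accumulation for typical parameters).
    Noise is independent normal with SD = assay SD at the prediction;
    negative values are clamped to 0 and values below 1 mg/L flagged as
    below the limit of quantification.
    """
    cfg = cohort.config
    error = error or AssayErrorModel(gamma=cfg.gamma)
    rng = np.random.default_rng(seed if seed is not None else cfg.seed + 1)
    subjects = []
    for i in range(cohort.n):
        times = cohort.sample_interval_starts[i] + np.asarray(cfg.sampling_times_h)
        p = cohort.true_params[i]
        crcl_L_h = float(cohort.crcl_mL_min[i]) * ML_MIN_TO_L_PER_H
        pred = predict_concentrations(
            cohort.schedules[i], times, p.intercept, p.slope, p.vc, crcl_L_h
        )
        if error.gamma > 0:
            noisy = pred + rng.normal(0.0, assay_sd(pred, error))
        else:
            noisy = pred.copy()
        noisy = np.clip(noisy, 0.0, None)
        subjects.append(
            SubjectDataset(
                subject_id=f"S{i + 1:03d}",
                schedule=cohort.schedules[i],
                times=times,
                concentrations=noisy,
                below_lloq=noisy < LLOQ_MG_L,
                covariates=cohort.covariates[i],
                crcl_mL_min=float(cohort.crcl_mL_min[i]),
            )
        )
    return subjects
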