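"""Goodness-of-fit diagnostics for the fitted population model.

Implements the standard pharmacometric battery: population and individual
(post-Bayesian) predictions with R² from observed-vs-predicted regression,
bias and imprecision of weighted residuals, normalised prediction
distribution errors (NPDE) with a Shapiro–Wilk normality check, and
visual-predictive-check (VPC) percentile bands.

All diagnostics are pure functions of (fit, data, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .npag_fit import FitResult, SubjectDataset, assay_sd, posterior_estimates
from .pk_model import predict_concentrations
from .population import semiparametric_sample

__all__ = [
    "NPDEResult",
    "predictions",
    "fit_metrics",
    "npde",
    "vpc",
]


@dataclass(frozen=True)
class NPDEResult:
    npde: np.ndarray
    mean: float
    variance: float
    shapiro_statistic: float
    shapiro_pvalue: float


def predictions(fit: FitResult, data: list[SubjectDataset],
                lloq_policy: str = "exclude") -> pd.DataFrame:
    """Observed vs predicted table, one row per usable observation.

    Population prediction: prior-weight-averaged prediction over support
    points.  Individual prediction: prediction at the subject's
    posterior-mean parameters.  Weighted residual: (obs − population
    prediction) / assay SD at the population prediction.
    """
    pts = fit.distribution.param_matrix
    w = fit.distribution.weights
    rows = []
    for s in data:
        times, obs = s.usable(lloq_policy)
        if len(times) == 0:
            continue
        per_point = predict_concentrations(
            s.schedule, times, pts[:, 0], pts[:, 1], pts[:, 2], s.crcl_L_per_h
        )
        pop = per_point @ w
        ip = posterior_estimates(fit, s, lloq_policy)
        ind = predict_concentrations(
            s.schedule, times, ip.intercept, ip.slope, ip.vc, s.crcl_L_per_h
        )
        wres = (obs - pop) / assay_sd(pop, fit.error)
        for t, o, pp, pi, r in zip(times, obs, pop, ind, wres):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "time_h": float(t),
                    "observed": float(o),
                    "pred_population": float(pp),
                    "pred_individual": float(pi),
                    "weighted_residual": float(r),
                }
            )
    return pd.DataFrame(rows)


def fit_metrics(preds: pd.DataFrame) -> dict[str, float]:
    """R² (population and individual), bias and imprecision.

    R² from least-squares regression of observed on predicted; bias is
    the mean weighted residual and imprecision the variance of the
    weighted residuals (mean square minus squared bias).
    """
    if len(preds) < 3:
        raise ValueError("need at least 3 observations")
    out = {}
    for level in ("population", "individual"):
        pred = preds[f"pred_{level}"].to_numpy()
        obs = preds["observed"].to_numpy()
        if np.ptp(pred) == 0:
            raise ValueError(f"{level} predictions have zero variance; R² undefined")
        if np.ptp(obs) == 0:
            r2 = 1.0 if np.allclose(obs, pred) else 0.0
        else:
            r = stats.linregress(pred, obs)
            r2 = float(r.rvalue**2)
        out[f"r2_{level[:3] if level == 'population' else 'ind'}"] = r2
    wres = preds["weighted_residual"].to_numpy()
    bias = float(np.mean(wres))
    out["bias"] = bias
    out["imprecision"] = float(np.mean(wres**2) - bias**2)
    return out


def _simulate_subject(
    fit: FitResult,
    subject: SubjectDataset,
    nsim: int,
    rng: np.random.Generator,
    lloq_policy: str = "exclude",
) -> tuple[np.ndarray, np.ndarray]:
    """(observed vector, (nsim, n_obs) simulated matrix) for one subject."""
    times, obs = subject.usable(lloq_policy)
    draws = semiparametric_sample(fit.distribution, nsim, seed=rng)
    pred = predict_concentrations(
        subject.schedule, times, draws.intercept, draws.slope, draws.vc,
        subject.crcl_L_per_h,
    ).T  # (nsim, n_obs)
    sd = assay_sd(pred, fit.error) if fit.gamma > 0 else 0.0
    sims = pred if np.isscalar(sd) and sd == 0.0 else pred + rng.normal(0.0, 1.0, pred.shape) * sd
    return obs, sims


def npde(
    fit: FitResult,
    data: list[SubjectDataset],
    nsim: int = 1000,
    seed: int | np.random.Generator | None = None,
    lloq_policy: str = "exclude",
) -> NPDEResult:
    """Normalised prediction distribution errors.

    Per subject, `nsim` replicate observation vectors are simulated under
    the fitted model and assay error; observations and simulations are
    decorrelated with the inverse Cholesky factor of the empirical
    simulation covariance; the prediction discrepancy (fraction of
    decorrelated simulations below the decorrelated observation, with a
    1/(2·nsim) continuity correction at 0 and 1) is mapped through the
    standard-normal quantile.  Under a correct model the pooled npde are
    iid N(0, 1); a Shapiro–Wilk statistic on the pooled values is
    reported.
    """
    if nsim < 200:
        raise ValueError("nsim must be >= 200")
    rng = np.random.default_rng(seed)
    eps = 1.0 / (2.0 * nsim)
    pooled = []
    for s in data:
        obs, sims = _simulate_subject(fit, s, nsim, rng, lloq_policy)
        if len(obs) == 0:
            continue
        mean = sims.mean(axis=0)
        cov = np.cov(sims, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            chol = np.linalg.cholesky(cov)
            dec_obs = np.linalg.solve(chol, obs - mean)
            dec_sims = np.linalg.solve(chol, (sims - mean).T).T
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular simulation covariance for {s.subject_id}; "
                "falling back to the marginal (uncorrelated) variant",
                RuntimeWarning,
            )
            sd = sims.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            dec_obs = (obs - mean) / sd
            dec_sims = (sims - mean) / sd
        pde = (dec_sims < dec_obs).mean(axis=0)
        pde = np.clip(pde, eps, 1.0 - eps)
        pooled.append(stats.norm.ppf(pde))
    values = np.concatenate(pooled)
    sw = stats.shapiro(values)
    return NPDEResult(
        npde=values,
        mean=float(values.mean()),
        variance=float(values.var(ddof=1)),
        shapiro_statistic=float(sw.statistic),
        shapiro_pvalue=float(sw.pvalue),
    )


def vpc(
    fit: FitResult,
    data: list[SubjectDataset],
    nsim: int = 1000,
    bins: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
    lloq_policy: str = "exclude",
) -> pd.DataFrame:
    """Visual-predictive-check bands at the observed sampling design.

    Observations are grouped by time-after-last-relevant sample time: by
    default one bin per distinct observation time (suiting the fixed
    1/4/6/8 h design); `bins` gives explicit edges instead.  Per bin the
    observed percentiles and the percentiles of the pooled simulated
    observations are reported.
    """
    if nsim < 200:
        raise ValueError("nsim must be >= 200")
    rng = np.random.default_rng(seed)
    all_times, all_obs, all_sims = [], [], []
    for s in data:
        obs, sims = _simulate_subject(fit, s, nsim, rng, lloq_policy)
        times, _ = s.usable(lloq_policy)
        if len(obs) == 0:
            continue
        # express times as offsets into the sampled dosing interval so
        # q8h and q12h subjects can share bins
        starts = np.array([e.start_time for e in s.schedule.events])
        offsets = np.array([t - starts[starts <= t].max() for t in times])
        all_times.append(offsets)
        all_obs.append(obs)
        all_sims.append(sims)
    t = np.concatenate(all_times)
    y = np.concatenate(all_obs)
    sims = np.hstack(all_sims)  # (nsim, total_obs)

    if bins is None:
        edges_ids = {v: i for i, v in enumerate(np.unique(t))}
        bin_ids = np.array([edges_ids[v] for v in t])
        centers = np.unique(t)
    else:
        bins = np.asarray(bins, dtype=float)
        bin_ids = np.digitize(t, bins) - 1
        centers = 0.5 * (bins[:-1] + bins[1:])

    rows = []
    for b in np.unique(bin_ids):
        mask = bin_ids == b
        if b < 0 or (bins is not None and b >= len(bins) - 1) or mask.sum() == 0:
            warnings.warn(f"dropping empty/out-of-range VPC bin {b}", RuntimeWarning)
            continue
        obs_p = np.percentile(y[mask], percentiles)
        sim_p = np.percentile(sims[:, mask], percentiles)
        rows.append(
            {
                "bin": int(b),
                "time_h": float(centers[b]),
                "n_obs": int(mask.sum()),
                "obs_p5": obs_p[0], "obs_p50": obs_p[1], "obs_p95": obs_p[2],
                "sim_p5": sim_p[0], "sim_p50": sim_p[1], "sim_p95": sim_p[2],
            }
        )
    return pd.DataFrame(rows)
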