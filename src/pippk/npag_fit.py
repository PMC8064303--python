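"""Nonparametric maximum-likelihood population estimation on an adaptive grid.

The population distribution over (intercept, slope, Vc) is estimated as a
discrete mixing distribution: support points with probability weights that
maximise the marginal likelihood

    LL(w, points, gamma) = sum_i log sum_j w_j L_ij

where L_ij is subject i's observation likelihood at point j under the
residual model

    SD(C) = gamma * (c0 + c1 * C),    c0 = 0.4388 mg/L, c1 = 0.027,

the proportional-polynomial inter-day assay-error model with a process-
noise multiplier gamma.  The algorithm follows the nonparametric adaptive
grid (NPAG) outline:

1. seed a low-discrepancy (Sobol) grid of candidate points in a box;
2. solve the convex weight sub-problem by EM multiplicative updates;
3. prune negligible-weight points, then propose +/- delta per-dimension
   perturbations of the survivors, keeping them only when the objective
   rises; shrink delta geometrically when no proposal helps;
4. re-estimate gamma by bounded 1-D maximisation of the total likelihood;
5. cycle until the improvement at the minimum delta falls below tolerance.

This is a deliberately compact NPAG: no D-optimality candidate generation,
plain shrink-and-perturb refinement.  The estimand — the nonparametric
MLE of the mixing distribution — is the same.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import qmc

from .pk_model import InfusionSchedule, PKParameters, predict_concentrations
from .population import NonparametricDistribution, SupportPoint
from .renal import ML_MIN_TO_L_PER_H, PatientCovariates

__all__ = [
    "AssayErrorModel",
    "SubjectDataset",
    "ParameterBounds",
    "NpagConfig",
    "FitResult",
    "assay_sd",
    "subject_loglik",
    "solve_weights",
    "npag_fit",
    "posterior_estimates",
    "covariate_screen",
]

LLOQ_MG_L = 1.0

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class AssayErrorModel:
    """SD(C) = gamma * (c0 + c1 * C); defaults from assay quality-control."""

    c0: float = 0.4388
    c1: float = 0.027
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.c1 < 0:
            raise ValueError("require c0 > 0 and c1 >= 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def assay_sd(conc: float | np.ndarray, error: AssayErrorModel) -> float | np.ndarray:
    """Assay/residual SD (mg/L) at concentration `conc`."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    out = error.gamma * (error.c0 + error.c1 * conc)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SubjectDataset:
    """One subject's dosing history, sparse observations and covariates."""

    subject_id: str
    schedule: InfusionSchedule
    times: np.ndarray                 # observation times, h
    concentrations: np.ndarray        # observed total conc, mg/L
    below_lloq: np.ndarray            # bool flags
    covariates: PatientCovariates | None = None
    crcl_mL_min: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        q = np.asarray(self.below_lloq, dtype=bool)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "below_lloq", q)
        if not (len(t) == len(c) == len(q)):
            raise ValueError("times/concentrations/flags must share a length")
        if np.any(t < 0) or np.any(c < 0):
            raise ValueError("times and concentrations must be >= 0")
        if self.crcl_mL_min <= 0:
            raise ValueError("creatinine clearance must be > 0")

    @property
    def crcl_L_per_h(self) -> float:
        return self.crcl_mL_min * ML_MIN_TO_L_PER_H

    def usable(self, lloq_policy: str = "exclude") -> tuple[np.ndarray, np.ndarray]:
        """(times, concentrations) entering the likelihood.

        ``"exclude"`` drops observations flagged below the 1 mg/L LLOQ;
        ``"half"`` substitutes LLOQ/2 for them.
        """
        if lloq_policy == "exclude":
            keep = ~self.below_lloq
            return self.times[keep], self.concentrations[keep]
        if lloq_policy == "half":
            conc = np.where(self.below_lloq, LLOQ_MG_L / 2.0, self.concentrations)
            return self.times, conc
        raise ValueError(f"unknown lloq_policy {lloq_policy!r}")


@dataclass(frozen=True)
class ParameterBounds:
    """Search box per parameter; generous around published adult estimates."""

    intercept: tuple[float, float] = (0.01, 50.0)
    slope: tuple[float, float] = (0.001, 10.0)
    vc: tuple[float, float] = (1.0, 200.0)

    def __post_init__(self) -> None:
        for name in ("intercept", "slope", "vc"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    @property
    def lows(self) -> np.ndarray:
        return np.array([self.intercept[0], self.slope[0], self.vc[0]])

    @property
    def highs(self) -> np.ndarray:
        return np.array([self.intercept[1], self.slope[1], self.vc[1]])


@dataclass(frozen=True)
class NpagConfig:
    n_grid: int = 2048
    max_cycles: int = 200
    delta_init: float = 0.2        # perturbation, fraction of each range
    delta_min: float = 0.001
    ll_tol: float = 1e-4
    sweep_tol: float = 0.01       # stop when a full delta sweep gains less
    prune_rel: float = 1e-8        # drop weights below prune_rel * max weight
    estimate_gamma: bool = True
    gamma_bounds: tuple[float, float] = (0.05, 20.0)
    lloq_policy: str = "exclude"
    seed: int = 20210348


@dataclass(frozen=True)
class FitResult:
    distribution: NonparametricDistribution
    error: AssayErrorModel            # with the fitted gamma
    log_likelihood: float
    cycles: int
    converged: bool
    ll_trace: tuple[float, ...] = field(default_factory=tuple)

    @property
    def gamma(self) -> float:
        return self.error.gamma


def subject_loglik(
    subject: SubjectDataset,
    params: PKParameters,
    error: AssayErrorModel,
    lloq_policy: str = "exclude",
) -> float:
    """Normal log-likelihood of one subject's observations at `params`."""
    times, obs = subject.usable(lloq_policy)
    if len(times) == 0:
        return 0.0
    pred = predict_concentrations(
        subject.schedule, times, params.intercept, params.slope, params.vc,
        subject.crcl_L_per_h,
    )
    sd = assay_sd(pred, error)
    if np.any(sd <= 0):
        raise ZeroDivisionError("assay SD is zero; gamma must be > 0")
    z = (obs - pred) / sd
    return float(np.sum(-0.5 * z**2 - np.log(sd) - 0.5 * _LOG_2PI))


def solve_weights(
    L: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 20000,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Maximise sum_i log sum_j w_j L_ij over the probability simplex.

    EM multiplicative updates (from a uniform start unless `w0` warm-starts
    the iteration):
        w_j <- w_j * (1/N) sum_i L_ij / (L w)_i
    The problem is concave in w, so the fixed point is the global optimum.
    Returns (weights, objective).  `L` may be row-scaled by the caller; the
    argmax is invariant to per-row scaling.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2:
        raise ValueError("L must be 2-D (subjects x points)")
    if np.any(~np.isfinite(L)) or np.any(L < 0):
        raise ValueError("L must be finite and non-negative")
    row_max = L.max(axis=1)
    if np.any(row_max <= 0):
        bad = np.where(row_max <= 0)[0]
        raise ValueError(
            f"subjects {bad.tolist()} have zero likelihood at every support "
            "point: data/model mismatch or bounds too narrow"
        )
    n, p = L.shape
    if w0 is not None:
        w = np.clip(np.asarray(w0, dtype=float), 1e-300, None)
        w = w / w.sum()
    else:
        w = np.full(p, 1.0 / p)

    # Active-set accelerated EM.  SQUAREM-style extrapolation can clip a
    # weight to zero that the multiplicative map could never revive, so
    # after each inner convergence the Karush-Kuhn-Tucker condition
    #     g_j = (1/N) sum_i L_ij / (L w)_i <= 1   (= 1 on the support)
    # is checked over *all* columns and any violating column is
    # reactivated with a small weight.
    active = np.arange(p)
    evals = 0

    def em(La: np.ndarray, wa: np.ndarray) -> np.ndarray:
        nonlocal evals
        evals += 1
        out = wa * (La.T @ (1.0 / (La @ wa))) / n
        return out / out.sum()

    wa = w[active] / w[active].sum()
    obj = float(np.sum(np.log(L[:, active] @ wa)))
    while evals < max_iter:
        La = L[:, active]

        def objective(v: np.ndarray) -> float:
            return float(np.sum(np.log(La @ v)))

        # ---- inner accelerated EM on the current active set
        while evals < max_iter:
            w1 = em(La, wa)
            w2 = em(La, w1)
            r = w1 - wa
            v = (w2 - w1) - r
            nv = float(np.dot(v, v))
            if nv > 0:
                alpha = -np.sqrt(float(np.dot(r, r)) / nv)
                cand = np.clip(wa - 2.0 * alpha * r + alpha * alpha * v, 0.0, None)
                s = cand.sum()
                if s > 0:
                    cand = em(La, cand / s)  # stabilising EM step
                    if objective(cand) >= objective(w2):
                        w2 = cand
            new_obj = objective(w2)
            wa = w2
            if new_obj - obj < tol:
                obj = max(new_obj, obj)
                break
            obj = new_obj
            # shed numerically dead columns (reactivated below if KKT-live)
            live = wa > 1e-14 * wa.max()
            if not np.all(live):
                active = active[live]
                La = L[:, active]
                wa = wa[live] / wa[live].sum()

        # ---- KKT screen over all columns
        w_full = np.zeros(p)
        w_full[active] = wa
        g = (L.T @ (1.0 / (L @ w_full))) / n
        viol = np.where((w_full <= 0) & (g > 1.0 + 1e-9))[0]
        if len(viol) == 0:
            break
        active = np.unique(np.concatenate([active, viol]))
        w_full[viol] = max(1e-3 / p, 1e-12)
        wa = w_full[active] / w_full[active].sum()
        obj = float(np.sum(np.log(L[:, active] @ wa)))
    w = np.zeros(p)
    w[active] = wa / wa.sum()
    return w, obj


# ---------------------------------------------------------------------------
# npag_fit internals: predictions for every (subject, point) pair are cached
# so that gamma re-estimation and weight solving never re-run the PK model.
# ---------------------------------------------------------------------------


class _Cache:
    """Per-subject observation vectors and per-point predicted matrices."""

    def __init__(self, data, lloq_policy: str):
        self.subjects = data
        self.obs = []
        self.times = []
        for s in data:
            t, c = s.usable(lloq_policy)
            self.times.append(t)
            self.obs.append(c)
        if all(len(t) == 0 for t in self.times):
            raise ValueError("no usable observations in the dataset")

    def predict(self, points: np.ndarray) -> list[np.ndarray]:
        """List over subjects of (n_obs_i, n_points) predicted conc."""
        out = []
        for s, t in zip(self.subjects, self.times):
            if len(t) == 0:
                out.append(np.zeros((0, len(points))))
                continue
            out.append(
                predict_concentrations(
                    s.schedule, t, points[:, 0], points[:, 1], points[:, 2],
                    s.crcl_L_per_h,
                )
            )
        return out


def _loglik_matrix(
    cache: _Cache, preds: list[np.ndarray], error: AssayErrorModel
) -> np.ndarray:
    """(n_subjects, n_points) matrix of per-subject log-likelihoods."""
    rows = []
    for obs, pred in zip(cache.obs, preds):
        if len(obs) == 0:
            rows.append(np.zeros(pred.shape[1]))
            continue
        sd = error.gamma * (error.c0 + error.c1 * pred)
        z = (obs[:, None] - pred) / sd
        rows.append(np.sum(-0.5 * z**2 - np.log(sd) - 0.5 * _LOG_2PI, axis=0))
    return np.vstack(rows)


def _scaled_likelihood(logL: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-scaled likelihoods and the log offsets removed per row."""
    off = logL.max(axis=1)
    return np.exp(logL - off[:, None]), off


def _objective(logL: np.ndarray, w: np.ndarray) -> float:
    L, off = _scaled_likelihood(logL)
    mix = L @ w
    return float(np.sum(np.log(np.clip(mix, 1e-300, None)) + off))


def _solve(logL: np.ndarray, w0: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    L, off = _scaled_likelihood(logL)
    w, obj = solve_weights(L, w0=w0)
    return w, obj + float(off.sum())


def npag_fit(
    data,
    bounds: ParameterBounds | None = None,
    config: NpagConfig | None = None,
    fix_slope: float | None = None,
) -> FitResult:
    """Fit the nonparametric population model to a list of SubjectDataset.

    `fix_slope` pins the clearance-vs-CrCl slope (e.g. 0.0 for the
    no-covariate reduced model); the adaptive search then runs over
    (intercept, Vc) only.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 subjects")
    bounds = bounds or ParameterBounds()
    config = config or NpagConfig()
    cache = _Cache(data, config.lloq_policy)
    rng_seed = config.seed

    lows, highs = bounds.lows.copy(), bounds.highs.copy()
    free = np.array([True, fix_slope is None, True])
    dims = int(free.sum())

    sob = qmc.Sobol(d=dims, scramble=True, seed=rng_seed)
    unit = sob.random(config.n_grid)
    points = np.empty((config.n_grid, 3))
    points[:, free] = lows[free] + unit * (highs[free] - lows[free])
    if fix_slope is not None:
        points[:, 1] = fix_slope

    error = AssayErrorModel()
    preds = cache.predict(points)

    def logL_for(preds_list, err):
        return _loglik_matrix(cache, preds_list, err)

    logL = logL_for(preds, error)
    w, ll = _solve(logL)
    delta = config.delta_init
    trace: list[float] = []
    converged = False
    improved_since_reset = False
    ll_sweep_start = ll
    cycles = 0

    for cycle in range(1, config.max_cycles + 1):
        cycles = cycle
        # -- prune
        keep = w > config.prune_rel * w.max()
        points, w = points[keep], w[keep]
        preds = [p[:, keep] for p in preds]
        logL = logL[:, keep]
        w = w / w.sum()

        improved = False

        # -- adaptive expansion: +/- delta per free dimension
        cands = []
        for j in np.where(free)[0]:
            step = delta * (highs[j] - lows[j])
            for sign in (+1.0, -1.0):
                moved = points.copy()
                moved[:, j] = np.clip(moved[:, j] + sign * step, lows[j], highs[j])
                cands.append(moved)
        cand = np.unique(np.vstack(cands), axis=0)
        cand_preds = cache.predict(cand)
        all_points = np.vstack([points, cand])
        all_preds = [np.hstack([p, cp]) for p, cp in zip(preds, cand_preds)]
        all_logL = logL_for(all_preds, error)
        w_start = np.concatenate(
            [0.95 * w, np.full(len(cand), 0.05 / max(len(cand), 1))]
        )
        w_new, ll_new = _solve(all_logL, w0=w_start)
        if ll_new > ll + config.ll_tol:
            points, w, preds, logL = all_points, w_new, all_preds, all_logL
            ll = ll_new
            improved = True

        # -- gamma step (monotone: keeps the better of old/new gamma)
        if config.estimate_gamma:
            current_preds = preds

            def neg_ll(g: float) -> float:
                err_g = replace(error, gamma=float(g))
                return -_objective(logL_for(current_preds, err_g), w)

            res = minimize_scalar(
                neg_ll, bounds=config.gamma_bounds, method="bounded",
                options={"xatol": 1e-4},
            )
            gain = -res.fun - ll
            if gain > 0:
                error = replace(error, gamma=float(res.x))
                logL = logL_for(preds, error)
                w, ll = _solve(logL, w0=w)
                if gain > config.ll_tol:
                    improved = True

        trace.append(ll)
        if improved:
            improved_since_reset = True
        else:
            if delta <= config.delta_min:
                # one full delta sweep with no gain anywhere -> done;
                # otherwise re-expand and sweep again (the refinement can
                # open new basins for the coarse perturbations)
                if (not improved_since_reset
                        or ll - ll_sweep_start < config.sweep_tol):
                    converged = True
                    break
                delta = config.delta_init
                improved_since_reset = False
                ll_sweep_start = ll
            else:
                delta = max(delta * 0.5, config.delta_min)

    if not converged:
        warnings.warn(
            f"NPAG did not converge within {config.max_cycles} cycles "
            f"(last LL {ll:.4f})",
            RuntimeWarning,
        )

    keep = w > config.prune_rel * w.max()
    points, w = points[keep], w[keep]
    w = w / w.sum()
    dist = _distribution_from(points, w)
    return FitResult(
        distribution=dist,
        error=error,
        log_likelihood=ll,
        cycles=cycles,
        converged=converged,
        ll_trace=tuple(trace),
    )


def _distribution_from(points: np.ndarray, w: np.ndarray) -> NonparametricDistribution:
    mean = w @ points
    centred = points - mean
    cov = (centred * w[:, None]).T @ centred
    cov = 0.5 * (cov + cov.T)
    sps = tuple(
        SupportPoint(PKParameters(*map(float, pt)), float(wi))
        for pt, wi in zip(points, w / w.sum())
    )
    return NonparametricDistribution(points=sps, covariance=cov)


def posterior_estimates(
    fit: FitResult,
    subject: SubjectDataset,
    lloq_policy: str = "exclude",
) -> PKParameters:
    """Posterior-mean parameters for one subject under the fitted prior.

    Posterior weight of point j is proportional to w_j * L_j(subject);
    with no usable observations the prior weighted mean is returned.
    """
    pts = fit.distribution.param_matrix
    w = fit.distribution.weights
    logL = np.array(
        [
            subject_loglik(subject, PKParameters(*map(float, p)), fit.error,
                           lloq_policy)
            for p in pts
        ]
    )
    post = w * np.exp(logL - logL.max())
    total = post.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("zero posterior mass: subject incompatible with fit")
    post /= total
    mean = post @ pts
    return PKParameters(float(mean[0]), float(mean[1]), float(mean[2]))


def covariate_screen(
    data,
    bounds: ParameterBounds | None = None,
    config: NpagConfig | None = None,
) -> float:
    """Forward-inclusion statistic for CrCl on clearance.

    Fits the full model (CL = intercept + slope * CrCl) and the reduced
    model (slope fixed at 0) and returns 2 * (LL_full - LL_reduced).
    Positive values favour including the covariate; the accept/reject
    threshold is left to the analyst.
    """
    full = npag_fit(data, bounds, config)
    reduced = npag_fit(data, bounds, config, fix_slope=0.0)
    for fit, name in ((full, "full"), (reduced, "reduced")):
        if not fit.converged:
            warnings.warn(f"{name} model did not converge", RuntimeWarning)
    return 2.0 * (full.log_likelihood - reduced.log_likelihood)
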