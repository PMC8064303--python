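"""Population models: discrete support-point distributions and samplers.

The fitted population is a nonparametric distribution — a small set of
support points (parameter vectors) with probability weights — plus the
full-model covariance matrix.  Virtual patients are drawn either

* semi-parametrically: pick a support point by its weight, then draw from
  a multivariate normal centred at it with covariance = full covariance /
  number of points (the standard smoothed-nonparametric simulation method
  in Pmetrics-style workflows), or
* parametrically: independent log-normals moment-matched to published
  mean/SD estimates, used when the support points of a fitted model are
  not available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pk_model import PKParameters

__all__ = [
    "SupportPoint",
    "NonparametricDistribution",
    "ParameterSample",
    "semiparametric_sample",
    "parametric_sample",
    "weighted_summary",
    "REFERENCE_MEANS",
    "REFERENCE_SDS",
    "REFERENCE_MEDIANS",
    "reference_parametric_sample",
]

PARAM_NAMES = ("intercept", "slope", "vc")

#: Published adult population estimates (mean, SD, median) for piperacillin
#: in non-critically ill patients with Enterobacteriaceae bacteraemia:
#: clearance intercept (L/h), clearance-vs-CrCl slope, central volume (L).
REFERENCE_MEANS = {"intercept": 4.556, "slope": 1.353, "vc": 30.68}
REFERENCE_SDS = {"intercept": 5.035, "slope": 1.032, "vc": 23.349}
REFERENCE_MEDIANS = {"intercept": 3.503, "slope": 1.39, "vc": 20.039}


@dataclass(frozen=True)
class SupportPoint:
    params: PKParameters
    weight: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class NonparametricDistribution:
    """Weighted support points plus the full-model covariance (3x3)."""

    points: tuple[SupportPoint, ...]
    covariance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", cov)
        if not self.points:
            raise ValueError("at least one support point required")
        w = self.weights
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric 3x3")
        if np.min(np.linalg.eigvalsh(0.5 * (cov + cov.T))) < -1e-8:
            raise ValueError("covariance must be positive semi-definite")

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.points])

    @property
    def param_matrix(self) -> np.ndarray:
        """(n_points, 3) array ordered (intercept, slope, vc)."""
        return np.array(
            [[p.params.intercept, p.params.slope, p.params.vc] for p in self.points]
        )


@dataclass(frozen=True)
class ParameterSample:
    """`n` virtual-patient parameter vectors, as parallel arrays."""

    intercept: np.ndarray
    slope: np.ndarray
    vc: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if not (len(self.intercept) == len(self.slope) == len(self.vc)):
            raise ValueError("parameter arrays must share a length")

    @property
    def n(self) -> int:
        return len(self.intercept)

    def __getitem__(self, i: int) -> PKParameters:
        return PKParameters(
            float(self.intercept[i]), float(self.slope[i]), float(self.vc[i])
        )


def _valid(draws: np.ndarray) -> np.ndarray:
    """Positivity mask: intercept >= 0, slope >= 0, vc > 0."""
    return (draws[:, 0] >= 0) & (draws[:, 1] >= 0) & (draws[:, 2] > 0)


def semiparametric_sample(
    dist: NonparametricDistribution,
    n: int,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 1000,
) -> ParameterSample:
    """Draw `n` patients from the smoothed support-point mixture.

    Component j is chosen with probability = its weight; the draw is
    multivariate normal centred at point j with covariance = full-model
    covariance divided by the number of points.  Draws violating parameter
    positivity are rejected and redrawn (at most `max_attempts` rounds).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    means = dist.param_matrix
    cov = dist.covariance / len(dist.points)
    comp = rng.choice(len(dist.points), size=n, p=dist.weights)
    draws = np.empty((n, 3))
    pending = np.arange(n)
    for _ in range(max_attempts):
        z = rng.multivariate_normal(np.zeros(3), cov, size=len(pending),
                                    method="cholesky" if _is_pd(cov) else "svd")
        draws[pending] = means[comp[pending]] + z
        ok = _valid(draws[pending])
        pending = pending[~ok]
        if len(pending) == 0:
            break
    else:
        raise RuntimeError(
            f"rejection sampling failed for {len(pending)} draws after "
            f"{max_attempts} attempts; check the covariance scale"
        )
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return ParameterSample(draws[:, 0], draws[:, 1], draws[:, 2], seed=seed_val)


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def parametric_sample(
    means: Sequence[float] | dict,
    sds: Sequence[float] | dict,
    n: int,
    seed: int | np.random.Generator | None = None,
    distribution: str = "lognormal",
) -> ParameterSample:
    """Independent per-parameter draws moment-matched to (mean, SD).

    ``distribution="lognormal"`` (default) matches the arithmetic mean and
    SD of a log-normal — no probability mass at or below zero, which
    matters here because the published SDs exceed the means.  The
    documented alternative ``"truncnorm"`` is a normal truncated at zero
    with the *pre-truncation* moments set to (mean, SD).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = _as_triplet(means)
    s = _as_triplet(sds)
    if np.any(m <= 0):
        raise ValueError("means must be positive")
    if np.any(s < 0):
        raise ValueError("SDs must be >= 0")
    rng = np.random.default_rng(seed)
    draws = np.empty((n, 3))
    for j in range(3):
        if s[j] == 0:
            draws[:, j] = m[j]
        elif distribution == "lognormal":
            sigma2 = np.log1p((s[j] / m[j]) ** 2)
            mu = np.log(m[j]) - 0.5 * sigma2
            draws[:, j] = rng.lognormal(mu, np.sqrt(sigma2), size=n)
        elif distribution == "truncnorm":
            a = (0.0 - m[j]) / s[j]
            draws[:, j] = stats.truncnorm.rvs(
                a, np.inf, loc=m[j], scale=s[j], size=n, random_state=rng
            )
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return ParameterSample(draws[:, 0], draws[:, 1], draws[:, 2], seed=seed_val)


def reference_parametric_sample(
    n: int,
    seed: int | np.random.Generator | None = None,
    distribution: str = "lognormal",
) -> ParameterSample:
    """Virtual patients from the published mean/SD estimates (log-normal)."""
    return parametric_sample(REFERENCE_MEANS, REFERENCE_SDS, n, seed, distribution)


def _as_triplet(x: Sequence[float] | dict) -> np.ndarray:
    if isinstance(x, dict):
        return np.array([x[k] for k in PARAM_NAMES], dtype=float)
    return np.asarray(x, dtype=float)


def weighted_summary(dist: NonparametricDistribution) -> pd.DataFrame:
    """Weighted mean, SD and marginal median of each parameter.

    The weighted median is the smallest support value whose cumulative
    weight reaches 0.5.
    """
    w = dist.weights
    pm = dist.param_matrix
    rows = {}
    for j, name in enumerate(PARAM_NAMES):
        v = pm[:, j]
        mean = float(np.sum(w * v))
        var = float(np.sum(w * (v - mean) ** 2))
        order = np.argsort(v)
        cum = np.cumsum(w[order])
        median = float(v[order][np.searchsorted(cum, 0.5)])
        rows[name] = {"mean": mean, "sd": np.sqrt(max(var, 0.0)), "median": median}
    return pd.DataFrame(rows).T[["mean", "sd", "median"]]
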