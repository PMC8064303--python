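"""Prediction tables, fit metrics, NPDE and VPC behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pippk import (
    AssayErrorModel,
    FitResult,
    InfusionEvent,
    InfusionSchedule,
    NonparametricDistribution,
    PKParameters,
    SubjectDataset,
    SupportPoint,
    concentration_at,
    fit_metrics,
    npde,
    predictions,
    vpc,
)


def _point_fit(params=(4.0, 1.3, 30.0), gamma=1.0, cov_scale=0.0):
    dist = NonparametricDistribution(
        points=(SupportPoint(PKParameters(*params), 1.0),),
        covariance=np.eye(3) * cov_scale,
    )
    return FitResult(
        distribution=dist,
        error=AssayErrorModel(gamma=gamma),
        log_likelihood=0.0,
        cycles=1,
        converged=True,
    )


def _noiseless_subjects(fit, n=3):
    """Subjects whose observations equal the fit's noise-free predictions."""
    p = fit.distribution.points[0].params
    sched = InfusionSchedule(
        tuple(InfusionEvent(t, 4.0, 4000.0) for t in (0, 8, 16, 24, 32, 40)),
        horizon=48.0,
    )
    out = []
    for i, crcl in enumerate(np.linspace(40.0, 140.0, n)):
        times = np.array([41.0, 44.0, 46.0, 48.0])
        conc = np.array(
            [concentration_at(sched, p, crcl * 0.06, t) for t in times]
        )
        out.append(
            SubjectDataset(f"S{i}", sched, times, conc,
                           np.zeros(4, dtype=bool), crcl_mL_min=crcl)
        )
    return out


class TestPredictions:
    def test_noiseless_single_point_is_exact(self):
        fit = _point_fit()
        data = _noiseless_subjects(fit)
        preds = predictions(fit, data)
        np.testing.assert_allclose(
            preds["pred_individual"], preds["observed"], rtol=1e-9
        )
        np.testing.assert_allclose(
            preds["pred_population"], preds["observed"], rtol=1e-9
        )

    def test_observation_order_invariance(self):
        fit = _point_fit()
        data = _noiseless_subjects(fit)
        preds = predictions(fit, data)
        reversed_data = list(reversed(data))
        preds_rev = predictions(fit, reversed_data)
        a = preds.sort_values(["subject_id", "time_h"]).reset_index(drop=True)
        b = preds_rev.sort_values(["subject_id", "time_h"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestFitMetrics:
    def test_perfect_predictions(self):
        fit = _point_fit()
        preds = predictions(fit, _noiseless_subjects(fit))
        m = fit_metrics(preds)
        assert m["r2_pop"] == pytest.approx(1.0)
        assert m["r2_ind"] == pytest.approx(1.0)
        assert m["bias"] == pytest.approx(0.0, abs=1e-9)
        assert m["imprecision"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_bias(self):
        # predictions = obs + c at SD = 1 -> bias = -c, imprecision = 0
        df = pd.DataFrame(
            {
                "observed": [10.0, 20.0, 30.0],
                "pred_population": [13.0, 23.0, 33.0],
                "pred_individual": [13.0, 23.0, 33.0],
                "weighted_residual": [-3.0, -3.0, -3.0],
            }
        )
        m = fit_metrics(df)
        assert m["bias"] == pytest.approx(-3.0)
        assert m["imprecision"] == pytest.approx(0.0)
        assert m["r2_pop"] == pytest.approx(1.0)  # linear relation

    def test_random_set_matches_formula_oracle(self):
        rng = np.random.default_rng(8)
        obs = rng.uniform(5.0, 120.0, 20)
        pred = obs + rng.normal(0.0, 6.0, 20)
        wres = rng.normal(0.0, 1.0, 20)
        df = pd.DataFrame(
            {
                "observed": obs,
                "pred_population": pred,
                "pred_individual": pred,
                "weighted_residual": wres,
            }
        )
        m = fit_metrics(df)
        r2 = np.corrcoef(pred, obs)[0, 1] ** 2
        assert m["r2_pop"] == pytest.approx(r2)
        assert m["bias"] == pytest.approx(wres.mean())
        assert m["imprecision"] == pytest.approx(wres.var())

    def test_too_few_observations(self):
        df = pd.DataFrame(
            {
                "observed": [1.0, 2.0],
                "pred_population": [1.0, 2.0],
                "pred_individual": [1.0, 2.0],
                "weighted_residual": [0.0, 0.0],
            }
        )
        with pytest.raises(ValueError):
            fit_metrics(df)


class TestNpde:
    def test_calibrated_under_true_model(self):
        # data simulated from the fit itself (point-mass population, assay
        # noise only) -> npde ~ N(0, 1)
        fit = _point_fit(cov_scale=0.0, gamma=1.0)
        rng = np.random.default_rng(5)
        data = []
        base = _noiseless_subjects(fit, n=25)
        from pippk import assay_sd

        for s in base:
            noisy = s.concentrations + rng.normal(
                0.0, assay_sd(s.concentrations, fit.error)
            )
            data.append(
                SubjectDataset(s.subject_id, s.schedule, s.times,
                               np.clip(noisy, 0.0, None),
                               s.below_lloq, crcl_mL_min=s.crcl_mL_min)
            )
        res = npde(fit, data, nsim=400, seed=9)
        assert abs(res.mean) < 0.35
        assert 0.5 < res.variance < 1.6

    def test_requires_enough_simulations(self):
        fit = _point_fit()
        with pytest.raises(ValueError):
            npde(fit, _noiseless_subjects(fit), nsim=50)

    def test_deterministic_given_seed(self):
        fit = _point_fit(cov_scale=0.1)
        data = _noiseless_subjects(fit, n=5)
        a = npde(fit, data, nsim=300, seed=4)
        b = npde(fit, data, nsim=300, seed=4)
        np.testing.assert_array_equal(a.npde, b.npde)


class TestVpc:
    def test_band_ordering(self):
        fit = _point_fit(cov_scale=0.25)
        data = _noiseless_subjects(fit, n=10)
        bands = vpc(fit, data, nsim=300, seed=2)
        assert np.all(bands["sim_p5"] <= bands["sim_p50"])
        assert np.all(bands["sim_p50"] <= bands["sim_p95"])

    def test_zero_noise_single_point_collapse(self):
        # one subject, point-mass prior, no assay noise: every simulated
        # percentile collapses onto the deterministic prediction curve
        fit = _point_fit(gamma=0.0)
        data = _noiseless_subjects(fit, n=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bands = vpc(fit, data, nsim=250, seed=3)
        np.testing.assert_allclose(bands["sim_p5"], bands["sim_p95"], rtol=1e-9)
        np.testing.assert_allclose(bands["obs_p50"], bands["sim_p50"], rtol=1e-9)
        np.testing.assert_allclose(bands["obs_p5"], bands["sim_p5"], rtol=1e-9)

    def test_observed_median_inside_band_when_calibrated(self):
        fit = _point_fit(cov_scale=0.25, gamma=1.0)
        rng = np.random.default_rng(12)
        base = _noiseless_subjects(fit, n=30)
        from pippk import assay_sd

        data = []
        for s in base:
            noisy = s.concentrations + rng.normal(
                0.0, assay_sd(s.concentrations, fit.error)
            )
            data.append(
                SubjectDataset(s.subject_id, s.schedule, s.times,
                               np.clip(noisy, 0.0, None), s.below_lloq,
                               crcl_mL_min=s.crcl_mL_min)
            )
        bands = vpc(fit, data, nsim=400, seed=13)
        inside = (
            (bands["obs_p50"] >= bands["sim_p5"])
            & (bands["obs_p50"] <= bands["sim_p95"])
        )
        assert inside.mean() >= 0.8
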