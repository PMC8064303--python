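"""Nonparametric estimation: error model, likelihoods, EM weights, NPAG."""

import warnings

import numpy as np
import pytest
from scipy import stats

from pippk import (
    AssayErrorModel,
    CohortConfig,
    FitResult,
    InfusionEvent,
    InfusionSchedule,
    NonparametricDistribution,
    NpagConfig,
    ParameterBounds,
    PKParameters,
    SubjectDataset,
    SupportPoint,
    assay_sd,
    generate_cohort,
    npag_fit,
    posterior_estimates,
    simulate_dataset,
    solve_weights,
    subject_loglik,
)


class TestAssayErrorModel:
    @pytest.mark.parametrize(
        "conc,gamma,expected",
        [
            (0.0, 1.0, 0.4388),     # quality-control polynomial at zero
            (100.0, 1.0, 3.1388),
            (100.0, 2.0, 6.2776),   # gamma scales linearly
        ],
    )
    def test_sd_polynomial(self, conc, gamma, expected):
        err = AssayErrorModel(gamma=gamma)
        assert assay_sd(conc, err) == pytest.approx(expected, abs=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            assay_sd(-1.0, AssayErrorModel())


def _one_obs_subject(conc_values, times=None, crcl=100.0):
    times = times if times is not None else [1.0] * len(conc_values)
    sched = InfusionSchedule((InfusionEvent(0.0, 4.0, 4000.0),), horizon=48.0)
    return SubjectDataset(
        subject_id="T1",
        schedule=sched,
        times=np.asarray(times, dtype=float),
        concentrations=np.asarray(conc_values, dtype=float),
        below_lloq=np.zeros(len(conc_values), dtype=bool),
        crcl_mL_min=crcl,
    )


class TestSubjectLoglik:
    def test_matches_direct_density_product(self):
        subj = _one_obs_subject([30.0, 60.0, 40.0, 20.0],
                                times=[1.0, 4.0, 6.0, 8.0])
        params = PKParameters(2.0, 1.0, 25.0)
        err = AssayErrorModel(gamma=1.3)
        from pippk import concentration_at

        direct = 0.0
        for t, o in zip(subj.times, subj.concentrations):
            pred = concentration_at(subj.schedule, params, subj.crcl_L_per_h, t)
            sd = assay_sd(pred, err)
            direct += stats.norm.logpdf(o, loc=pred, scale=sd)
        assert subject_loglik(subj, params, err) == pytest.approx(direct, rel=1e-12)

    def test_monotone_in_residual(self):
        params = PKParameters(2.0, 1.0, 25.0)
        err = AssayErrorModel()
        from pippk import concentration_at

        pred = concentration_at(
            _one_obs_subject([1.0]).schedule, params, 6.0, 1.0
        )
        ll_exact = subject_loglik(_one_obs_subject([pred]), params, err)
        ll_off = subject_loglik(_one_obs_subject([pred + 5.0]), params, err)
        ll_far = subject_loglik(_one_obs_subject([pred + 10.0]), params, err)
        assert ll_exact > ll_off > ll_far

    def test_lloq_exclusion(self):
        subj = SubjectDataset(
            subject_id="T2",
            schedule=InfusionSchedule((InfusionEvent(0.0, 4.0, 4000.0),), 48.0),
            times=np.array([1.0, 8.0]),
            concentrations=np.array([30.0, 0.5]),
            below_lloq=np.array([False, True]),
            crcl_mL_min=100.0,
        )
        t, c = subj.usable("exclude")
        assert len(t) == 1 and c[0] == 30.0
        t2, c2 = subj.usable("half")
        assert len(t2) == 2 and c2[1] == 0.5  # substitution: LLOQ/2


class TestSolveWeights:
    def test_dominant_column_gets_all_mass(self):
        L = np.array([[1.0, 10.0], [0.5, 8.0], [0.2, 4.0]])
        w, _ = solve_weights(L)
        assert w[1] == pytest.approx(1.0, abs=1e-6)

    def test_identical_columns_split_equally(self):
        L = np.array([[2.0, 2.0, 0.1], [1.5, 1.5, 0.2], [3.0, 3.0, 0.1]])
        w, _ = solve_weights(L)
        assert w[0] == pytest.approx(w[1], abs=1e-9)

    def test_matches_simplex_grid_search(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            L = rng.uniform(0.05, 3.0, size=(5, 3))
            _, obj = solve_weights(L)
            step = 1e-3
            g = np.arange(0.0, 1.0 + step / 2, step)
            g1, g2 = np.meshgrid(g, g, indexing="ij")
            mask = g1 + g2 <= 1.0 + 1e-12
            W = np.stack([g1[mask], g2[mask], 1.0 - g1[mask] - g2[mask]], axis=1)
            grid_best = np.log(W @ L.T).sum(axis=1).max()
            assert obj >= grid_best - 1e-6

    def test_all_zero_row_rejected(self):
        L = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            solve_weights(L)


@pytest.fixture(scope="module")
def small_cohort_fit():
    """27-subject synthetic cohort and its NPAG fit (shared, module scope)."""
    cfg = CohortConfig(n_subjects=27, seed=11)
    cohort = generate_cohort(cfg)
    data = simulate_dataset(cohort, seed=12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = npag_fit(data, config=NpagConfig(n_grid=512, max_cycles=60,
                                               sweep_tol=0.05, seed=1))
    return cohort, data, fit


class TestNpagFit:
    def test_degenerate_single_point_recovery(self):
        truth = PKParameters(4.0, 1.35, 30.0)
        sched = InfusionSchedule(
            tuple(InfusionEvent(t, 4.0, 4000.0) for t in (0, 8, 16, 24, 32, 40)),
            horizon=48.0,
        )
        from pippk import concentration_at

        data = []
        for i, crcl in enumerate([40.0, 80.0, 120.0, 160.0, 60.0, 100.0]):
            times = np.array([41.0, 44.0, 46.0, 48.0])
            conc = np.array(
                [concentration_at(sched, truth, crcl * 0.06, t) for t in times]
            )
            data.append(
                SubjectDataset(f"S{i}", sched, times, conc,
                               np.zeros(4, dtype=bool), crcl_mL_min=crcl)
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            # gamma fixed: estimating process noise from noiseless data is
            # degenerate (it collapses to the bound and needles the surface)
            fit = npag_fit(
                data,
                bounds=ParameterBounds((1.0, 8.0), (0.5, 2.5), (15.0, 60.0)),
                config=NpagConfig(n_grid=256, max_cycles=60, seed=2,
                                  estimate_gamma=False),
            )
        pm = fit.distribution.param_matrix
        w = fit.distribution.weights
        near = (
            (np.abs(pm[:, 0] - truth.intercept) <= 0.01 * truth.intercept + 1e-9)
            & (np.abs(pm[:, 1] - truth.slope) <= 0.01 * truth.slope + 1e-9)
            & (np.abs(pm[:, 2] - truth.vc) <= 0.01 * truth.vc + 1e-9)
        )
        assert w[near].sum() >= 0.99

    def test_loglik_trace_monotone(self, small_cohort_fit):
        _, _, fit = small_cohort_fit
        trace = np.asarray(fit.ll_trace)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_weights_on_simplex(self, small_cohort_fit):
        _, _, fit = small_cohort_fit
        w = fit.distribution.weights
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_population_mean_recovery(self, small_cohort_fit):
        cohort, _, fit = small_cohort_fit
        med_crcl = np.median(cohort.crcl_mL_min) * 0.06
        pm = fit.distribution.param_matrix
        w = fit.distribution.weights
        cl_fit = float((pm[:, 0] + pm[:, 1] * med_crcl) @ w)
        cl_true = float(
            (cohort.true_params.intercept
             + cohort.true_params.slope * med_crcl).mean()
        )
        assert cl_fit == pytest.approx(cl_true, rel=0.2)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            npag_fit([_one_obs_subject([30.0])])


class TestPosteriorEstimates:
    def _two_point_fit(self):
        pts = (
            SupportPoint(PKParameters(2.0, 1.0, 20.0), 0.5),
            SupportPoint(PKParameters(8.0, 1.0, 60.0), 0.5),
        )
        dist = NonparametricDistribution(points=pts, covariance=np.zeros((3, 3)))
        return FitResult(
            distribution=dist, error=AssayErrorModel(),
            log_likelihood=0.0, cycles=1, converged=True,
        )

    def test_single_point_prior_returned_verbatim(self):
        dist = NonparametricDistribution(
            points=(SupportPoint(PKParameters(4.0, 1.3, 30.0), 1.0),),
            covariance=np.zeros((3, 3)),
        )
        fit = FitResult(distribution=dist, error=AssayErrorModel(),
                        log_likelihood=0.0, cycles=1, converged=True)
        post = posterior_estimates(fit, _one_obs_subject([50.0]))
        assert (post.intercept, post.slope, post.vc) == (4.0, 1.3, 30.0)

    def test_two_point_bayes(self):
        fit = self._two_point_fit()
        from pippk import concentration_at

        subj_template = _one_obs_subject([1.0], times=[4.0], crcl=100.0)
        pred_low = concentration_at(
            subj_template.schedule, PKParameters(2.0, 1.0, 20.0), 6.0, 4.0
        )
        subj = _one_obs_subject([pred_low], times=[4.0], crcl=100.0)
        post = posterior_estimates(fit, subj)
        assert post.intercept == pytest.approx(2.0, rel=0.01)
        assert post.vc == pytest.approx(20.0, rel=0.01)

    def test_no_observations_gives_prior_mean(self):
        fit = self._two_point_fit()
        subj = SubjectDataset(
            "E", InfusionSchedule((InfusionEvent(0, 4, 4000),), 48.0),
            np.array([]), np.array([]), np.array([], dtype=bool),
            crcl_mL_min=100.0,
        )
        post = posterior_estimates(fit, subj)
        assert post.intercept == pytest.approx(5.0)
        assert post.vc == pytest.approx(40.0)
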