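"""Laplace likelihood, model selection rules, covariate screen, diagnostics."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from pulsepd.population_fit import (
    EstimationSpec,
    ModelDataset,
    bic,
    build_dataset,
    circadian_term,
    compare_models,
    fit,
    neg2ll,
    screen_covariates,
)
from pulsepd.pulse_model import PopulationModel, PulseShape, predict_concentration


def make_pop(**overrides):
    base = dict(theta_amplitude=7.86, theta_kout=2.78, theta_secretion_sd=0.182,
                theta_baseline=0.185, theta_a0=1.05, omega2={},
                omega2_bov_amplitude=0.0, sigma2_prop=0.04)
    base.update(overrides)
    return PopulationModel(**base)


def simulate_subject(pop, eta_baseline, pt, grid, rng, sigma=0.2):
    f = predict_concentration(grid, pop.theta_baseline * math.exp(eta_baseline),
                              pop.theta_kout, pop.theta_a0, pt,
                              [pop.theta_amplitude] * len(pt),
                              pop.theta_secretion_sd)
    return np.maximum(f * (1 + rng.normal(0, sigma, f.size)), 1e-6)


@pytest.fixture()
def one_subject_dataset(rng):
    grid = np.linspace(0, 24, 49)
    pt = np.array([4.0, 12.0, 18.0])
    pop = make_pop(omega2={"baseline": 0.4})
    y = simulate_subject(pop, 0.3, pt, grid, rng)
    obs = pd.DataFrame({"ID": "s1", "TIME": grid, "DV": y})
    data = ModelDataset(observations=obs, pulse_times={"s1": pt},
                        covariates={"s1": {"tbw_pct": 44.7}})
    return pop, data, grid, pt


class TestNeg2ll:
    def test_laplace_close_to_exact_marginal(self, one_subject_dataset):
        pop, data, grid, pt = one_subject_dataset
        spec = EstimationSpec(iiv=("baseline",), bov_on_amplitude=False)
        ofv = neg2ll(pop, spec, data)[0]

        y = data.observations["DV"].to_numpy()

        def loglik(eta):
            f = predict_concentration(grid, 0.185 * math.exp(eta), 2.78, 1.05,
                                      pt, [7.86] * 3, 0.182)
            v = 0.04 * f * f
            ll = -0.5 * np.sum(np.log(v) + (y - f) ** 2 / v)
            return ll - 0.5 * (eta**2 / 0.4 + math.log(2 * math.pi * 0.4))

        m = minimize_scalar(lambda e: -loglik(e), bounds=(-3, 3),
                            method="bounded")
        lmax = -m.fun
        val = quad(lambda e: math.exp(loglik(e) - lmax), -3, 3, limit=200)[0]
        exact = -2.0 * (math.log(val) + lmax)
        assert ofv == pytest.approx(exact, abs=0.5)

    def test_additive_over_independent_subjects(self, one_subject_dataset):
        pop, data, grid, pt = one_subject_dataset
        spec = EstimationSpec(iiv=("baseline",), bov_on_amplitude=False)
        single = neg2ll(pop, spec, data)[0]
        obs2 = pd.concat([data.observations,
                          data.observations.assign(ID="s2")])
        data2 = ModelDataset(observations=obs2,
                             pulse_times={"s1": pt, "s2": pt})
        assert neg2ll(pop, spec, data2)[0] == pytest.approx(2 * single,
                                                            rel=1e-12)

    def test_degenerate_no_random_effects_is_wls_deviance(self,
                                                          one_subject_dataset):
        pop, data, grid, pt = one_subject_dataset
        pop0 = dataclasses.replace(pop, omega2={})
        spec = EstimationSpec(iiv=(), bov_on_amplitude=False)
        ofv = neg2ll(pop0, spec, data)[0]
        y = data.observations["DV"].to_numpy()
        f = predict_concentration(grid, 0.185, 2.78, 1.05, pt, [7.86] * 3,
                                  0.182)
        v = 0.04 * f * f
        expected = np.sum(np.log(v) + (y - f) ** 2 / v)
        assert ofv == pytest.approx(expected, rel=1e-12)

    def test_likelihood_prefers_truth_over_perturbation(self, rng):
        grid = np.linspace(0, 24, 73)
        pt = np.array([3.0, 8.0, 14.0, 20.0])
        pop = make_pop(omega2={"baseline": 0.2, "kout": 0.05},
                       sigma2_prop=0.02)
        rows = []
        pulse_times = {}
        for i in range(8):
            eta_b = rng.normal(0, math.sqrt(0.2))
            eta_k = rng.normal(0, math.sqrt(0.05))
            f = predict_concentration(
                grid, 0.185 * math.exp(eta_b), 2.78 * math.exp(eta_k), 1.05,
                pt, [7.86] * 4, 0.182)
            y = np.maximum(f * (1 + rng.normal(0, math.sqrt(0.02), f.size)),
                           1e-6)
            sid = f"s{i}"
            rows.append(pd.DataFrame({"ID": sid, "TIME": grid, "DV": y}))
            pulse_times[sid] = pt
        data = ModelDataset(observations=pd.concat(rows),
                            pulse_times=pulse_times)
        spec = EstimationSpec(iiv=("baseline", "kout"), bov_on_amplitude=False)
        ofv_true = neg2ll(pop, spec, data)[0]
        pert = dataclasses.replace(pop, theta_amplitude=2 * 7.86,
                                   theta_baseline=2 * 0.185)
        ofv_pert = neg2ll(pert, spec, data)[0]
        assert ofv_true < ofv_pert


class TestFit:
    def test_theta_recovery_within_three_se(self, rng):
        grid = np.linspace(0, 24, 145)
        pt = np.arange(1.57, 23.9, 1.57)
        truth = make_pop(omega2={"baseline": 0.2, "amplitude": 0.1},
                         omega2_bov_amplitude=0.3, sigma2_prop=0.0225)
        rows = []
        pulse_times = {}
        for i in range(6):
            eta_b = rng.normal(0, math.sqrt(0.2))
            eta_a = rng.normal(0, math.sqrt(0.1))
            kap = rng.normal(0, math.sqrt(0.3), pt.size)
            amps = 7.86 * np.exp(eta_a + kap)
            f = predict_concentration(grid, 0.185 * math.exp(eta_b), 2.78,
                                      1.05, pt, amps, 0.182)
            y = np.maximum(f * (1 + rng.normal(0, 0.15, f.size)), 1e-6)
            sid = f"s{i}"
            rows.append(pd.DataFrame({"ID": sid, "TIME": grid, "DV": y}))
            pulse_times[sid] = pt
        data = ModelDataset(observations=pd.concat(rows),
                            pulse_times=pulse_times)
        spec = EstimationSpec(
            free_fixed=("theta_amplitude", "theta_baseline", "theta_kout"),
            free_variances=("sigma2",),
            iiv=("baseline", "amplitude"))
        start = dataclasses.replace(truth, theta_amplitude=5.0,
                                    theta_baseline=0.3, theta_kout=2.0,
                                    sigma2_prop=0.05)
        res = fit(data, spec, start, compute_se=True)
        for name, true_val in [("theta_amplitude", 7.86),
                               ("theta_baseline", 0.185),
                               ("theta_kout", 2.78)]:
            est = res.all_estimates()[name]
            se = res.se.get(name)
            assert se is not None and se > 0
            assert abs(est - true_val) < 3 * se, (name, est, se)
        assert res.condition_number is None or res.condition_number >= 1.0

    def test_refit_from_optimum_is_stable(self, one_subject_dataset):
        pop, data, grid, pt = one_subject_dataset
        spec = EstimationSpec(free_fixed=("theta_baseline",),
                              free_variances=(), iiv=("baseline",),
                              bov_on_amplitude=False)
        first = fit(data, spec, pop, compute_se=False)
        second = fit(data, spec, first.pop, compute_se=False)
        assert abs(second.ofv - first.ofv) < 0.05

    def test_all_fixed_spec_is_evaluation_only(self, one_subject_dataset):
        pop, data, grid, pt = one_subject_dataset
        spec = EstimationSpec(iiv=("baseline",), bov_on_amplitude=False)
        res = fit(data, spec, pop, compute_se=True)
        assert res.n_params == 0
        assert res.se == {}
        assert res.ofv == pytest.approx(neg2ll(pop, spec, data)[0], abs=1e-6)

    def test_shrinkage_extremes(self, rng):
        # eta estimates collapse toward zero when per-subject data carry no
        # information about the random effect, and spread fully when the
        # data are dense and informative
        pt = np.array([4.0])
        pop = make_pop(omega2={"baseline": 1.0}, sigma2_prop=0.01)
        spec = EstimationSpec(iiv=("baseline",), bov_on_amplitude=False)

        def build(grid):
            rows = []
            pulse_times = {}
            for i in range(12):
                eta = rng.normal(0, 1.0)
                f = predict_concentration(grid, 0.185 * math.exp(eta), 2.78,
                                          0.185, pt, [7.86], 0.182)
                y = np.maximum(f * (1 + rng.normal(0, 0.1, f.size)), 1e-6)
                sid = f"s{i}"
                rows.append(pd.DataFrame({"ID": sid, "TIME": grid, "DV": y}))
                pulse_times[sid] = pt
            data = ModelDataset(observations=pd.concat(rows),
                                pulse_times=pulse_times)
            return fit(data, spec, pop, compute_se=False)

        # two samples right at the start, where the initial concentration
        # dominates and the baseline eta is barely expressed
        sparse = build(np.array([0.0, 0.02]))
        dense = build(np.linspace(8.0, 24.0, 100))
        # with 12 subjects the EBE spread itself is noisy, hence wide bands
        assert sparse.shrinkage_pct["omega2_baseline"] > 60.0
        assert dense.shrinkage_pct["omega2_baseline"] < 40.0


class TestModelSelection:
    def _fit_like(self, ofv, k, n):
        from pulsepd.population_fit import FitResult
        return FitResult(pop=make_pop(), drug=None, ofv=ofv, n_obs=n,
                         free_names=tuple(f"p{i}" for i in range(k)))

    def test_forward_boundary(self):
        small = self._fit_like(100.0, 1, 500)
        assert compare_models(small, self._fit_like(96.15, 2, 500), 1).forward_accept
        assert not compare_models(small, self._fit_like(96.16, 2, 500),
                                  1).forward_accept

    def test_backward_boundary(self):
        small = self._fit_like(100.0, 1, 500)
        # removal raising the OFV by only 6.5 points -> covariate excluded
        assert not compare_models(small, self._fit_like(93.5, 2, 500),
                                  1).backward_retain
        assert compare_models(small, self._fit_like(93.3, 2, 500),
                              1).backward_retain

    def test_extra_df_must_be_positive(self):
        with pytest.raises(ValueError):
            compare_models(self._fit_like(1, 1, 10), self._fit_like(0, 2, 10), 0)

    def test_bic_reduces_to_ofv_without_parameters(self):
        assert bic(self._fit_like(42.0, 0, 100)) == 42.0

    def test_bic_penalty_is_log_n_per_parameter(self):
        n = 100
        b1 = bic(self._fit_like(42.0, 1, n))
        b2 = bic(self._fit_like(42.0, 2, n))
        assert b2 - b1 == pytest.approx(math.log(n))

    def test_gaussian_shape_preferred_on_gaussian_data(self, rng):
        grid = np.linspace(0, 24, 97)
        pt = np.array([4.0, 10.0, 16.0, 21.0])
        truth = make_pop(omega2={"baseline": 0.1}, sigma2_prop=0.01)
        rows = []
        pulse_times = {}
        for i in range(3):
            eta = rng.normal(0, math.sqrt(0.1))
            f = predict_concentration(grid, 0.185 * math.exp(eta), 2.78, 1.05,
                                      pt, [7.86] * 4, 0.182)
            y = np.maximum(f * (1 + rng.normal(0, 0.1, f.size)), 1e-6)
            sid = f"s{i}"
            rows.append(pd.DataFrame({"ID": sid, "TIME": grid, "DV": y}))
            pulse_times[sid] = pt
        data = ModelDataset(observations=pd.concat(rows),
                            pulse_times=pulse_times)
        results = {}
        for label, shape in [("gaussian", PulseShape("gaussian")),
                             ("rational", PulseShape("rational", 2))]:
            spec = EstimationSpec(free_fixed=("theta_amplitude",
                                              "theta_secretion_sd"),
                                  free_variances=("sigma2",),
                                  iiv=("baseline",), bov_on_amplitude=False,
                                  shape=shape)
            res = fit(data, spec, truth, compute_se=False)
            results[label] = bic(res, data)
        assert results["gaussian"] < results["rational"]


class TestCovariateScreen:
    def _fit_with_ebes(self, ebes):
        from pulsepd.population_fit import FitResult
        return FitResult(pop=make_pop(omega2={"baseline": 0.2}), drug=None,
                         ofv=0.0, n_obs=10, free_names=(), ebes=ebes)

    def test_exact_copy_is_candidate(self, rng):
        eta = rng.normal(0, 1, 10)
        ebes = {f"s{i}": {"baseline": eta[i], "kappas": np.empty(0)}
                for i in range(10)}
        table = pd.DataFrame({"tbw_pct": eta}, index=[f"s{i}" for i in range(10)])
        out = screen_covariates(self._fit_with_ebes(ebes), table)
        assert len(out.candidates) == 1
        assert out.candidates.iloc[0]["r"] == pytest.approx(1.0)

    def test_negative_correlation_counts(self, rng):
        eta = rng.normal(0, 1, 12)
        ebes = {f"s{i}": {"baseline": eta[i], "kappas": np.empty(0)}
                for i in range(12)}
        table = pd.DataFrame({"w": -eta + rng.normal(0, 0.3, 12)},
                             index=[f"s{i}" for i in range(12)])
        out = screen_covariates(self._fit_with_ebes(ebes), table)
        assert len(out.candidates) == 1
        assert out.candidates.iloc[0]["r"] < -0.5

    def test_independent_noise_rarely_selected(self, rng):
        hits = 0
        for _ in range(40):
            eta = rng.normal(0, 1, 46)
            ebes = {f"s{i}": {"baseline": eta[i], "kappas": np.empty(0)}
                    for i in range(46)}
            table = pd.DataFrame({"x": rng.normal(0, 1, 46)},
                                 index=[f"s{i}" for i in range(46)])
            out = screen_covariates(self._fit_with_ebes(ebes), table)
            hits += len(out.candidates)
        assert hits <= 2  # |r| >= 0.5 with n = 46 under the null is rare

    def test_constant_covariate_skipped(self, rng):
        eta = rng.normal(0, 1, 8)
        ebes = {f"s{i}": {"baseline": eta[i], "kappas": np.empty(0)}
                for i in range(8)}
        table = pd.DataFrame({"c": np.ones(8)}, index=[f"s{i}" for i in range(8)])
        out = screen_covariates(self._fit_with_ebes(ebes), table)
        assert len(out.candidates) == 0
        assert any("constant" in n for n in out.notices)


class TestCircadian:
    def test_zero_magnitude_is_identity(self):
        t = np.linspace(0, 48, 33)
        np.testing.assert_allclose(circadian_term(t, 3.0, 0.0), 1.0)

    def test_cosine_peaks_at_acrophase(self):
        assert circadian_term(3.0, 3.0, 0.4) == pytest.approx(1.4)

    def test_cosine_mean_is_one(self):
        t = np.linspace(0, 24, 241)[:-1]
        assert np.mean(circadian_term(t, 7.0, 0.3)) == pytest.approx(1.0,
                                                                     abs=1e-12)

    def test_day_night_window_wraps_midnight(self):
        f = circadian_term(np.array([23.5, 3.0, 12.0]), 0.0, 0.5,
                           mode="day_night")
        np.testing.assert_allclose(f, [1.5, 1.5, 1.0])


class TestBuildDataset:
    def test_unique_ids_for_stratified_occasions(self):
        from pulsepd.deconvolution import (DeconvolutionResult, FitStatistics,
                                           ObservationSeries)
        from pulsepd.pulse_model import PulseEvent

        def series(sub, occ):
            grid = np.arange(0, 4.001, 1 / 6)
            vals = np.full(grid.size, 1.0)
            return ObservationSeries(sub, occ, grid, vals,
                                     np.full(grid.size, 0.05),
                                     np.full(grid.size, 2), 0.03,
                                     np.ones(grid.size, bool))

        def result(sub, occ):
            return DeconvolutionResult(
                pulses=[PulseEvent(2.0, 1.0, 0.4)], basal_secretion=0.5,
                half_life=0.25, c0=1.0,
                fit_statistics=FitStatistics(0, True, 25, 5),
                subject_id=sub, occasion=occ)

        # 24 subjects x 2 occasions with 2 dropouts -> 46 model subjects
        profiles, decon = [], []
        for i in range(24):
            for occ in ("before", "after"):
                if occ == "after" and i in (3, 17):
                    continue
                profiles.append(series(f"sub{i}", occ))
                decon.append(result(f"sub{i}", occ))
        data = build_dataset(profiles, decon)
        assert len(set(data.observations["ID"])) == 46
        assert all(len(v) == 1 for v in data.pulse_times.values())

    def test_missing_deconvolution_result_raises(self):
        from pulsepd.deconvolution import ObservationSeries
        grid = np.arange(0, 4.001, 1 / 6)
        s = ObservationSeries("a", "1", grid, np.ones(grid.size),
                              np.full(grid.size, 0.05),
                              np.full(grid.size, 2), 0.03,
                              np.ones(grid.size, bool))
        with pytest.raises(ValueError, match="deconvolution"):
            build_dataset([s], {})

    def test_empty_profile_set_gives_empty_dataset(self):
        data = build_dataset([], {})
        assert data.n_obs == 0
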