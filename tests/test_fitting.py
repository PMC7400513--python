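"""Flux fitting: objective arithmetic, recovery, chi-squared verdicts,
profile-likelihood CIs, significance calls, stationarity."""

import numpy as np
import pytest
from scipy import stats

import fluxtrace as ft
from fluxtrace.errors import DegenerateFitError
from fluxtrace.fitting import ConfidenceInterval, FitResult, MeasurementSet
from fluxtrace.network import FluxVector

from conftest import build_model


# ---------------------------------------------------------------------------
# a linear-Gaussian toy: quadratic RSS in one free flux, no MIDs

def _toy_problem(m1=6.0, m2=6.2, rel=0.05):
    model = build_model(
        [("src_e", 1, False), ("A", 1, True), ("B", 1, True), ("C", 1, True),
         ("s1_e", 1, False), ("s2_e", 1, False)],
        [("U", "src_e (A) --> A (A)", 0),
         ("R1", "A (A) --> B (A)", 0),
         ("R2", "A (A) --> C (A)", 0),
         ("XB", "B (A) --> s1_e (A)", 0),
         ("XC", "C (A) --> s2_e (A)", 0)],
    )
    ms = MeasurementSet(
        mids=[], fragments={}, tracers={},
        soft_fluxes={"R1": (m1, rel), "XB": (m2, rel)},
        hard_fluxes={"U": 10.0},
    )
    return ft.FluxFitProblem(model, ms, ft.FitOptions(n_multistarts=3, seed=0))


class TestResidualArithmetic:
    def test_noise_free_truth_has_zero_rss(self, truth_theta):
        problem, theta = truth_theta
        assert problem.rss(theta) < 1e-18

    def test_single_mid_element_off_by_one_sd_contributes_one(self, truth_theta, scenario):
        ms = ft.simulate_mid_measurements(scenario, "parental", seed=0, noise_sd=0.0)
        ms.mids[0].mean[2] += 0.01  # one mass off by exactly the 0.01 SD
        problem = ft.FluxFitProblem(scenario.model, ms)
        theta = truth_theta[1]
        assert problem.rss(theta) == pytest.approx(1.0, abs=1e-7)

    def test_soft_flux_off_by_five_percent_contributes_one(self, truth_theta, scenario):
        ms = ft.simulate_mid_measurements(scenario, "parental", seed=0, noise_sd=0.0)
        true_glut = scenario.conditions["parental"].flux.net["GLUT"]
        ms.soft_fluxes["GLUT"] = (true_glut / 1.05, 0.05)
        problem = ft.FluxFitProblem(scenario.model, ms)
        assert problem.rss(truth_theta[1]) == pytest.approx(1.0, abs=1e-7)

    def test_removing_a_measurement_lowers_rss_by_its_term(self, scenario, truth_theta):
        ms = ft.simulate_mid_measurements(scenario, "parental", seed=21)
        theta = truth_theta[1]
        full = ft.FluxFitProblem(scenario.model, ms)
        r_full = full.residuals(theta)
        dropped = ms.mids[3]
        n_before = sum(len(m.mean) for m in ms.mids[:3])
        term = float(np.sum(r_full[n_before:n_before + len(dropped.mean)] ** 2))
        ms2 = MeasurementSet(
            mids=[m for m in ms.mids if m is not dropped],
            soft_fluxes=ms.soft_fluxes, hard_fluxes=ms.hard_fluxes,
            fragments=ms.fragments, tracers=ms.tracers,
        )
        part = ft.FluxFitProblem(scenario.model, ms2)
        assert full.rss(theta) - part.rss(theta) == pytest.approx(term, rel=1e-9)


class TestFitFluxes:
    def test_noise_free_recovery(self, scenario):
        ms = ft.simulate_mid_measurements(scenario, "parental", seed=0, noise_sd=0.0)
        fit = ft.fit_fluxes(scenario.model, ms, ft.FitOptions(n_multistarts=2, seed=0))
        assert fit.rss < 1e-6
        truth = scenario.conditions["parental"].flux
        # the pyruvate-cycling loop (PC/ME/MDH/malate transport) is nearly
        # flat in the objective; it is checked on an absolute scale instead
        loop = {"MPC2", "PC", "ME1", "ME2", "MDH", "MDHC", "MALT"}
        for rid in scenario.model.reaction_ids:
            err = abs(fit.flux.net[rid] - truth.net[rid])
            if rid in loop:
                assert err < 1.0, rid
            else:
                assert err <= 1e-3 * max(abs(truth.net[rid]), 1.0), rid

    def test_seeded_determinism(self, scenario):
        ms = ft.simulate_mid_measurements(scenario, "parental", seed=5)
        opts = ft.FitOptions(n_multistarts=2, seed=42)
        fit1 = ft.fit_fluxes(scenario.model, ms, opts)
        fit2 = ft.fit_fluxes(scenario.model, ms, opts)
        assert fit1.rss == fit2.rss
        assert np.array_equal(fit1.theta, fit2.theta)
        assert fit1.flux.net == fit2.flux.net


class TestGoodnessOfFit:
    @staticmethod
    def _result(rss, n_meas, n_par):
        return FitResult(flux=FluxVector(net={}), mixing_fractions={}, rss=rss,
                         n_measurements=n_meas, n_parameters=n_par,
                         theta=np.zeros(1), starts=[])

    def test_zero_rss_passes(self):
        gof = ft.goodness_of_fit(self._result(0.0, 30, 5))
        assert gof.passed

    def test_rss_just_above_tabulated_threshold_fails(self):
        gof = ft.goodness_of_fit(self._result(18.4, 21, 11))  # dof 10
        assert gof.threshold == pytest.approx(18.307, abs=5e-4)
        assert not gof.passed

    def test_overparameterized_model_rejected(self):
        with pytest.raises(DegenerateFitError):
            ft.goodness_of_fit(self._result(1.0, 5, 5))


class TestGridSearchCI:
    def test_linear_gaussian_toy_matches_analytic(self):
        problem = _toy_problem()
        fit = problem.fit()
        # analytic weighted-least-squares solution and standard error
        m = np.array([6.0, 6.2])
        sd = 0.05 * m
        w = 1 / sd**2
        best = float(np.sum(w * m) / np.sum(w))
        se = float(1 / np.sqrt(np.sum(w)))
        assert fit.flux.net["R1"] == pytest.approx(best, rel=1e-6)
        ci = ft.grid_search_ci(fit, "R1")
        assert ci.lower == pytest.approx(best - 1.959964 * se, rel=0.01)
        assert ci.upper == pytest.approx(best + 1.959964 * se, rel=0.01)

    def test_ci_nesting_90_in_95(self):
        problem = _toy_problem()
        fit = problem.fit()
        ci90 = ft.grid_search_ci(fit, "R1", level=0.90)
        ci95 = ft.grid_search_ci(fit, "R1", level=0.95)
        assert ci95.lower <= ci90.lower <= ci90.upper <= ci95.upper

    def test_hard_constrained_reaction_collapses(self):
        problem = _toy_problem()
        fit = problem.fit()
        ci = ft.grid_search_ci(fit, "U")
        assert ci.lower == ci.upper == 10.0


class TestCompareConditions:
    @staticmethod
    def _ci(lo, hi):
        best = (0.0 if lo is None else lo + (hi - lo if hi is not None else 0) / 2)
        if lo is not None and hi is not None:
            best = 0.5 * (lo + hi)
        elif lo is not None:
            best = lo
        elif hi is not None:
            best = hi
        return ConfidenceInterval("R", 0.95, lo, hi, best)

    def test_disjoint_intervals_significant(self):
        calls = ft.compare_conditions({"R": self._ci(1, 2)}, {"R": self._ci(3, 4)})
        assert calls["R"].significant is True
        assert calls["R"].direction == "increased"

    def test_overlapping_intervals_not_significant(self):
        calls = ft.compare_conditions({"R": self._ci(1, 3)}, {"R": self._ci(2, 4)})
        assert calls["R"].significant is False

    def test_touching_intervals_not_significant(self):
        calls = ft.compare_conditions({"R": self._ci(1, 2)}, {"R": self._ci(2, 3)})
        assert calls["R"].significant is False

    def test_nd_bound_blocks_decision(self):
        calls = ft.compare_conditions({"R": self._ci(1, None)}, {"R": self._ci(2, 4)})
        assert calls["R"].significant is None

    def test_nd_bound_away_from_decision_still_significant(self):
        calls = ft.compare_conditions({"R": self._ci(5, None)}, {"R": self._ci(1, 2)})
        assert calls["R"].significant is True
        assert calls["R"].direction == "decreased"


class TestStationarity:
    times = np.repeat([24.0, 29.0, 32.0], 3)

    def test_identical_mids_are_stationary(self):
        mids = np.tile([0.6, 0.3, 0.1], (9, 1))
        out = ft.assess_stationarity(self.times, {"f": mids})
        assert out["f"] is True

    def test_visible_drift_is_non_stationary(self):
        rng = np.random.default_rng(1)
        base = np.tile([0.6, 0.3, 0.1], (9, 1))
        base[:, 0] += 0.05 * (self.times - 24.0)
        base[:, 1] -= 0.05 * (self.times - 24.0)
        base += rng.normal(0, 0.01, base.shape)
        out = ft.assess_stationarity(self.times, {"f": base})
        assert out["f"] is False

    def test_drift_far_below_noise_is_stationary(self):
        rng = np.random.default_rng(2)
        base = np.tile([0.6, 0.3, 0.1], (9, 1))
        base[:, 0] += 1e-5 * (self.times - 24.0)
        base += rng.normal(0, 0.01, base.shape)
        out = ft.assess_stationarity(self.times, {"f": base})
        assert out["f"] is True

    def test_single_time_point_indeterminate(self):
        out = ft.assess_stationarity([24.0] * 3, {"f": np.tile([0.5, 0.5], (3, 1))})
        assert out["f"] is None
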