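"""Synthetic scenario: anchors, determinism, noise statistics, pipeline."""

import numpy as np
import pytest

import fluxtrace as ft
from fluxtrace import emu as emu_mod
from fluxtrace.emu import TracerSpec


class TestScenarioTruth:
    def test_truth_is_steady_state(self, scenario):
        for truth in scenario.conditions.values():
            assert ft.steady_state_residual(scenario.model, truth.flux) <= 1e-9

    def test_lactate_glucose_ratios_match_reported_table(self, scenario):
        p = scenario.conditions["parental"].flux
        f = scenario.conditions["fh_dim"].flux
        assert ft.flux_ratio(p.net["LDH"], p.net["GLUT"]) == 1.88
        assert ft.flux_ratio(f.net["LDH"], f.net["GLUT"]) == 1.89

    def test_fh_reverse_forward_ratio_lower_in_fh_dim(self, scenario):
        def ratio(flux):
            return flux.backward("FH") / flux.forward("FH")

        p = ratio(scenario.conditions["parental"].flux)
        f = ratio(scenario.conditions["fh_dim"].flux)
        assert f < p
        assert f < 0.25  # forward reaction dominates in the FH-attenuated line

    def test_tca_fluxes_reduced_in_fh_dim(self, scenario):
        p = scenario.conditions["parental"].flux.net
        f = scenario.conditions["fh_dim"].flux.net
        for rid in ("MPC1", "PDH", "CS", "IDH", "AKGDH", "SDH", "FH", "MDH"):
            assert f[rid] < p[rid]
        assert f["PROS"] < 0.25 * p["PROS"]  # proline synthesis near-collapse


class TestDeterminism:
    def test_measurements_identical_for_identical_seeds(self):
        a = ft.make_scenario(seed=5)
        b = ft.make_scenario(seed=5)
        ma = ft.simulate_mid_measurements(a, "parental", seed=7)
        mb = ft.simulate_mid_measurements(b, "parental", seed=7)
        for x, y in zip(ma.mids, mb.mids):
            assert x.fragment == y.fragment and x.experiment == y.experiment
            assert np.array_equal(x.mean, y.mean)
        assert ma.soft_fluxes == mb.soft_fluxes
        ta = ft.simulate_timecourses(a, "fh_dim", seed=9)
        tb = ft.simulate_timecourses(b, "fh_dim", seed=9)
        assert np.array_equal(ta["counts"].values, tb["counts"].values)
        for met in ta["amounts"]:
            assert np.array_equal(ta["amounts"][met].values, tb["amounts"][met].values)

    def test_different_seeds_differ(self, scenario):
        m1 = ft.simulate_mid_measurements(scenario, "parental", seed=1)
        m2 = ft.simulate_mid_measurements(scenario, "parental", seed=2)
        assert not np.array_equal(m1.mids[0].mean, m2.mids[0].mean)


class TestNoiseStatistics:
    def test_empirical_mid_noise_sd_matches_nominal(self, scenario):
        truth = scenario.true_raw_mids("parental")
        devs = []
        for s in range(300):
            ms = ft.simulate_mid_measurements(scenario, "parental", seed=40000 + s)
            for m in ms.mids:
                devs.append(m.mean - truth[m.experiment][m.fragment][: len(m.mean)])
        sd = float(np.std(np.concatenate(devs)))
        assert abs(sd - 0.01) <= 0.001  # within 10% of the nominal 0.01

    def test_concentration_noise_never_negative(self, scenario):
        tc = ft.simulate_timecourses(scenario, "parental", seed=3)
        for series in tc["amounts"].values():
            assert np.all(series.values >= 0.0)


class TestRoundTrips:
    def test_noise_free_timecourses_recover_all_rates(self, scenario):
        for cond, truth in scenario.conditions.items():
            tc = ft.simulate_timecourses(scenario, cond, noise=False)
            mu = ft.fit_growth_rate(tc["counts"]).rate
            assert mu == pytest.approx(truth.mu, rel=1e-9)
            k = ft.fit_degradation_rate(tc["cell_free_glutamine"]).rate
            assert k == pytest.approx(0.00345, rel=1e-9)
            for met, series in tc["amounts"].items():
                fit = ft.fit_exchange_rate(
                    series, mu=truth.mu, X0=truth.X0,
                    k=truth.degradation.get(met, 0.0), n_boot=0,
                )
                assert fit.q == pytest.approx(truth.q(met), rel=1e-6), met

    def test_noise_free_measurements_correct_back_to_backbone(self, scenario):
        ms = ft.simulate_mid_measurements(scenario, "parental", seed=0, noise_sd=0.0)
        backbone = scenario.true_backbone_mids("parental")
        table = ft.AbundanceTable.default()
        for m in ms.mids:
            f = scenario.fragments[m.fragment]
            corrected = ft.correct_mid(
                ft.MIDVector(m.fragment, m.mean, space="derivatized-raw"), f, table
            )
            np.testing.assert_allclose(
                corrected.masses, backbone[m.experiment][m.fragment], atol=1e-8
            )

    def test_unlabeled_control_corrects_to_pure_m0(self, monkeypatch):
        monkeypatch.setattr(emu_mod, "NAT_C13", 0.0)
        sc = ft.make_scenario(seed=0)
        sc.tracers = {"ctrl": [TracerSpec("glc_e", (), purity=0.5)]}
        ms = ft.simulate_mid_measurements(sc, "parental", seed=0, noise_sd=0.0)
        table = ft.AbundanceTable.default()
        for m in ms.mids:
            f = sc.fragments[m.fragment]
            corrected = ft.correct_mid(
                ft.MIDVector(m.fragment, m.mean, space="derivatized-raw"), f, table
            )
            assert corrected.masses[0] == pytest.approx(1.0, abs=1e-8)

    def test_stationarity_holds_on_noise_free_replicates(self):
        sc = ft.make_scenario(seed=0)
        sc.mid_sd = 0.0
        reps = ft.simulate_mid_replicates(sc, "parental", seed=0)
        for exp, (times, frags) in reps.items():
            verdicts = ft.assess_stationarity(times, frags)
            assert all(v is True for v in verdicts.values())

    def test_injected_drift_detected(self):
        sc = ft.make_scenario(seed=0)
        reps = ft.simulate_mid_replicates(sc, "parental", seed=1, drift=0.05)
        _, frags = reps["glc12"]
        verdicts = ft.assess_stationarity(*reps["glc12"])
        assert not any(verdicts.values())


class TestDatasetExport:
    def test_write_dataset_round_trip(self, tmp_path):
        sc = ft.make_scenario(seed=4)
        ft.write_dataset(sc, tmp_path, seed=4)
        model = ft.load_model(tmp_path / "model.tsv")
        assert model.reaction_ids == sc.model.reaction_ids
        assert (tmp_path / "mids_parental.tsv").exists()
        assert (tmp_path / "truth_fh_dim.json").exists()
        frags = ft.load_fragments(tmp_path / "fragments.tsv")
        assert {f.id for f in frags} == set(sc.fragments)


class TestEndToEnd:
    def test_pipeline_report(self):
        report = ft.end_to_end(seed=3, n_multistarts=2, ci_reactions=("MPC1", "G6PDH"))
        sc = ft.make_scenario(seed=3)
        for cond in ("parental", "fh_dim"):
            c = report["conditions"][cond]
            truth = sc.conditions[cond]
            assert c["gof"].passed
            assert c["mu"] == pytest.approx(truth.mu, rel=0.05)
            assert c["k_glutamine"] == pytest.approx(0.00345, rel=0.25)
            for rid, ci in c["cis"].items():
                lo = -np.inf if ci.lower is None else ci.lower
                hi = np.inf if ci.upper is None else ci.upper
                assert lo - 1e-6 <= truth.flux.net[rid] <= hi + 1e-6, rid
        assert "percent_change" in report["exchange_table"].columns
        rows = set(report["atp_table"]["pathway"])
        assert {"glycolysis", "tca_cycle", "total_net"} <= rows
        assert report["significance"]["MPC1"].significant is True
        assert report["significance"]["MPC1"].direction == "decreased"
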