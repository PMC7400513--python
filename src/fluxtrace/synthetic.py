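"""Paired synthetic datasets emulating the FH-attenuation study design.

No raw data accompany the study this package emulates, so every pipeline
stage is exercised against generated data with the statistical structure
the analysis assumes: exponential growth (mu 0.0343 / 0.0208 1/h for the
parental-like and FH-attenuated-like condition), first-order glutamine
degradation (k 0.00345 1/h), extracellular exchange fluxes anchored to
the reported uptake/secretion table, parallel [1,2-13C]glucose (99%
purity) and [U-13C]glutamine (98%) labelling with Gaussian MID noise of
SD 0.01, and 5% relative error on the glucose/lactate soft measurements.

The generator's defaults ARE the study conditions; they are not tuning
knobs. Noisy raw MIDs keep independent Gaussian errors (they are not
re-normalized), so the downstream chi-squared test is correctly
specified; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._data import data_path
from .correction import AbundanceTable, build_matrix
from .emu import EMUNetwork, TracerSpec, load_fragments
from .exoflux import TimeCourse, amount_model
from .fitting import MeasurementSet, MIDMeasurement
from .network import BIOMASS_ID, FluxVector, NetworkModel, expand, load_model, parameterize

#: metabolite -> (exchange reaction, sign of q: secretion +, uptake -)
EXCHANGE_MAP = {
    "glucose": ("GLUT", -1),
    "lactate": ("LDH", +1),
    "pyruvate": ("PYRX", +1),
    "glutamine": ("GLNUP", -1),
    "serine": ("SERUP", -1),
    "alanine": ("ALAX", +1),
    "proline": ("PROX", +1),
}

_PARENTAL_FIXED = {
    "GLUT": 578.8, "LDH": 1087.7, "PYRX": 61.7, "GLNUP": 82.7,
    "SERUP": 22.0, "ALAX": 17.1, "PROX": 13.9, BIOMASS_ID: 0.0343,
    "G6PDH": 60.0, "PC": 25.0, "ME2": 20.0,
}
_FHDIM_FIXED = {
    "GLUT": 533.5, "LDH": 1009.8, "PYRX": 57.8, "GLNUP": 52.7,
    "SERUP": 16.2, "ALAX": 19.4, "PROX": 1.5, BIOMASS_ID: 0.0208,
    "G6PDH": 55.0, "PC": 10.0, "ME2": 10.0,
}
_PARENTAL_EXCHANGE = {"FH": 600.0, "MDH": 150.0, "GDH": 30.0, "SDH": 50.0}
_FHDIM_EXCHANGE = {"FH": 10.0, "MDH": 100.0, "GDH": 20.0, "SDH": 30.0}

#: Initial medium amounts, nmol in a 4 mL dish (20 mM glucose, 2 mM
#: glutamine per the culture recipe; serine from dialysed serum).
_A0 = {"glucose": 80000.0, "glutamine": 8000.0, "serine": 1600.0,
       "lactate": 0.0, "pyruvate": 0.0, "alanine": 0.0, "proline": 0.0}


@dataclass
class ConditionTruth:
    name: str
    flux: FluxVector
    mixing: dict
    mu: float
    X0: float  # in units of 10^6 cells
    A0: dict
    degradation: dict  # metabolite -> k (1/h)

    def q(self, metabolite: str) -> float:
        rid, sign = EXCHANGE_MAP[metabolite]
        return sign * self.flux.net[rid]


@dataclass
class Scenario:
    """Ground truth plus sampling design for a paired labelling study."""

    name: str
    model: NetworkModel
    conditions: dict  # name -> ConditionTruth
    tracers: dict  # experiment -> [TracerSpec]
    fragments: dict  # id -> FragmentSpec
    seed: int = 0
    mid_sd: float = 0.01
    soft_rel_sd: float = 0.05
    conc_cv: float = 0.02
    count_cv: float = 0.02
    times: tuple = tuple(float(t) for t in range(0, 49, 8))
    quench_times: tuple = (24.0, 29.0, 32.0)
    n_replicates: int = 3
    _sim_cache: dict = field(default_factory=dict, repr=False)

    # -- cached noise-free simulation -------------------------------------

    def _simulator(self):
        if "emunet" not in self._sim_cache:
            frags = [self.fragments[f] for f in sorted(self.fragments)]
            emunet = EMUNetwork(self.model, frags)
            table = AbundanceTable.default()
            corr = {f.id: build_matrix(f, table).matrix for f in frags}
            self._sim_cache["emunet"] = (emunet, corr)
        return self._sim_cache["emunet"]

    def true_raw_mids(self, condition: str) -> dict:
        """Noise-free raw (derivatized-ion) MIDs, {experiment: {fragment: array}}."""
        key = ("raw", condition)
        if key not in self._sim_cache:
            emunet, corr = self._simulator()
            truth = self.conditions[condition]
            backbone = emunet.simulate(truth.flux, self.tracers, truth.mixing)
            raw = {}
            for exp, frag_mids in backbone.items():
                raw[exp] = {}
                for fid, mid in frag_mids.items():
                    y = corr[fid] @ mid
                    raw[exp][fid] = y / y.sum()
            self._sim_cache[key] = raw
        return self._sim_cache[key]

    def true_backbone_mids(self, condition: str) -> dict:
        emunet, _ = self._simulator()
        truth = self.conditions[condition]
        return emunet.simulate(truth.flux, self.tracers, truth.mixing)


def make_scenario(name: str = "hek293_fhdim", seed: int = 0,
                  model: NetworkModel | None = None) -> Scenario:
    """Build the paired parental-like / FH-attenuated-like scenario.

    Extracellular anchors follow the reported exchange-flux table; internal
    free fluxes (oxPPP, pyruvate carboxylase, mitochondrial malic enzyme)
    are set once to physiologically plausible values; the FH-attenuated
    condition carries a much lower FH exchange flux (reverse/forward ratio
    pattern) and near-zero proline output.
    """
    if model is None:
        model = load_model(data_path("reference_model.tsv"))
    conditions = {}
    for cond, fixed, exch, mu, x0 in (
        ("parental", _PARENTAL_FIXED, _PARENTAL_EXCHANGE, 0.0343, 0.35),
        ("fh_dim", _FHDIM_FIXED, _FHDIM_EXCHANGE, 0.0208, 0.5),
    ):
        param = parameterize(model, fixed=fixed)
        flux = expand(param, param.u0, model=model, exchange=dict(exch),
                      check_bounds=True)
        mixing = (
            {"pyr_mix": {"pyr_c": 0.8, "pyr_m2": 0.2},
             "mal_mix": {"mal_m": 0.75, "mal_c": 0.25}}
            if cond == "parental"
            else {"pyr_mix": {"pyr_c": 0.85, "pyr_m2": 0.15},
                  "mal_mix": {"mal_m": 0.8, "mal_c": 0.2}}
        )
        conditions[cond] = ConditionTruth(
            name=cond, flux=flux, mixing=mixing, mu=mu, X0=x0, A0=dict(_A0),
            degradation={"glutamine": 0.00345},
        )
    tracers = {
        "glc12": [TracerSpec("glc_e", (1, 2), purity=0.99)],
        "glnU": [TracerSpec("gln_e", (1, 2, 3, 4, 5), purity=0.98)],
    }
    fragments = {f.id: f for f in load_fragments(data_path("fragments.tsv"))}
    return Scenario(
        name=name, model=model, conditions=conditions, tracers=tracers,
        fragments=fragments, seed=seed,
    )


# ---------------------------------------------------------------------------
# time courses

def simulate_timecourses(scenario: Scenario, condition: str, seed: int | None = None,
                         noise: bool = True) -> dict:
    """Cell counts, metabolite amounts and a cell-free glutamine series.

    Returns {"counts": TimeCourse, "cell_free_glutamine": TimeCourse,
    "amounts": {metabolite: TimeCourse}}; replicates appear as repeated
    time points. Multiplicative Gaussian noise (CV 2%) is applied and
    negative draws are clipped to zero.
    """
    truth = scenario.conditions[condition]
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    t1 = np.asarray(scenario.times)
    reps = scenario.n_replicates if noise else 1
    t = np.repeat(t1, reps)

    def noisy(values, cv):
        if not noise:
            return values
        return np.clip(values * (1 + rng.normal(0.0, cv, len(values))), 0.0, None)

    counts = TimeCourse(
        id="counts", times=t, kind="cell_count",
        values=noisy(truth.X0 * np.exp(truth.mu * t), scenario.count_cv),
    )
    k_gln = truth.degradation.get("glutamine", 0.0)
    cell_free = TimeCourse(
        id="cell_free_glutamine", times=t, kind="cell_free_concentration",
        values=noisy(truth.A0["glutamine"] * np.exp(-k_gln * t), scenario.conc_cv),
    )
    amounts = {}
    for met in EXCHANGE_MAP:
        k = truth.degradation.get(met, 0.0)
        a = amount_model(t, truth.A0[met], truth.q(met), truth.mu, truth.X0, k)
        amounts[met] = TimeCourse(
            id=met, times=t, kind="concentration", values=noisy(a, scenario.conc_cv)
        )
    return {"counts": counts, "cell_free_glutamine": cell_free, "amounts": amounts}


# ---------------------------------------------------------------------------
# MID measurements

def simulate_mid_measurements(
    scenario: Scenario, condition: str, seed: int | None = None,
    noise_sd: float | None = None, constraint_overrides: dict | None = None,
) -> MeasurementSet:
    """One pooled measurement set (mean over quench times) per tracer.

    The stated SD (default 0.01) applies to the pooled measurement: noise
    is drawn once per mass at that SD, independent across masses, and the
    result is deliberately not re-normalized so the fit's error model is
    exact. Glucose/lactate enter as soft measurements with 5% relative
    noise; the remaining measured exchange fluxes and the growth rate are
    hard constraints at the generating truth unless ``constraint_overrides``
    supplies estimated values (as a real analysis would).
    """
    truth = scenario.conditions[condition]
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    sd = scenario.mid_sd if noise_sd is None else noise_sd
    raw = scenario.true_raw_mids(condition)
    mids = []
    for exp in sorted(raw):
        for fid in sorted(raw[exp]):
            y = raw[exp][fid].copy()
            if sd > 0:
                y = y + rng.normal(0.0, sd, len(y))
            mids.append(MIDMeasurement(fragment=fid, experiment=exp, mean=y,
                                       sd=scenario.mid_sd))
    soft = {}
    for rid in ("GLUT", "LDH"):
        value = truth.flux.net[rid]
        measured = value * (1 + rng.normal(0.0, scenario.soft_rel_sd)) if sd > 0 else value
        soft[rid] = (float(measured), scenario.soft_rel_sd)
    hard = {rid: truth.flux.net[rid]
            for rid in ("PYRX", "GLNUP", "SERUP", "ALAX", "PROX")}
    hard[BIOMASS_ID] = truth.mu
    for rid, value in (constraint_overrides or {}).items():
        if rid in soft:
            soft[rid] = (float(value), scenario.soft_rel_sd)
        else:
            hard[rid] = float(value)
    return MeasurementSet(
        mids=mids, soft_fluxes=soft, hard_fluxes=hard,
        fragments=dict(scenario.fragments), tracers=dict(scenario.tracers),
        quench_times=scenario.quench_times, space="derivatized-raw",
    )


def simulate_mid_replicates(scenario: Scenario, condition: str,
                            seed: int | None = None, drift: float = 0.0):
    """Per-quench-time replicate raw MIDs for stationarity assessment.

    Each of the three quench times carries replicate noise SD 0.01*sqrt(3)
    (so their mean matches the pooled SD of 0.01). ``drift`` adds a linear
    trend (per hour) to the M+0 fraction to emulate a non-stationary pool.
    Returns {experiment: (times, {fragment: array (n_obs, n_masses)})}.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    raw = scenario.true_raw_mids(condition)
    rep_sd = scenario.mid_sd * np.sqrt(scenario.n_replicates)
    out = {}
    for exp in sorted(raw):
        times = np.repeat(np.asarray(scenario.quench_times), scenario.n_replicates)
        frags = {}
        for fid in sorted(raw[exp]):
            base = raw[exp][fid]
            obs = np.tile(base, (len(times), 1))
            if drift != 0.0:
                t0 = scenario.quench_times[0]
                obs[:, 0] += drift * (times - t0)
                obs[:, 1] -= drift * (times - t0)
            obs += rng.normal(0.0, rep_sd, obs.shape)
            frags[fid] = obs
        out[exp] = (times, frags)
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline

def end_to_end(seed: int = 0, n_multistarts: int = 3,
               ci_reactions: tuple = ("MPC1", "G6PDH", "FH")) -> dict:
    """Full pipeline smoke run: generate, regress, fit, compare, account.

    Returns a report dict with exometabolomic estimates, flux fits with
    recovery errors, confidence intervals and significance calls for the
    selected reactions, and the comparative ATP ledger.
    """
    from . import cofactors, exoflux
    from .fitting import (
        FitOptions,
        compare_conditions,
        fit_fluxes,
        goodness_of_fit,
        grid_search_ci,
    )

    scenario = make_scenario(seed=seed)
    report: dict = {"scenario": scenario.name, "seed": seed, "conditions": {}}
    fits = {}
    cis = {}
    for i, cond in enumerate(scenario.conditions):
        truth = scenario.conditions[cond]
        stage = "exometabolomics"
        try:
            tc = simulate_timecourses(scenario, cond, seed=seed * 7919 + i)
            growth = exoflux.fit_growth_rate(tc["counts"])
            k_gln = exoflux.fit_degradation_rate(tc["cell_free_glutamine"]).rate
            exo = {}
            for met, series in tc["amounts"].items():
                k = k_gln if met == "glutamine" else 0.0
                exo[met] = exoflux.fit_exchange_rate(
                    series, mu=growth.rate, X0=truth.X0, k=k, seed=seed * 31 + i
                )
            stage = "flux fit"
            # constrain the fit with the estimated rates, as a real
            # analysis must (the map sign turns signed q back into the
            # nonnegative net flux of the exchange reaction)
            overrides = {BIOMASS_ID: growth.rate}
            for met, result in exo.items():
                rid, sign = EXCHANGE_MAP[met]
                overrides[rid] = sign * result.q
            ms = simulate_mid_measurements(scenario, cond, seed=seed * 104729 + i,
                                           constraint_overrides=overrides)
            fit = fit_fluxes(
                scenario.model, ms,
                FitOptions(n_multistarts=n_multistarts, seed=seed * 13 + i),
            )
            gof = goodness_of_fit(fit)
            stage = "confidence intervals"
            cis[cond] = {
                rid: grid_search_ci(fit, rid) for rid in ci_reactions
            }
        except Exception as exc:  # surface the failing stage by name
            raise RuntimeError(f"pipeline stage {stage!r} failed for {cond!r}: {exc}") from exc
        fits[cond] = fit
        recovery = {
            rid: abs(fit.flux.net[rid] - truth.flux.net[rid])
            for rid in scenario.model.reaction_ids
        }
        report["conditions"][cond] = {
            "mu": growth.rate, "k_glutamine": k_gln,
            "exchange_rates": {m: r.q for m, r in exo.items()},
            "exo_results": exo,
            "fit": fit, "gof": gof, "recovery_error": recovery,
            "cis": cis[cond],
        }
    p = report["conditions"]["parental"]["exo_results"]
    f = report["conditions"]["fh_dim"]["exo_results"]
    report["exchange_table"] = exoflux.exchange_report(p, f)
    report["significance"] = compare_conditions(cis["parental"], cis["fh_dim"])
    stoich = cofactors.CofactorStoichiometry.default()
    ledgers = {
        cond: cofactors.atp_production(fits[cond].flux, stoich)
        for cond in fits
    }
    report["ledgers"] = ledgers
    report["atp_table"] = cofactors.ledger_report(
        ledgers["parental"], ledgers["fh_dim"]
    )
    return report


# ---------------------------------------------------------------------------
# method validation studies

def calibration_study(scenario: Scenario | None = None, n_replicates: int = 100,
                      n_multistarts: int = 2, seed: int = 0,
                      condition: str = "parental") -> dict:
    """Chi-squared calibration of the flux fit on correctly specified data.

    Each replicate draws fresh measurement noise (MID SD 0.01, 5% soft flux
    error) from the ground truth, refits, and applies the chi-squared test
    at alpha 0.05. On a correctly specified model the pass rate should sit
    near 95%.
    """
    from .fitting import FitOptions, fit_fluxes, goodness_of_fit

    scenario = scenario or make_scenario(seed=seed)
    rss, passes, dof = [], 0, None
    for i in range(n_replicates):
        ms = simulate_mid_measurements(scenario, condition, seed=seed * 65537 + i)
        fit = fit_fluxes(scenario.model, ms,
                         FitOptions(n_multistarts=n_multistarts, seed=seed + i))
        gof = goodness_of_fit(fit)
        rss.append(fit.rss)
        passes += gof.passed
        dof = gof.dof
    return {
        "n_replicates": n_replicates,
        "pass_rate": passes / n_replicates,
        "rss": rss,
        "dof": dof,
        "mean_rss": float(np.mean(rss)),
    }


def ci_coverage_study(scenario: Scenario | None = None, n_seeds: int = 10,
                      reactions: tuple = ("GLUT", "LDH", "G6PDH", "MPC1", "AKGDH"),
                      n_multistarts: int = 2, seed: int = 0,
                      condition: str = "parental") -> dict:
    """Grid-search CI coverage of ground-truth fluxes on noisy replicates.

    The audited reactions span the identifiable directions of the fit
    (soft-measured uptake/secretion, oxPPP, pyruvate import, TCA flux).
    Returns the fraction of (replicate, reaction) CIs containing the truth.
    """
    from .fitting import FitOptions, fit_fluxes, grid_search_ci

    scenario = scenario or make_scenario(seed=seed)
    truth = scenario.conditions[condition].flux
    hits, total, detail = 0, 0, {r: 0 for r in reactions}
    for i in range(n_seeds):
        ms = simulate_mid_measurements(scenario, condition, seed=seed * 99991 + i)
        fit = fit_fluxes(scenario.model, ms,
                         FitOptions(n_multistarts=n_multistarts, seed=seed + i))
        for rid in reactions:
            ci = grid_search_ci(fit, rid)
            lo = -np.inf if ci.lower is None else ci.lower - 1e-6
            hi = np.inf if ci.upper is None else ci.upper + 1e-6
            inside = lo <= truth.net[rid] <= hi
            hits += inside
            detail[rid] += inside
            total += 1
    return {
        "coverage": hits / total,
        "n_seeds": n_seeds,
        "per_reaction": {r: detail[r] / n_seeds for r in reactions},
    }


# ---------------------------------------------------------------------------
# file export (formats the other modules read)

def write_dataset(scenario: Scenario, out_dir, seed: int | None = None):
    """Write model, tracer, fragment, measurement, time-course and truth
    files for both conditions into ``out_dir``."""
    import json
    from pathlib import Path

    from .network import write_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_model(scenario.model, out / "model.tsv")
    with open(out / "tracers.tsv", "w") as fh:
        fh.write("# experiment\tsubstrate\tpositions\tpurity\tfraction\n")
        for exp, specs in scenario.tracers.items():
            for s in specs:
                pos = ",".join(str(p) for p in s.labeled_positions)
                fh.write(f"{exp}\t{s.substrate}\t{pos}\t{s.purity}\t{s.fraction}\n")
    with open(out / "fragments.tsv", "w") as fh:
        for f in scenario.fragments.values():
            carbons = ",".join(str(p + 1) for p in f.positions)
            formula = "".join(
                f"{el}{n if n > 1 else ''}" for el, n in f.formula.items()
            )
            fh.write(f"{f.id}\t{f.metabolite}\t{carbons}\t{formula}\n")
    for i, cond in enumerate(scenario.conditions):
        base_seed = (scenario.seed if seed is None else seed) * 7919 + i
        ms = simulate_mid_measurements(scenario, cond, seed=base_seed)
        with open(out / f"mids_{cond}.tsv", "w") as fh:
            fh.write("# experiment\tfragment\tmass\tmean\tsd\n")
            for m in ms.mids:
                for mass, mean in enumerate(m.mean):
                    fh.write(f"{m.experiment}\t{m.fragment}\t{mass}\t{mean:.6f}\t{m.sd}\n")
        with open(out / f"constraints_{cond}.tsv", "w") as fh:
            fh.write("# reaction\tvalue\tmode\n")
            for rid, (value, _) in ms.soft_fluxes.items():
                fh.write(f"{rid}\t{value:.4f}\tsoft5pct\n")
            for rid, value in ms.hard_fluxes.items():
                fh.write(f"{rid}\t{value:.6g}\tfixed\n")
        tc = simulate_timecourses(scenario, cond, seed=base_seed + 1)
        with open(out / f"timecourses_{cond}.tsv", "w") as fh:
            fh.write("# id\tkind\ttime\tvalue\n")
            for series in [tc["counts"], tc["cell_free_glutamine"], *tc["amounts"].values()]:
                for t, v in zip(series.times, series.values):
                    fh.write(f"{series.id}\t{series.kind}\t{t:g}\t{v:.6g}\n")
        truth = scenario.conditions[cond]
        with open(out / f"truth_{cond}.json", "w") as fh:
            json.dump(
                {
                    "net_fluxes": truth.flux.net,
                    "exchange_fluxes": truth.flux.exchange,
                    "mixing_fractions": truth.mixing,
                    "mu": truth.mu, "X0": truth.X0,
                    "degradation": truth.degradation,
                },
                fh, indent=2,
            )
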