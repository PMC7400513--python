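"""Shared fixtures: the reference scenario and toy networks small enough
for the brute-force isotopomer oracle."""

import numpy as np
import pytest

import fluxtrace as ft
from fluxtrace.examples import (  # noqa: F401  (re-exported for tests)
    TOY_BUILDERS,
    build_model,
    frag,
    toy_chain,
    toy_cleave,
    toy_diamond,
    toy_reversible,
    toy_symmetric_fumarate,
    toy_tca_loop,
)


@pytest.fixture(scope="session")
def reference_model():
    return ft.load_model(ft.data_path("reference_model.tsv"))


@pytest.fixture(scope="session")
def scenario():
    return ft.make_scenario(seed=11)


@pytest.fixture(scope="session")
def truth_theta(scenario):
    """Parameter vector of the parental ground truth for the fit problem."""
    ms = ft.simulate_mid_measurements(scenario, "parental", seed=0, noise_sd=0.0)
    problem = ft.FluxFitProblem(scenario.model, ms)
    truth = scenario.conditions["parental"]
    u = problem.param.free_values(truth.flux)
    s = problem.options.exchange_scale
    eu = np.array([truth.flux.exchange[r] / (s + truth.flux.exchange[r])
                   for r in problem.exchange_ids])
    mix = []
    for pool, contributors in problem.mixing_pools:
        mix.extend(truth.mixing[pool][c] for c in contributors[:-1])
    return problem, np.concatenate([u, eu, np.array(mix)])
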