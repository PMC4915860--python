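"""Shared fixtures. Expensive pipeline runs (MCMC studies, the TP06 design)
are session-scoped so several tests can interrogate the same computation."""

from __future__ import annotations

import numpy as np
import pytest

import cardiouq as cq
from cardiouq import emulator as em_mod
from cardiouq.inference import (
    Prior,
    TraceLikelihood,
    identifiability_study,
    postprocess,
    run_mcmc,
)
from cardiouq.simulation import add_noise, prepace, run


@pytest.fixture(scope="session")
def br_model():
    return cq.get_model("beeler_reuter_1977")


@pytest.fixture(scope="session")
def tp06_model():
    return cq.get_model("tentusscher_2006_epi")


@pytest.fixture(scope="session")
def tt04_model():
    return cq.get_model("tentusscher_2004")


@pytest.fixture(scope="session")
def br_study():
    """Full single-AP recovery pipeline on Beeler-Reuter synthetic data."""
    model = cq.get_model("beeler_reuter_1977")
    protocol = cq.make_protocol("single_ap")
    return identifiability_study(model, protocol, seed=3, n_iterations=20_000)


@pytest.fixture(scope="session")
def tp06_design():
    """50-point Latin-hypercube TP06 design (20 beats at 1 Hz per point)."""
    return em_mod.build_design(50, seed=7)


@pytest.fixture(scope="session")
def tp06_test_runs():
    return em_mod.build_design(10, seed=8)


@pytest.fixture(scope="session")
def tp06_emulators(tp06_design):
    return em_mod.fit_all(tp06_design)


def _tt04_posterior(protocol, seed):
    model = cq.get_model("tentusscher_2004")
    seg = protocol.segments[0]
    state0, _ = prepace(model, None, seg.period, 100)
    clean = run(model, None, protocol, initial_state=state0)
    data = add_noise(clean, 0.25, seed=seed)
    prior = Prior.for_model(model)
    like = TraceLikelihood(model, protocol, data, initial_state=state0)

    def log_post(x):
        return like(x) if prior.contains(x) else -np.inf

    return log_post, prior, np.append(model.defaults.to_array(), 0.25)


@pytest.fixture(scope="session")
def tt04_single_ap_chain():
    """Reduced-scale TT04 single-AP posterior exploration.

    The chain starts at the generating parameters (the optimiser step is
    exercised elsewhere); what is probed here is the information content of
    the protocol, i.e. how far the posterior lets parameters wander.
    """
    log_post, prior, truth = _tt04_posterior(cq.make_protocol("single_ap"), seed=10)
    chain = run_mcmc(log_post, truth.copy(), 3000, seed=11, names=prior.names)
    return postprocess(chain, 0.25, 1), truth


@pytest.fixture(scope="session")
def tt04_long_chain():
    """Reduced-scale TT04 posterior for the 20 s (twenty-AP) protocol."""
    log_post, prior, truth = _tt04_posterior(
        cq.make_protocol("long_pacing", duration=20_000), seed=10
    )
    chain = run_mcmc(log_post, truth.copy(), 800, seed=12, names=prior.names)
    return postprocess(chain, 0.25, 1), truth
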