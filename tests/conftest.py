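"""Shared fixtures: reference parameter sets and the headline simulation.

The long mean-field run (the drifting-limit-cycle regime) is expensive, so
it is integrated once per session and shared by the analysis and
acceptance tests.
"""

import numpy as np
import pytest

from whiskstdp import (
    STDPRule,
    VonMisesSpec,
    default_initial_weights,
    euler_integrate,
    hz_to_angular,
    make_thalamic_model,
)

PSI_VPM = 5 * np.pi / 6


@pytest.fixture(scope="session")
def vpm_spec():
    return VonMisesSpec(kappa=1.0, psi=PSI_VPM)


@pytest.fixture(scope="session")
def headline_model(vpm_spec):
    """N=150 thalamic population, 7 Hz whisking, 3 ms delay, full modulation."""
    return make_thalamic_model(
        N=150, D=10.0, gamma=1.0, nu=hz_to_angular(7.0), d=0.003,
        phase_spec=vpm_spec,
    )


@pytest.fixture(scope="session")
def headline_rule():
    """Asymmetric exponential rule in the drifting (nearly additive) regime."""
    return STDPRule(
        "asymmetric_exponential", tau_plus=0.022, tau_minus=0.050,
        mu=0.01, alpha=1.1, lam=0.01,
    )


@pytest.fixture(scope="session")
def headline_trajectory(headline_model, headline_rule):
    """Long mean-field run on the drifting limit cycle (shared; ~7 s)."""
    init = default_initial_weights(headline_model.N, seed=0)
    return euler_integrate(
        init, headline_rule, headline_model,
        n_steps=200_000, dt=0.1, record_every=10,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
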