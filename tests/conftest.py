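"""Shared fixtures: small simulated ensembles reused across test modules."""

import numpy as np
import pytest

from fretkin.synthetic_traces import (
    EmissionModel,
    simulate_ensemble,
    three_state_model,
    two_state_model,
)

# kinetic conditions exercised throughout: a slow reversible two-state
# contact (high monovalent salt) and a three-state scheme with a twofold
# degenerate bound level (divalent-ion exchange)
TWO_STATE_RATES = dict(k01=0.0296, k10=0.051)
THREE_STATE_RATES = dict(k01=0.0214, k10=0.146, k12=0.331, k21=0.0256)


@pytest.fixture(scope="session")
def two_state_rate_model():
    return two_state_model(**TWO_STATE_RATES)


@pytest.fixture(scope="session")
def three_state_rate_model():
    return three_state_model(**THREE_STATE_RATES)


@pytest.fixture(scope="session")
def noisy_two_state_ensemble(two_state_rate_model):
    """60 traces x 400 s at 5 Hz, sigma_FRET = 0.1."""
    traces, paths = simulate_ensemble(
        two_state_rate_model,
        EmissionModel(fret_noise_sd=0.10),
        n_traces=60,
        duration=400.0,
        dt=0.2,
        seed=101,
    )
    return traces, paths


@pytest.fixture(scope="session")
def noiseless_two_state_ensemble(two_state_rate_model):
    traces, paths = simulate_ensemble(
        two_state_rate_model,
        EmissionModel(fret_noise_sd=0.0),
        n_traces=20,
        duration=400.0,
        dt=0.2,
        seed=77,
    )
    return traces, paths


@pytest.fixture(scope="session")
def noisy_three_state_ensemble(three_state_rate_model):
    traces, paths = simulate_ensemble(
        three_state_rate_model,
        EmissionModel(fret_noise_sd=0.10),
        n_traces=80,
        duration=400.0,
        dt=0.2,
        seed=202,
    )
    return traces, paths
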