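"""Shared fixtures: small simulated dyads generated at test time."""

import numpy as np
import pytest

from dyadcoh import SimulationConfig, make_protocol, simulate_dyad


@pytest.fixture(scope="session")
def short_timeline():
    """One trial per condition: 3 task + 4 rest epochs, 680 s."""
    return make_protocol(n_trials_per_condition=1, task_dur=120.0, rest_dur=80.0, seed=11)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_lsc=4, n_ssc=2, artifact_rate=0.3)


@pytest.fixture(scope="session")
def small_dyad(small_config, short_timeline):
    """A single simulated dyad on the reduced montage (4 LSC + 2 SSC)."""
    child, mother, truth = simulate_dyad(small_config, short_timeline, seed=42)
    return child, mother, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
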