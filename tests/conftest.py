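import numpy as np
import pytest

from neurostates import SyntheticConfig, generate_session
from neurostates import preprocessing as pp

# phase->state map reused by small-model fixtures: 4 states, one free
SMALL_MAP = {
    "seek": [
        ("start", 0), ("box open", 1), ("jump out", 2),
        ("interaction", 0), ("return transit", 1), ("jump in", 2),
    ],
    "hide": [
        ("start", 0), ("jump out", 2), ("interaction", 0),
        ("return transit", 1), ("jump in", 2),
    ],
}


def small_config(**overrides) -> SyntheticConfig:
    cfg = SyntheticConfig(
        K_true=4,
        d_true=2,
        n_neurons=10,
        n_trials=4,
        mean_trial_duration_s=30.0,
        phase_state_map={k: list(v) for k, v in SMALL_MAP.items()},
        free_states={3: "darting"},
        state_mean_scale=3.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_session():
    """A 10-neuron, 8-trial session with 4 well-separated states."""
    return generate_session(small_config(), seed=1)


@pytest.fixture(scope="session")
def small_binned(small_session):
    session, _ = small_session
    return {
        t.trial_id: pp.bin_spikes(session, t.trial_id) for t in session.trials
    }
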