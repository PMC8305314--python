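import numpy as np
import pytest
from hypothesis import settings

import mobileaat as m

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_session(rng):
    """Two-participant-sized session: 2 trials per category x direction, with
    ratings and a neophobia score."""
    cfg = m.ExperimentSimConfig(n_participants=1, trials_per_cell=2, seed=42)
    sessions, _ = m.simulate_experiment(cfg)
    return sessions[0]


@pytest.fixture
def pull_trial(rng):
    """One clean simulated pull trial plus its ground truth."""
    cfg = m.TraceSimConfig(seed=7)
    trace, truth = m.simulate_trace(cfg)
    rec = m.TrialRecord(
        participant_id="P0",
        block=1,
        stimulus_id="palatable_00",
        category="palatable",
        instructed_direction="pull",
        stim_onset=cfg.stim_onset_s,
        trace=trace,
        trial=0,
    )
    return rec, truth
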