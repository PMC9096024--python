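"""Shared fixtures: small synthetic sessions and spike-only trial schedules."""
import numpy as np
import pytest

from pcsacc.synthgen import (CellConfig, KinematicsConfig, draw_saccade_events,
                             generate_population, generate_schedule)


@pytest.fixture(scope="session")
def kin():
    return KinematicsConfig()


@pytest.fixture(scope="session")
def make_scored_trials(kin):
    """Schedule + ground-truth saccades, all marked correct (spike-only tests
    bypass the eye-detection chain)."""
    def _make(n_blocks=10, seed=11):
        root = np.random.SeedSequence(seed)
        s1, s2 = root.spawn(2)
        trials = generate_schedule(n_blocks, kin, s1)
        draw_saccade_events(trials, kin, s2)
        for t in trials:
            t.outcome = "correct"
        return trials
    return _make


@pytest.fixture(scope="session")
def scored_trials_10(make_scored_trials):
    return make_scored_trials(n_blocks=10, seed=11)


@pytest.fixture(scope="session")
def flat_cell_config():
    return CellConfig(baseline_rate_ss=60.0)


@pytest.fixture(scope="session")
def detected_session(kin):
    """A small full session (4 cells, 12 blocks) with detection already run."""
    from pcsacc.eyekin import detect_session
    from pcsacc.synthgen import default_population_spec

    session = generate_population(default_population_spec(), kin,
                                  n_blocks=12, seed=21)
    detect_session(session.trials, session.eye)
    return session
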