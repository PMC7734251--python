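"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from fatigueloop.control import SessionProtocol
from fatigueloop.synthetic import (
    FatigueModel,
    GaitPattern,
    simulate_gait_emg,
    simulate_resting_segment,
)


@pytest.fixture(scope="session")
def rest_recording():
    """5-s resting segment used for burst thresholds."""
    return simulate_resting_segment(5.0, seed=104)


@pytest.fixture(scope="session")
def short_gait_session():
    """One minute of forced running with moderate bilateral asymmetry."""
    proto = SessionProtocol(group="FOR-T", run_target_min=1.0)
    gait = GaitPattern(asymmetry=0.5)
    rec, truth = simulate_gait_emg(proto, FatigueModel(), gait, seed=31)
    return rec, truth


@pytest.fixture(scope="session")
def symmetric_gait_session():
    """One minute of running with no fatigue and no asymmetry."""
    proto = SessionProtocol(group="FOR-T", run_target_min=1.0)
    gait = GaitPattern(asymmetry=0.0)
    rec, truth = simulate_gait_emg(proto, FatigueModel(kappa=0.0), gait, seed=32)
    return rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
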