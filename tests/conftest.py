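"""Shared fixtures: synthetic sessions reused across test modules.

Expensive generator calls are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from sleepcouple.staging import stage
from sleepcouple.synth import (
    CouplingParams,
    RippleParams,
    SynthParams,
    generate_recording,
)


@pytest.fixture(scope="session")
def rec600():
    """Default 10-min synthetic session (full state cycle), seed 1."""
    return generate_recording(SynthParams(seed=1))


@pytest.fixture(scope="session")
def hyp600(rec600):
    return stage(rec600)


@pytest.fixture(scope="session")
def nrem_rec():
    """10-min NREM-only session at 2 kHz with default 9/min ripples."""
    p = SynthParams(
        seed=21,
        bout_schedule=[("WI", 20.0), ("NREM", 600.0), ("WI", 20.0)],
    )
    return generate_recording(p)


@pytest.fixture(scope="session")
def coupled_rec():
    """NREM session at 1 kHz with strong (gain 2) ripple-spindle coupling."""
    p = SynthParams(
        seed=22,
        fs=1000.0,
        bout_schedule=[("WI", 10.0), ("NREM", 300.0), ("WI", 10.0)],
        ripples=RippleParams(rate_per_min=15.0),
        coupling=CouplingParams(gain=2.0),
    )
    return generate_recording(p)


@pytest.fixture(scope="session")
def uncoupled_rec():
    """Same world as coupled_rec but with coupling gain 0."""
    p = SynthParams(
        seed=22,
        fs=1000.0,
        bout_schedule=[("WI", 10.0), ("NREM", 300.0), ("WI", 10.0)],
        ripples=RippleParams(rate_per_min=15.0),
        coupling=CouplingParams(gain=0.0),
    )
    return generate_recording(p)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
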