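"""Shared fixtures: expensive synthetic objects built once per session."""

import numpy as np
import pytest

from wavewire import (
    ProtonWireTopology,
    WireScript,
    build_scale_set,
    cwt_fast,
    make_wire_trajectory,
    wire_summary,
)


@pytest.fixture(scope="session")
def default_wire():
    """Default excited-state toy wire (1 ps, dt=0.5 fs) with ground truth."""
    script = WireScript()
    traj, gt = make_wire_trajectory(script)
    return script, traj, gt


@pytest.fixture(scope="session")
def default_wire_summary(default_wire):
    _, traj, _ = default_wire
    return wire_summary(traj, ProtonWireTopology())


@pytest.fixture(scope="session")
def low_freq_scales():
    """Fine grid around the pocket-mode region, dt = 0.5 fs."""
    return build_scale_set([(60.0, 250.0, 2.0)], dt=0.5)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
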