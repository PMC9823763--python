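"""Shared fixtures for the emoradar test suite."""

from __future__ import annotations

import numpy as np
import pytest

from emoradar import synthgen
from emoradar.synthgen import DisplacementModel, make_displacement


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def analytic_config():
    return synthgen.analytic_profile()


@pytest.fixture(scope="session")
def reduced_config():
    return synthgen.reduced_profile()


@pytest.fixture(scope="session")
def vital_cube():
    """One 40 s complex I/Q cube with known respiration 0.3 Hz / heart 1.2 Hz."""
    config = synthgen.reduced_profile()
    model = DisplacementModel(resp_amplitude=2.0, resp_freq=0.3,
                              heart_amplitude=0.3, heart_freq=1.2,
                              noise_sd=0.0)
    disp = make_displacement(model, duration=40.0, rate=config.frame_rate,
                             seed=0)
    cube = synthgen.simulate_if_cube(config, disp, statics=[],
                                     phase_noise_sd=0.0, seed=1,
                                     baseline_range=0.5, complex_iq=True)
    return cube, disp


@pytest.fixture()
def float64_model():
    """Run model layers in float64 for tight numeric gradient checks."""
    import emoradar.model as M
    old = M.DTYPE
    M.DTYPE = np.float64
    yield M
    M.DTYPE = old
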