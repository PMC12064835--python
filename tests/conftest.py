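"""Shared fixtures: default parameters and one settled reference simulation.

The settled 48 h run is computed once per session and reused by every test
that needs a developed travelling wave (front kinematics, tracers, the
excision comparison), which keeps the suite fast without weakening any
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteowave import default_params, simulate


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def settled_states(params):
    """Full default run (48 h), saved every 0.5 h."""
    return simulate(params, "step", save_every=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
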