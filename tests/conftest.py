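"""Shared fixtures: small landscapes and a reusable burned-in population.

Everything is generated programmatically with fixed seeds; the session-scoped
burned-in state keeps the expensive simulation work out of individual tests.
"""

import numpy as np
import pytest

from evorescue.ibm import SimConfig, run_burn_in
from evorescue.landscape import LandscapeParams, generate_landscape


@pytest.fixture(scope="session")
def landscape64():
    """Standard-normal environmental landscape, 64x64, fixed seed."""
    return generate_landscape(LandscapeParams(seed=11, resolution=64))


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale simulation configuration used across IBM tests."""
    return SimConfig(K=400, burn_in=300, seed=0)


@pytest.fixture(scope="session")
def burned_state(landscape64, small_cfg):
    """One shared 300-generation burn-in (cloned by tests that mutate it)."""
    return run_burn_in(landscape64, small_cfg, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
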