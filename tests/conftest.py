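from __future__ import annotations

import numpy as np
import pytest

from viroflow import ScenarioConfig, simulate


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_scenario():
    """One modest scenario shared by read-only tests."""
    return simulate(ScenarioConfig(seed=11, n_votus=30))
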