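"""Shared fixtures: a small synthetic world reused across test modules."""

import numpy as np
import pytest

from energyscape.synthetic import SimConfig, generate_landscape, simulate_individual


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=7, n_individuals=3, duration_days=6, grid_size=64)


@pytest.fixture(scope="session")
def world(small_cfg):
    """(landscape, ground truth) for the session's small world."""
    return generate_landscape(small_cfg)


@pytest.fixture(scope="session")
def one_individual(small_cfg, world):
    """(track, bursts, burst_truth) for the first simulated individual
    (dynamic GPS schedule)."""
    land, truth = world
    return simulate_individual(small_cfg, land, truth, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
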