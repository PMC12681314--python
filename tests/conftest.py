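"""Shared fixtures: a small simulated acquisition reused across modules.

The small fixture (48 x 48 grid, 6 coils, 3 slices, 10 frames of 25 spokes,
64 readout points) exercises every pipeline stage in seconds; the
full-size desk fixture lives in the acceptance tests.
"""

import numpy as np
import pytest

from smsradial import RunConfig, run_simulation
from smsradial.coilprep import estimate_sensitivities
from smsradial.experiments import SimulationRun


SMALL_KW = dict(
    grid_size=48,
    n_coils=6,
    n_frames=10,
    spokes_per_frame=25,
    points_per_spoke=64,
    noise_level=0.05,
    max_iterations=30,
    seed=0,
)


@pytest.fixture(scope="session")
def small_cfg() -> RunConfig:
    return RunConfig(**SMALL_KW)


@pytest.fixture(scope="session")
def small_run(small_cfg) -> SimulationRun:
    return run_simulation(small_cfg)


@pytest.fixture(scope="session")
def small_estimated_maps(small_run, small_cfg):
    maps, kspace, _ = estimate_sensitivities(small_run.kspace, small_cfg.grid_size)
    return maps, kspace


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    """The full desk-scale study conditions (64 grid, 8 coils, 40 frames)."""
    return RunConfig(max_iterations=30)


@pytest.fixture(scope="session")
def default_run(default_cfg) -> SimulationRun:
    return run_simulation(default_cfg)


@pytest.fixture(scope="session")
def default_noiseless_run(default_cfg) -> SimulationRun:
    return run_simulation(default_cfg.replace(noise_level=0.0))


@pytest.fixture(scope="session")
def default_estimated_maps(default_run, default_cfg):
    maps, kspace, _ = estimate_sensitivities(default_run.kspace, default_cfg.grid_size)
    return maps, kspace


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
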