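"""Shared fixtures: synthetic campaigns reused across test modules.

All fixtures are deterministic (fixed seeds) and generated at session scope
so expensive Langevin/WHAM work runs once.
"""

import numpy as np
import pytest
from hypothesis import settings

from flipkin.pipeline import run_benchmark

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from flipkin.synthetic import ModelSystem, SimulationSpec, run_umbrella_campaign
from flipkin.wham import wham


@pytest.fixture(scope="session")
def double_well_model():
    """Default flipping-like double well (intra +30, extra -135, 3 kcal/mol
    barrier, extra state 2 kcal/mol more stable, constant D = 0.15)."""
    return ModelSystem.flipping_double_well()


@pytest.fixture(scope="session")
def small_campaign(double_well_model):
    """92 windows covering -150..32 deg (both states and the direct barrier),
    4000 samples per window: cheap but realistic umbrella data."""
    centers = -150.0 + 2.0 * np.arange(92)
    spec = SimulationSpec(n_samples=10_000, seed=11)
    return run_umbrella_campaign(
        double_well_model, centers, 400.0, spec, exchange_every=2000, seed=11
    )


@pytest.fixture(scope="session")
def small_profile(small_campaign):
    return wham(small_campaign.windows, n_bins=180)


@pytest.fixture(scope="session")
def benchmark_summary():
    """Full-scale end-to-end recovery: 180 windows x 1e5 samples, 1e4-walker
    first-passage oracle."""
    return run_benchmark(seed=0)
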