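"""Shared fixtures: small networks and cached baseline runs.

Simulations are the expensive part of this suite; session-scoped fixtures
run them once and share the results across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from swostim.network import build_lattice, sample_parameters
from swostim.simulator import SimConfig, run_simulation


@pytest.fixture(scope="session")
def default_net():
    net = build_lattice(seed=0)
    return sample_parameters(net, 0.05, seed=1)


@pytest.fixture(scope="session")
def small_net():
    """10x10 lattice for cheap simulation tests."""
    net = build_lattice(10, 10, seed=3)
    return sample_parameters(net, 0.05, seed=4)


@pytest.fixture(scope="session")
def baseline_run(default_net):
    """One 60-s unstimulated run of the default network."""
    cfg = SimConfig(net=default_net, duration_s=60.0, seed=11)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
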