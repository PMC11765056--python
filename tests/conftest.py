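"""Shared fixtures: small deterministic phantom cases and grids."""

import numpy as np
import pytest

from dosecast import PhantomConfig, VoxelGrid, generate_phantom


@pytest.fixture(scope="session")
def grid32():
    return VoxelGrid((32, 32, 32))


@pytest.fixture(scope="session")
def grid16():
    return VoxelGrid((16, 16, 16))


@pytest.fixture(scope="session")
def full_case(grid32):
    """One 32^3 phantom carrying all 7 OARs and all 3 PTVs."""
    cfg = PhantomConfig(grid=grid32, seed=42, missing_structure_rate=0.0)
    return generate_phantom(cfg, 0)


@pytest.fixture(scope="session")
def small_case(grid16):
    """One 16^3 phantom with every structure present (fast path)."""
    cfg = PhantomConfig(grid=grid16, seed=7, missing_structure_rate=0.0)
    return generate_phantom(cfg, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
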