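"""Shared fixtures: small deterministic cubes and phantoms."""

from __future__ import annotations

import numpy as np
import pytest

from multimsi.cube import SpectralImageCube
from multimsi.phantom import PhantomSpec, make_phantom


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def small_cube(rng) -> SpectralImageCube:
    """4x5 grid, 6 variables, one black pixel at (1, 2)."""
    values = rng.uniform(0.1, 2.0, size=(4, 5, 6))
    values[1, 2, :] = 0.0
    return SpectralImageCube(values=values, variables=np.arange(6, dtype=float) + 400.0)


@pytest.fixture(scope="session")
def small_phantom():
    """48x48 trimodal phantom with planted structure, light noise, seed 0."""
    spec = PhantomSpec(
        grid=(48, 48),
        block_widths=(30, 25, 10),
        n_features=6,
        seed=0,
        noise_sigma=0.01,
        floor_sigma=0.005,
        anatomy_strength=0.0,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry at default (heavier) noise, with anatomy texture."""
    spec = PhantomSpec(grid=(48, 48), block_widths=(30, 25, 10), n_features=6, seed=0)
    return make_phantom(spec)
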