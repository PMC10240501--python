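"""Shared fixtures: default instrument fields and small rendered cubes.

Session-scoped where construction is expensive; everything is seeded so
the suite is deterministic.
"""

import numpy as np
import pytest
from hypothesis import settings

from bcarskit import (
    NoiseModel, WavenumberAxis, cars_spectrum, default_pump, default_stokes,
    demo_scene, quartz_susceptibility, render_hypercube,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pump():
    return default_pump()


@pytest.fixture(scope="session")
def stokes():
    """Full-bandwidth Stokes (1100-1600 nm): two-color covers ~570-3400."""
    return default_stokes((1100.0, 1600.0))


@pytest.fixture(scope="session")
def axis_fine():
    """0.5 cm^-1 axis over the full Raman-active range."""
    return WavenumberAxis.from_step(400.0, 3200.0, 0.5)


@pytest.fixture(scope="session")
def axis_coarse():
    """2 cm^-1 axis used for cube-level tests."""
    return WavenumberAxis.from_step(900.0, 3100.0, 2.0)


@pytest.fixture(scope="session")
def nrb_reference(pump, stokes, axis_fine):
    """Clean quartz (pure-NRB) spectrum for KK normalization, chi_nr = 10."""
    return cars_spectrum(quartz_susceptibility(10.0), pump, stokes, axis_fine,
                         three_color=False)


@pytest.fixture(scope="session")
def cells_cube_noisy(pump, stokes, axis_coarse):
    """Noisy 3-species + substrate cube at the default noise level."""
    scene = demo_scene("cells", shape=(24, 24), seed=11, axis=axis_coarse)
    noise = NoiseModel(poisson_gain=1.0, gaussian_sigma=5.0, dark_level=0.0,
                       seed=11)
    cube, truth = render_hypercube(scene, pump, stokes, noise)
    return cube, truth


@pytest.fixture(scope="session")
def cells_cube_clean(pump, stokes, axis_coarse):
    """Noise-free version of the cells scene (zero dark, no noise terms)."""
    scene = demo_scene("cells", shape=(24, 24), seed=11, axis=axis_coarse)
    noise = NoiseModel(poisson_gain=0.0, gaussian_sigma=0.0, dark_level=0.0,
                       seed=0)
    cube, truth = render_hypercube(scene, pump, stokes, noise)
    return cube, truth


def best_match_cosine(candidates: np.ndarray, target: np.ndarray) -> float:
    """Largest |cosine| between `target` and any row of `candidates`."""
    t = target / np.linalg.norm(target)
    c = candidates / np.linalg.norm(candidates, axis=1, keepdims=True)
    return float(np.max(np.abs(c @ t)))
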