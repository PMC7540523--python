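"""Shared fixtures: phantoms and cached pipeline runs.

The study-scale phantom and its extraction are expensive, so they are built
once per session and shared by the integration and acceptance tests.  The
small phantom keeps the same physics at a reduced field of view for cheap
pipeline-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mvring.io import RunConfig
from mvring.pipeline import extract
from mvring.synthetic import RingSpec, biphasic_phantom, default_phantom
from mvring.types import Grid

SESSION_SEED = 1


@pytest.fixture(scope="session")
def phantom():
    """Study-scale biphasic vortex-ring phantom (64 x 64 x 40, 30 frames)."""
    return default_phantom(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def reference_extraction(phantom):
    velocity, masks, _ = phantom
    return extract(velocity, masks, RunConfig())


def make_small_phantom(seed: int = SESSION_SEED, noise_sd: float = 0.01, grad_amp: float = 0.05):
    """Reduced-FOV phantom (32 x 32 x 24, 20 frames, R = 9 mm ring)."""
    grid = Grid(shape=(32, 32, 24), spacing=(1.8, 2.5, 4.0), n_frames=20)
    center = np.array(
        [grid.origin[i] + (grid.shape[i] - 1) * grid.spacing[i] / 2 for i in range(3)]
    )
    spec = RingSpec(
        center=center + np.array([0.0, 0.0, 8.0]),
        normal=np.array([0.0, 0.0, 1.0]),
        radius=9.0,
        core_radius=3.0,
        circulation=0.015,
        amplitude_curve=np.zeros(20),
    )
    return biphasic_phantom(
        spec,
        grid,
        ea_timing=((3, 7), (12, 16)),
        noise_sd=noise_sd,
        grad_amp=grad_amp,
        seed=seed,
        lv_center=center,
        lv_semi_axes=(17.0, 17.0, 26.0),
    )


@pytest.fixture(scope="session")
def small_phantom():
    return make_small_phantom()


@pytest.fixture(scope="session")
def small_extraction(small_phantom):
    velocity, masks, _ = small_phantom
    return extract(velocity, masks, RunConfig())
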