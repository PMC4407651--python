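import numpy as np
import pytest

from rhizoflow.phase_io import AIR, SOIL, WATER, PhaseVolume
from rhizoflow.synthetic_geometry import SyntheticSpec, generate_sand_like


@pytest.fixture(scope="session")
def sand16():
    """Small saturated sand-like volume reused across solver tests.

    Grain radii are scaled to the tiny grid (the package defaults suit
    64^3 volumes)."""
    spec = SyntheticSpec(
        texture="sand_like",
        grid_shape=(16, 16, 16),
        target_porosity=0.45,
        grain_radius_range=(3.0, 6.0),
        rng_seed=3,
    )
    return generate_sand_like(spec)


@pytest.fixture(scope="session")
def sand32():
    spec = SyntheticSpec(
        texture="sand_like",
        grid_shape=(32, 32, 32),
        target_porosity=0.45,
        grain_radius_range=(4.0, 8.0),
        rng_seed=5,
    )
    return generate_sand_like(spec)


@pytest.fixture()
def channel_volume():
    """Straight vertical water channel of radius 5 voxels in solid."""
    labels = np.zeros((16, 32, 32), dtype=np.uint8)
    yy, xx = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
    circ = (yy - 15.5) ** 2 + (xx - 15.5) ** 2 <= 5.0**2
    labels[:, circ] = WATER
    return PhaseVolume(labels, 10.0)


def poiseuille_slab_mask(aperture, length=4, width=6):
    """Fluid slab of given aperture between solid walls, invariant along
    the flow (axis 2) and the spanwise (axis 0) directions."""
    mask = np.zeros((width, aperture + 2, length), dtype=bool)
    mask[:, 1 : 1 + aperture, :] = True
    return mask


def duct_mask(side, length=4):
    """Square duct of given side, flow along axis 0."""
    mask = np.zeros((length, side + 2, side + 2), dtype=bool)
    mask[:, 1 : 1 + side, 1 : 1 + side] = True
    return mask


def duct_mean_velocity_coefficient(terms=200):
    """Series-solution mean velocity of a square duct, per unit force and
    duct side squared (independent analytic oracle)."""
    s = sum(
        np.tanh((2 * i + 1) * np.pi / 2.0) / (2 * i + 1) ** 5 for i in range(terms)
    )
    return 1.0 / 12.0 - (16.0 / np.pi**5) * s
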