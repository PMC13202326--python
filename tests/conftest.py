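"""Shared fixtures: small seeded phantom cases and random mask/dose factories."""

import numpy as np
import pytest

from gradose.core import StructureMask, StructureSet, VolumeGrid
from gradose.phantom import PhantomConfig, compose_case


TINY_PHANTOM = PhantomConfig(
    shape=(16, 16, 16),
    spacing=(4.0, 4.0, 4.0),
    gtv_radius_range_mm=(5.0, 7.0),
    min_entry_depth_mm=6.0,
)

DESK_PHANTOM = PhantomConfig(shape=(24, 24, 24), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def tiny_case():
    """A 16^3 phantom case (fast; for loss/metric plumbing tests)."""
    return compose_case(TINY_PHANTOM, seed=3)


@pytest.fixture(scope="session")
def desk_case():
    """A 24^3 phantom case at the desk-preset resolution."""
    return compose_case(DESK_PHANTOM, seed=11)


@pytest.fixture(scope="session")
def default_case():
    """A 48^3 x 2 mm phantom case at the paper-faithful grid."""
    return compose_case(PhantomConfig(), seed=5)


def random_mask(rng, shape, p=0.3, nonempty=True):
    m = rng.random(shape) < p
    if nonempty and not m.any():
        m.flat[rng.integers(m.size)] = True
    return m


def random_grid(rng, shape, spacing=(2.0, 2.0, 2.0)):
    return VolumeGrid(rng.random(shape), spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
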