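"""Shared fixtures: all test data are generated programmatically."""

import numpy as np
import pytest

import brainmodes as bm


@pytest.fixture(scope="session")
def sphere4():
    """Unit icosphere at subdivision 4 (2,562 vertices)."""
    return bm.make_icosphere(4, 1.0)


@pytest.fixture(scope="session")
def sphere_basis(sphere4):
    """First 50 Laplace-Beltrami modes of the unit icosphere."""
    return bm.solve_modes(bm.assemble_lbo(sphere4), 50)


@pytest.fixture(scope="session")
def sphere2():
    """Small unit icosphere (162 vertices) for cheap tests."""
    return bm.make_icosphere(2, 1.0)


@pytest.fixture(scope="session")
def sphere2_basis(sphere2):
    return bm.solve_modes(bm.assemble_lbo(sphere2), 40)


@pytest.fixture(scope="session")
def sphere2_parc(sphere2):
    return bm.make_parcellation(sphere2, 16, seed=0)


@pytest.fixture(scope="session")
def ellipsoid_tet():
    """Tetra mesh of a small solid ellipsoid plus its 21-mode basis."""
    mask = bm.make_ellipsoid_volume((6, 7.5, 9), 1.0)
    tet = bm.tetrahedralize_mask(mask)
    basis = bm.solve_modes(bm.assemble_lbo(tet), 21)
    return mask, tet, basis


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def regular_tetrahedron_off() -> str:
    """OFF text for the smallest closed triangulation."""
    return (
        "OFF\n4 4 6\n"
        "1 1 1\n1 -1 -1\n-1 1 -1\n-1 -1 1\n"
        "3 0 1 2\n3 0 3 1\n3 0 2 3\n3 1 3 2\n"
    )
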