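"""Shared fixtures: reference geometry/mesh (session-scoped, they are
moderately expensive to build) and a single-cube FE model for patch tests."""

import numpy as np
import pytest

from lvmech import (
    FEModel,
    FiberField,
    LVGeometry,
    Mesh,
    assign_fibers,
    build_mesh,
    solve_geometry,
)
from lvmech.fe import BoundaryConditions


@pytest.fixture(scope="session")
def reference_geometry():
    return solve_geometry(50.0, 73.6)


@pytest.fixture(scope="session")
def coarse_mesh(reference_geometry):
    """Default-resolution calibrated mesh (n_circ=12, n_long=6, 7 layers)."""
    return build_mesh(reference_geometry, 12, 6, 7)


@pytest.fixture(scope="session")
def coarse_fibers(coarse_mesh):
    return assign_fibers(coarse_mesh)


@pytest.fixture(scope="session")
def tiny_mesh(reference_geometry):
    """Smallest admissible LV mesh, for solver tests."""
    return build_mesh(reference_geometry, 8, 4, 2)


@pytest.fixture(scope="session")
def tiny_model(tiny_mesh):
    return FEModel(tiny_mesh, assign_fibers(tiny_mesh))


def make_cube_model(side=10.0, foundation=0.0, fiber_dir=(1.0, 0.0, 0.0),
                    active_fiber_law="linear", **kwargs):
    """Single 8-node cube element with axis-aligned fibers."""
    s = side
    nodes = np.array(
        [
            [0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0],
            [0, 0, s], [s, 0, s], [s, s, s], [0, s, s],
            [s / 2, s / 2, 0],
        ],
        dtype=float,
    )
    elems = np.array([[0, 1, 2, 3, 4, 5, 6, 7]])
    geom = LVGeometry(a_endo=40.0, b_endo=20.0, a_epi=49.0, b_epi=29.0)
    mesh = Mesh(
        nodes=nodes, elems=elems,
        region=np.array([1]), layer=np.array([1]), long_index=np.array([0]),
        endo_faces=np.array([[0, 3, 2, 1]]),
        epi_faces=np.array([[4, 5, 6, 7]]),
        base_faces=np.array([[0, 1, 5, 4]]),
        base_nodes=np.array([0, 1, 2, 3]),
        base_ring=np.array([0, 1, 2, 3]),
        pressure_node=8, geometry=geom, n_circ=4, n_long=1, n_layers=1,
    )
    ngp = 8
    f = np.tile(np.asarray(fiber_dir, dtype=float), (1, ngp, 1))
    r = np.tile([0.0, 0.0, 1.0], (1, ngp, 1))
    l = np.cross(r, f)
    field = FiberField(
        myofiber=f, collagen=r,
        beta=np.zeros((1, ngp)), eta=np.zeros((1, ngp)),
        circumferential=f, longitudinal=l, radial=r,
    )
    return FEModel(
        mesh, field,
        bcs=BoundaryConditions(foundation_stiffness=foundation),
        active_fiber_law=active_fiber_law,
        **kwargs,
    )


@pytest.fixture()
def cube_model():
    return make_cube_model()
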