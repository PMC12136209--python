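"""Shared fixtures: small geometries and cached FEM solves.

FEM solves are expensive, so meshes and solutions that several tests inspect
are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from aortastress import AnatomyParams, make_dissected_aorta
from aortastress.fem import SolverConfig, solve_penalty
from aortastress.hemodynamics import LumenPressureField, lumen_pressure_field
from aortastress.mesh import build_solid_mesh, coarse_case


def uniform_pressure(mesh, p_kpa: float) -> LumenPressureField:
    na, nc = mesh.grid_shape
    z = np.zeros((na, nc), dtype=bool)
    return LumenPressureField(values=np.full((na, nc), p_kpa), fl_mask=z, thrombosed=z)


def make_tube_mesh(radius=17.0, length=100.0, n_circ=16, n_axial=12, **kwargs):
    params = AnatomyParams.straight_tube(
        radius=radius, length=length, n_circ=n_circ, n_axial=n_axial, **kwargs
    )
    case = make_dissected_aorta(params)
    return case, build_solid_mesh(case)


@pytest.fixture(scope="session")
def default_case():
    """Default dissected aorta on the full 50 x 200 grid."""
    return make_dissected_aorta()


@pytest.fixture(scope="session")
def coarse_dissected():
    """Default dissected case regenerated at FEM resolution (25 x 50)."""
    return coarse_case(make_dissected_aorta(), 2, 4)


@pytest.fixture(scope="session")
def dissected_mesh(coarse_dissected):
    return build_solid_mesh(coarse_dissected)


@pytest.fixture(scope="session")
def dissected_pressure(coarse_dissected):
    return lumen_pressure_field(coarse_dissected)


@pytest.fixture(scope="session")
def dissected_solution(dissected_mesh, dissected_pressure):
    """Penalty solve of the default dissected case (shared by several tests)."""
    disp, stress = solve_penalty(dissected_mesh, dissected_pressure)
    return disp, stress


@pytest.fixture(scope="session")
def tube_mesh():
    """Straight tube, outer radius 17 mm, wall 2 mm (inner radius 15 mm)."""
    case, mesh = make_tube_mesh()
    return case, mesh


@pytest.fixture(scope="session")
def tube_solution(tube_mesh):
    _, mesh = tube_mesh
    pressure = uniform_pressure(mesh, 20.0)
    disp, stress = solve_penalty(mesh, pressure)
    return mesh, pressure, disp, stress
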