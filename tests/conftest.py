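"""Shared fixtures: the reduced reference slab and its solution grid.

The reference slab keeps the study geometry (2.4 mm wall, 7 F catheter,
0.5 mm insertion, minimum admissible 26.4 mm lateral extent) at a 0.6 mm
grid so the whole conductivity-group / amplitude sweep stays fast; the
solutions are shared session-wide by every test that needs a converged
nonlinear field.
"""

import numpy as np
import pytest

from pfasim.conductivity import ConductivityModel
from pfasim.electrostatics import solve_potential
from pfasim.fibers import make_fiber_field
from pfasim.geometry import ScenarioConfig, build_slab_scenario
from pfasim.metrics import compute_metrics

REF_AMPLITUDES = (1000.0, 1500.0, 2000.0)
REF_GROUPS = (1, 2, 3, 4)


@pytest.fixture(scope="session")
def ref_config():
    return ScenarioConfig(lateral_extent=26.4e-3, resolution=0.6e-3,
                          blood_depth=6e-3)


@pytest.fixture(scope="session")
def ref_slab(ref_config):
    mesh = build_slab_scenario(ref_config)
    fibers = make_fiber_field(mesh, "UNIFORM", {"theta": 0.0})
    return mesh, fibers


@pytest.fixture(scope="session")
def grid_solutions(ref_slab):
    """{(group, mode, amplitude): (FieldSolution, AblationMetrics)} over the
    full comparison grid; IC is group-independent and solved once per
    amplitude."""
    mesh, fibers = ref_slab
    out = {}
    for amp in REF_AMPLITUDES:
        ic = None
        for group in REF_GROUPS:
            model = ConductivityModel.from_group(group, "AC")
            sol = solve_potential(mesh, fibers, model, amp)
            out[(group, "AC", amp)] = (
                sol, compute_metrics(mesh, sol.e_mag, keep_isosurface=False))
            if ic is None:
                model = ConductivityModel.from_group(group, "IC")
                sol = solve_potential(mesh, fibers, model, amp)
                ic = (sol, compute_metrics(mesh, sol.e_mag,
                                           keep_isosurface=False))
            out[(group, "IC", amp)] = ic
    return out


@pytest.fixture(scope="session")
def ref_solution_ac(grid_solutions):
    return grid_solutions[(4, "AC", 1000.0)][0]


@pytest.fixture(scope="session")
def ref_solution_ic(grid_solutions):
    return grid_solutions[(4, "IC", 1000.0)][0]


def make_plate_mesh(n=8, h=1e-3):
    """Single-material box with the two x-faces as Dirichlet node sets."""
    from pfasim.geometry import build_box
    mesh = build_box((n, n, n), (h, h, h))
    nid = (np.arange(mesh.n_nodes)
           .reshape(n + 1, n + 1, n + 1).transpose(2, 1, 0))
    return mesh, nid[0].ravel(), nid[n].ravel()


def hull_nodes(mesh):
    n = np.asarray(mesh.shape)
    nid = (np.arange(mesh.n_nodes)
           .reshape(n[2] + 1, n[1] + 1, n[0] + 1).transpose(2, 1, 0))
    return np.unique(np.concatenate([
        nid[0].ravel(), nid[-1].ravel(), nid[:, 0].ravel(),
        nid[:, -1].ravel(), nid[:, :, 0].ravel(), nid[:, :, -1].ravel()]))
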