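"""Field solver against closed-form oracles: parallel plate, manufactured
monopole, anisotropic coordinate stretching, current conservation."""

import numpy as np
import pytest

from pfasim.conductivity import ConductivityModel
from pfasim.electrostatics import (FieldSolution, compute_power_density,
                                   element_gradients, solve_fixed_conductivity,
                                   solve_potential, total_electrode_current)
from pfasim.errors import BoundaryTagError, DomainError
from pfasim.geometry import Region, build_box

from conftest import hull_nodes, make_plate_mesh


def _plate_solution(sigma_value, n=8, h=1e-3, V0=100.0, tensor=None):
    mesh, left, right = make_plate_mesh(n, h)
    if tensor is not None:
        sigma = np.tile(tensor, (mesh.n_elements, 1, 1))
    else:
        sigma = np.full(mesh.n_elements, sigma_value)
    dirn = np.concatenate([left, right])
    dirv = np.concatenate([np.full(left.size, V0), np.zeros(right.size)])
    V, K = solve_fixed_conductivity(mesh, sigma, dirn, dirv)
    return mesh, V, K, left, right, V0, n * h


def test_parallel_plate_uniform_field():
    mesh, V, K, left, right, V0, d = _plate_solution(0.0537)
    E = -element_gradients(mesh, V)
    e_mag = np.linalg.norm(E, axis=1)
    assert np.allclose(e_mag, V0 / d, rtol=1e-10)
    assert np.allclose(E[:, 1:], 0.0, atol=1e-10 * V0 / d)


def test_parallel_plate_anisotropic_transverse_independent():
    """1-D solution ignores transverse conductivities; current scales by
    sigma_l."""
    sl, st_ = 0.0848, 0.0226
    tensor = np.diag([sl, st_, st_])
    mesh, V, K, left, right, V0, d = _plate_solution(None, tensor=tensor)
    E = -element_gradients(mesh, V)
    assert np.allclose(np.linalg.norm(E, axis=1), V0 / d, rtol=1e-10)
    I = (K @ V)[left].sum()
    area = d * d
    assert I == pytest.approx(sl * (V0 / d) * area, rel=1e-8)


def test_parallel_plate_current_closed_form_and_conservation():
    mesh, V, K, left, right, V0, d = _plate_solution(0.0537)
    I_left = (K @ V)[left].sum()
    I_right = (K @ V)[right].sum()
    assert I_left == pytest.approx(0.0537 * (V0 / d) * d * d, rel=1e-8)
    assert abs(I_left + I_right) < 1e-8 * abs(I_left)


def test_linearity_with_fixed_conductivity(ref_slab):
    """Sigmoid disabled: V scales linearly, Q quadratically, current doubles
    exactly when the amplitude doubles."""
    mesh, fibers = ref_slab
    model = ConductivityModel.from_group(2, "AC", field_dependent=False)
    s1 = solve_potential(mesh, fibers, model, 500.0)
    s2 = solve_potential(mesh, fibers, model, 1000.0)
    assert np.allclose(s2.V, 2 * s1.V, atol=1e-6 * np.abs(s2.V).max())
    assert np.allclose(s2.Q, 4 * s1.Q, rtol=1e-5,
                       atol=1e-8 * s2.Q.max())
    i1 = total_electrode_current(s1, "ELECTRODE_LEFT_SURFACE")
    i2 = total_electrode_current(s2, "ELECTRODE_LEFT_SURFACE")
    assert i2 == pytest.approx(2 * i1, rel=1e-6)


def test_manufactured_monopole_solution():
    """Exact V0*a/r trace on the voxel electrode and outer box; the interior
    solve must reproduce the monopole within 2% over a < r < 5a."""
    h, n, a, V0 = 0.5e-3, 44, 2e-3, 1.0
    mesh = build_box((n, n, n), (h, h, h),
                     origin=(-11e-3, -11e-3, -11e-3))
    r = np.linalg.norm(mesh.node_coords, axis=1)
    exact = V0 * a / np.maximum(r, h / 4)
    inner = np.flatnonzero(r <= a)
    dirn = np.unique(np.concatenate([hull_nodes(mesh), inner]))
    V, _ = solve_fixed_conductivity(mesh, np.ones(mesh.n_elements), dirn,
                                    exact[dirn])
    band = (r > a) & (r < 5 * a)
    rel = np.abs(V[band] - exact[band]) / exact[band]
    assert rel.max() < 0.02


def test_anisotropic_stretch_equivalence():
    """Diagonal-tensor solve equals the isotropic solve of the
    coordinate-stretched problem (x_k' = x_k / sqrt(sigma_k))."""
    sl, st_ = 0.0848, 0.0226
    n, h = 20, 1e-3
    mesh_a = build_box((n, n, n), (h, h, h),
                       origin=(-10e-3, -10e-3, -10e-3))
    sig = np.zeros((mesh_a.n_elements, 3, 3))
    sig[:, 0, 0], sig[:, 1, 1], sig[:, 2, 2] = sl, st_, st_
    inner = np.flatnonzero(
        np.abs(mesh_a.node_coords).max(axis=1) <= 2e-3 + 1e-9)
    hull = hull_nodes(mesh_a)
    dirn = np.concatenate([inner, hull])
    dirv = np.concatenate([np.ones(inner.size), np.zeros(hull.size)])
    Va, _ = solve_fixed_conductivity(mesh_a, sig, dirn, dirv)
    stretched = (h / np.sqrt(sl), h / np.sqrt(st_), h / np.sqrt(st_))
    mesh_i = build_box((n, n, n), stretched)
    Vi, _ = solve_fixed_conductivity(mesh_i, np.ones(mesh_i.n_elements),
                                     dirn, dirv)
    assert np.abs(Va - Vi).max() < 0.01  # spec bound; agrees to ~1e-14


def test_power_density_examples():
    assert 0.0537 * (1e5) ** 2 == pytest.approx(5.37e8)
    rng = np.random.default_rng(7)
    E = rng.normal(size=(50, 3)) * 1e5
    fibers = rng.normal(size=(50, 3))
    fibers /= np.linalg.norm(fibers, axis=1)[:, None]
    from pfasim.conductivity import conductivity_tensor
    sig = conductivity_tensor(fibers, 0.0848, 0.0226)
    sol = FieldSolution(mesh=None, V=None, E=E,
                        e_mag=np.linalg.norm(E, axis=1), sigma_eff=sig,
                        J=None, Q=None, picard_iterations=0, residual=0.0,
                        amplitude=1.0)
    Q = compute_power_density(sol)
    brute = np.array([e @ s @ e for e, s in zip(E, sig)])
    assert np.allclose(Q, brute, rtol=1e-12)
    # E aligned with the fiber: Q = sigma_l |E|^2
    e_par = fibers * 1e5
    sol2 = FieldSolution(mesh=None, V=None, E=e_par,
                         e_mag=np.linalg.norm(e_par, axis=1), sigma_eff=sig,
                         J=None, Q=None, picard_iterations=0, residual=0.0,
                         amplitude=1.0)
    assert np.allclose(compute_power_density(sol2), 0.0848 * 1e10,
                       rtol=1e-10)


def test_solution_invariants_on_reference_slab(ref_solution_ac):
    """Discrete maximum principle, Q >= 0, Q = E.(sigma E), e_mag = |E|."""
    sol = ref_solution_ac
    assert np.all(sol.Q >= 0)
    assert np.allclose(sol.Q, compute_power_density(sol), rtol=1e-12)
    assert np.allclose(sol.e_mag, np.linalg.norm(sol.E, axis=1), rtol=1e-12)
    slack = 1e-6 * sol.amplitude
    assert sol.V.max() <= sol.amplitude + slack
    assert sol.V.min() >= -slack
    left = sol.electrode_nodes["ELECTRODE_LEFT_SURFACE"]
    right = sol.electrode_nodes["ELECTRODE_RIGHT_SURFACE"]
    assert np.allclose(sol.V[left], sol.amplitude)
    assert np.allclose(sol.V[right], 0.0)


def test_current_conservation_on_converged_solutions(grid_solutions):
    for (g, mode, amp), (sol, _) in grid_solutions.items():
        il = total_electrode_current(sol, "ELECTRODE_LEFT_SURFACE")
        ir = total_electrode_current(sol, "ELECTRODE_RIGHT_SURFACE")
        assert il > 0
        assert abs(il + ir) < 0.005 * abs(il)


def test_ac_unit_ratio_matches_ic_solution(ref_slab):
    mesh, fibers = ref_slab
    ac = ConductivityModel(mode="AC", ratio_R=1.0)
    ic = ConductivityModel(mode="IC")
    sa = solve_potential(mesh, fibers, ac, 1000.0)
    si = solve_potential(mesh, fibers, ic, 1000.0)
    assert np.allclose(sa.V, si.V, atol=1e-6 * 1000.0)


def test_ablation_volume_converges_under_refinement():
    """Successive 0.8 -> 0.6 -> 0.4 mm refinements of the reference slab
    change the ablation volume by shrinking increments (discretization
    convergence; the staircase boundary makes the leading error O(h))."""
    from pfasim.fibers import make_fiber_field
    from pfasim.geometry import ScenarioConfig, build_slab_scenario
    from pfasim.metrics import compute_metrics
    vols = []
    for res in (0.8e-3, 0.6e-3, 0.4e-3):
        cfg = ScenarioConfig(lateral_extent=26.4e-3, resolution=res,
                             blood_depth=3.2e-3)
        mesh = build_slab_scenario(cfg)
        fibers = make_fiber_field(mesh, "UNIFORM", {"theta": 0.0})
        model = ConductivityModel.from_group(4, "AC")
        sol = solve_potential(mesh, fibers, model, 1000.0)
        vols.append(compute_metrics(mesh, sol.e_mag,
                                    keep_isosurface=False).volume)
    d1 = abs(vols[1] - vols[0]) / vols[1]
    d2 = abs(vols[2] - vols[1]) / vols[2]
    assert d2 < d1
    assert d2 < 0.05


def test_solver_errors(ref_slab):
    mesh, fibers = ref_slab
    model = ConductivityModel.from_group(1, "AC")
    with pytest.raises(DomainError):
        solve_potential(mesh, fibers, model, -5.0)
    with pytest.raises(BoundaryTagError):
        box = build_box((4, 4, 4), (1e-3,) * 3)
        solve_potential(box, None, ConductivityModel(mode="IC"), 100.0)
    sol = solve_potential(mesh, fibers, model, 1000.0)
    with pytest.raises(BoundaryTagError):
        total_electrode_current(sol, "NO_SUCH_TAG")
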