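"""Nonlinear quasi-static potential solve and derived field quantities.

Solves div(sigma(E) grad V) = 0 on the structured hexahedral mesh with
Dirichlet values on the two electrode node sets (pulse amplitude on the left,
ground on the right) and natural zero-flux conditions elsewhere.  The
field-dependent myocardial conductivity is handled by Picard fixed-point
iteration with under-relaxation: solve the linear system, recompute the
element fields E = -grad V, update sigma(|E|), repeat until the relative
change in V drops below tolerance.

Elements are trilinear hexahedra; E, J and the Joule power density
Q = E . (sigma E) are piecewise constant per element (centroid gradient).
Electrode elements are excluded from assembly — every node they touch is a
Dirichlet node, which renders the metal exactly equipotential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .conductivity import ConductivityModel, effective_conductivity
from .errors import BoundaryTagError, ConvergenceError, DomainError
from .fibers import FiberField
from .geometry import (ELECTRODE_LEFT_SURFACE, ELECTRODE_RIGHT_SURFACE,
                       Region, TissueMesh)
from .materials import MaterialTable, default_materials

__all__ = ["SolverSettings", "FieldSolution", "solve_potential",
           "solve_fixed_conductivity", "compute_power_density",
           "total_electrode_current", "assemble_stiffness",
           "element_gradients"]

# VTK hex reference coordinates (xi, eta, zeta) in {-1, 1}
_REF = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                 [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)
_GPTS = _REF / np.sqrt(3.0)   # 2x2x2 Gauss points, weights 1


def _grad_operators(spacing):
    """(G, w_det, Gc): physical shape-function gradients at the 8 Gauss
    points (8, 8, 3), the constant weight*detJ, and the centroid gradient
    operator (8, 3) for a box element."""
    hx, hy, hz = spacing
    scale = np.array([2.0 / hx, 2.0 / hy, 2.0 / hz])
    G = np.empty((8, 8, 3))
    for g, (xi, eta, zeta) in enumerate(_GPTS):
        G[g, :, 0] = _REF[:, 0] * (1 + eta * _REF[:, 1]) * (1 + zeta * _REF[:, 2]) / 8
        G[g, :, 1] = _REF[:, 1] * (1 + xi * _REF[:, 0]) * (1 + zeta * _REF[:, 2]) / 8
        G[g, :, 2] = _REF[:, 2] * (1 + xi * _REF[:, 0]) * (1 + eta * _REF[:, 1]) / 8
    G *= scale
    w_det = hx * hy * hz / 8.0
    Gc = _REF / 8.0 * scale
    return G, w_det, Gc


def assemble_stiffness(mesh: TissueMesh, sigma, element_mask=None
                       ) -> sp.csr_matrix:
    """Global stiffness for per-element ``sigma``: (M, 3, 3) tensors or (M,)
    scalars.  ``element_mask`` restricts assembly (conducting elements)."""
    G, w_det, _ = _grad_operators(mesh.spacing)
    elems = mesh.elements
    if element_mask is not None:
        elems = elems[element_mask]
        sigma = sigma[element_mask]
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 1:
        K0 = w_det * np.einsum("gia,gja->ij", G, G)
        Ke = sigma[:, None, None] * K0
    else:
        Ke = w_det * np.einsum("gia,mab,gjb->mij", G, sigma, G,
                               optimize=True)
    rows = np.repeat(elems, 8, axis=1).ravel()
    cols = np.tile(elems, (1, 8)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return K.tocsr()


def element_gradients(mesh: TissueMesh, V: np.ndarray) -> np.ndarray:
    """Centroid gradient of the trilinear interpolant, (M, 3)."""
    _, _, Gc = _grad_operators(mesh.spacing)
    return V[mesh.elements] @ Gc


@dataclass(frozen=True)
class SolverSettings:
    picard_tolerance: float = 1e-6
    max_picard_iterations: int = 100
    relaxation: float = 0.7
    linear_solver_tolerance: float = 1e-10

    def __post_init__(self):
        if self.picard_tolerance <= 0:
            raise DomainError("picard_tolerance must be positive")
        if self.max_picard_iterations < 1:
            raise DomainError("max_picard_iterations must be >= 1")
        if not (0 < self.relaxation <= 1):
            raise DomainError("relaxation must lie in (0, 1]")


@dataclass
class FieldSolution:
    """Converged potential and derived per-element fields."""

    mesh: TissueMesh
    V: np.ndarray                 # (N,) volts
    E: np.ndarray                 # (M, 3) V/m
    e_mag: np.ndarray             # (M,) V/m
    sigma_eff: np.ndarray         # (M, 3, 3) S/m
    J: np.ndarray                 # (M, 3) A/m^2
    Q: np.ndarray                 # (M,) W/m^3
    picard_iterations: int
    residual: float
    amplitude: float
    stiffness: sp.csr_matrix = field(repr=False, default=None)
    electrode_nodes: dict = field(default_factory=dict, repr=False)


_DIRECT_SOLVE_MAX = 20_000  # free dofs; above this use preconditioned CG


def _linear_solve(K: sp.csr_matrix, n: int, dir_nodes: np.ndarray,
                  dir_values: np.ndarray, x0: np.ndarray | None = None,
                  rtol: float = 1e-10) -> np.ndarray:
    """Dirichlet-reduced solve: sparse LU for small systems, warm-started
    Jacobi-preconditioned CG (SPD operator) for large ones."""
    free = np.ones(n, dtype=bool)
    free[dir_nodes] = False
    free_idx = np.flatnonzero(free)
    Kff = K[free_idx][:, free_idx]
    rhs = -K[free_idx][:, dir_nodes] @ dir_values
    V = np.empty(n)
    V[dir_nodes] = dir_values
    if free_idx.size <= _DIRECT_SOLVE_MAX:
        V[free_idx] = spla.spsolve(Kff.tocsc(), rhs)
        return V
    d = Kff.diagonal()
    M = spla.LinearOperator(Kff.shape, lambda x: x / d)
    guess = x0[free_idx] if x0 is not None else None
    sol, info = spla.cg(Kff, rhs, x0=guess, rtol=rtol, atol=0.0, M=M,
                        maxiter=20_000)
    if info != 0:
        sol = spla.spsolve(Kff.tocsc(), rhs)
    V[free_idx] = sol
    return V


def solve_fixed_conductivity(mesh: TissueMesh, sigma, dirichlet_nodes,
                             dirichlet_values, element_mask=None,
                             x0: np.ndarray | None = None,
                             rtol: float = 1e-10
                             ) -> tuple[np.ndarray, sp.csr_matrix]:
    """One linear Dirichlet solve with a frozen conductivity field.

    Verification harness (manufactured solutions, stretch equivalence) and
    the inner step of the Picard loop.  Returns (V, assembled stiffness).
    """
    K = assemble_stiffness(mesh, sigma, element_mask)
    dir_nodes = np.asarray(dirichlet_nodes, dtype=np.int64)
    dir_values = np.broadcast_to(np.asarray(dirichlet_values, float),
                                 dir_nodes.shape).astype(float)
    V = _linear_solve(K, mesh.n_nodes, dir_nodes, dir_values, x0=x0,
                      rtol=rtol)
    return V, K


def _baseline_sigma(mesh: TissueMesh, fibers: FiberField | None,
                    model: ConductivityModel, materials: MaterialTable
                    ) -> np.ndarray:
    """(M, 3, 3) conductivity at zero field (electrode entries included for
    export completeness; they are never assembled)."""
    sigma = np.zeros((mesh.n_elements, 3, 3))
    eye = np.eye(3)
    for region in (Region.BLOOD, Region.INSULATOR, Region.ELECTRODE_LEFT,
                   Region.ELECTRODE_RIGHT):
        sigma[mesh.region_mask(region)] = materials[region].sigma * eye
    myo = np.flatnonzero(mesh.region_mask(Region.MYOCARDIUM))
    zero = np.zeros(myo.size)
    if model.mode == "AC":
        if fibers is None:
            from .errors import MissingFiberError
            raise MissingFiberError("AC mode requires a fiber field")
        if not np.array_equal(fibers.element_ids, myo):
            raise DomainError("fiber field does not cover the myocardium of "
                              "this mesh")
        sigma[myo] = effective_conductivity(fibers.directions, zero, model)
    else:
        sigma[myo] = effective_conductivity(None, zero, model)[:, None, None] \
            * eye
    return sigma


def solve_potential(mesh: TissueMesh, fibers: FiberField | None,
                    model: ConductivityModel, amplitude: float,
                    settings: SolverSettings | None = None,
                    materials: MaterialTable | None = None) -> FieldSolution:
    """Nonlinear potential solve for one pulse amplitude.

    The static solution is valid for every pulse of the protocol: the
    conductivity is memoryless in |E| and the biphasic polarity reversal
    leaves |E| and Q unchanged.
    """
    settings = settings or SolverSettings()
    materials = materials or default_materials()
    if amplitude <= 0:
        raise DomainError("amplitude must be positive")
    for tag in (ELECTRODE_LEFT_SURFACE, ELECTRODE_RIGHT_SURFACE):
        if tag not in mesh.boundary_facets \
                or len(mesh.boundary_facets[tag]) == 0:
            raise BoundaryTagError(f"mesh lacks electrode surface tag {tag}")

    left_nodes = mesh.region_nodes(Region.ELECTRODE_LEFT)
    right_nodes = mesh.region_nodes(Region.ELECTRODE_RIGHT)
    dir_nodes = np.concatenate([left_nodes, right_nodes])
    dir_values = np.concatenate([np.full(left_nodes.size, float(amplitude)),
                                 np.zeros(right_nodes.size)])
    conducting = ~(mesh.region_mask(Region.ELECTRODE_LEFT)
                   | mesh.region_mask(Region.ELECTRODE_RIGHT))
    myo = np.flatnonzero(mesh.region_mask(Region.MYOCARDIUM))

    sigma = _baseline_sigma(mesh, fibers, model, materials)
    V_old = np.zeros(mesh.n_nodes)
    # Aitken dynamic under-relaxation, seeded from settings.relaxation: the
    # steep sigmoid drives a two-cycle under any fixed relaxation factor
    # (transition-zone elements flip between the low and high branch);
    # the secant update annihilates it.
    omega = settings.relaxation
    r_prev = None
    max_iter = settings.max_picard_iterations if model.field_dependent else 1
    residual = np.inf
    K = None
    for iteration in range(1, max_iter + 1):
        V, K = solve_fixed_conductivity(mesh, sigma, dir_nodes, dir_values,
                                        element_mask=conducting, x0=V_old,
                                        rtol=settings.linear_solver_tolerance)
        residual = float(np.linalg.norm(V - V_old)
                         / max(np.linalg.norm(V), 1e-300))
        V_old = V
        if residual < settings.picard_tolerance or not model.field_dependent:
            break
        E = -element_gradients(mesh, V)
        e_mag_myo = np.linalg.norm(E[myo], axis=1)
        if model.mode == "AC":
            target = effective_conductivity(fibers.directions, e_mag_myo,
                                            model)
        else:
            target = effective_conductivity(None, e_mag_myo, model)[
                :, None, None] * np.eye(3)
        r = (target - sigma[myo]).ravel()
        if r_prev is not None:
            dr = r - r_prev
            denom = float(dr @ dr)
            if denom > 0:
                omega = float(np.clip(-omega * (r_prev @ dr) / denom,
                                      0.05, 1.0))
        sigma[myo] += omega * (target - sigma[myo])
        r_prev = r
    else:
        raise ConvergenceError(
            f"Picard iteration did not converge in {max_iter} steps "
            f"(relative V change {residual:.3e})", residual=residual)

    E = -element_gradients(mesh, V)
    e_mag = np.linalg.norm(E, axis=1)
    # store the conductivity actually consumed at the converged field
    if model.field_dependent:
        if model.mode == "AC":
            sigma[myo] = effective_conductivity(fibers.directions,
                                                e_mag[myo], model)
        else:
            sigma[myo] = effective_conductivity(None, e_mag[myo], model)[
                :, None, None] * np.eye(3)
        K = assemble_stiffness(mesh, sigma, element_mask=conducting)
        V = _linear_solve(K, mesh.n_nodes, dir_nodes, dir_values, x0=V,
                          rtol=settings.linear_solver_tolerance)
        E = -element_gradients(mesh, V)
        e_mag = np.linalg.norm(E, axis=1)
    J = np.einsum("mab,mb->ma", sigma, E)
    Q = np.einsum("ma,ma->m", E, J)
    return FieldSolution(mesh=mesh, V=V, E=E, e_mag=e_mag, sigma_eff=sigma,
                         J=J, Q=Q, picard_iterations=iteration,
                         residual=residual, amplitude=float(amplitude),
                         stiffness=K,
                         electrode_nodes={
                             ELECTRODE_LEFT_SURFACE: left_nodes,
                             ELECTRODE_RIGHT_SURFACE: right_nodes})


def compute_power_density(solution: FieldSolution) -> np.ndarray:
    """Joule power density Q = E . (sigma E) per element, W/m^3."""
    if solution.E is None or solution.sigma_eff is None:
        raise DomainError("solution lacks E / sigma fields")
    return np.einsum("ma,mab,mb->m", solution.E, solution.sigma_eff,
                     solution.E)


def total_electrode_current(solution: FieldSolution, electrode_tag: str
                            ) -> float:
    """Total current injected by the tagged electrode, amperes.

    Computed as the discrete reaction sum(K V) over the electrode's Dirichlet
    nodes — the FEM-consistent surface integral of J.n; positive for current
    flowing from the electrode into the tissue.
    """
    if electrode_tag not in solution.electrode_nodes:
        raise BoundaryTagError(electrode_tag)
    r = solution.stiffness @ solution.V
    return float(r[solution.electrode_nodes[electrode_tag]].sum())
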