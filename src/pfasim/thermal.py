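"""Transient Pennes bioheat stepping with the gated Joule source.

Solves rho c dT/dt = div(k grad T) + Q g(t) - rho_b c_b u . grad T with
zero-flux outer boundaries, blood inflow fixed at 37 C, and the Joule source
Q from the static field solution gated by the pulse schedule g(t).  Perfusion
and metabolic heat are neglected (orders of magnitude below the pulsed Joule
source); blood motion is a prescribed divergence-free velocity profile in the
blood region — a full CFD solve is out of scope.

Discretization: lumped-mass trilinear FEM diffusion + first-order upwind
advection on the structured node lattice, backward-Euler in time
(unconditionally stable for the stiff on/off source).  Temperatures in
Celsius throughout; the Kelvin offset cancels in every term used.

GATED mode steps the exact on/off schedule (fine steps during trains, coarse
steps during train intervals, source weighted by the exact on-fraction of
each step); DUTY_AVERAGED applies the duty-cycle-scaled source continuously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .electrostatics import FieldSolution, assemble_stiffness
from .errors import DomainError, StabilityError
from .geometry import BLOOD_INFLOW, Region, TissueMesh
from .materials import MaterialTable, default_materials
from .protocol import PulseProtocol, gating_schedule

__all__ = ["ThermalState", "ReynoldsResult", "reynolds_number",
           "build_velocity_field", "run_thermal_protocol"]

BODY_TEMPERATURE = 37.0  # C
_COURANT_LIMIT = 20.0    # accuracy guard for upwind advection


@dataclass
class ThermalState:
    """Temperature field after the protocol plus the max-T history."""

    T: np.ndarray                    # (N,) C per node
    t: float                         # s, end time
    max_T_trace: np.ndarray          # (steps, 2): t, max T over myocardium
    mode: str

    @property
    def max_myocardial_T(self) -> float:
        return float(self.max_T_trace[:, 1].max())


@dataclass(frozen=True)
class ReynoldsResult:
    value: float
    laminar: bool


def reynolds_number(rho: float, u: float, D: float, mu: float
                    ) -> ReynoldsResult:
    """Re = rho u D / mu with a laminar flag (Re < 2000)."""
    if rho <= 0 or u <= 0 or D <= 0 or mu <= 0:
        raise DomainError("Reynolds inputs must be positive")
    re = rho * u * D / mu
    return ReynoldsResult(value=re, laminar=re < 2000.0)


def build_velocity_field(mesh: TissueMesh, profile: str = "plug",
                         u0: float = 0.1) -> np.ndarray:
    """Prescribed blood velocity per element, (M, 3); zero outside blood.

    ``plug``: uniform (u0, 0, 0) in the blood region.  ``shear``: linear
    Couette-like profile u_x = u0 * z / blood_depth (no slip at the
    endocardium).  ``none``: stagnant blood.  All profiles are exactly
    divergence-free.
    """
    vel = np.zeros((mesh.n_elements, 3))
    blood = mesh.region_mask(Region.BLOOD)
    if profile == "none" or u0 == 0.0:
        return vel
    if profile == "plug":
        vel[blood, 0] = u0
    elif profile == "shear":
        zc = mesh.element_centroids()[blood, 2]
        zmax = mesh.node_coords[:, 2].max()
        vel[blood, 0] = u0 * np.clip(zc, 0.0, None) / max(zmax, 1e-300)
    else:
        raise DomainError(f"unknown velocity profile {profile!r}")
    return vel


def _node_velocities(mesh: TissueMesh, vel_elements: np.ndarray) -> np.ndarray:
    """Node velocities: average of attached element velocities, forced to
    zero on any node touching a non-blood element (no-slip interfaces)."""
    n = mesh.n_nodes
    acc = np.zeros((n, 3))
    cnt = np.zeros(n)
    for i in range(8):
        np.add.at(acc, mesh.elements[:, i], vel_elements)
        np.add.at(cnt, mesh.elements[:, i], 1.0)
    acc /= np.maximum(cnt, 1.0)[:, None]
    non_blood = np.unique(
        mesh.elements[~mesh.region_mask(Region.BLOOD)])
    acc[non_blood] = 0.0
    return acc


def _upwind_advection(mesh: TissueMesh, node_vel: np.ndarray,
                      rho_c_blood: float) -> sp.csr_matrix:
    """rho_b c_b u . grad T as a sparse upwind operator on the node lattice."""
    nx, ny, nz = mesh.shape
    shape_n = (nx + 1, ny + 1, nz + 1)
    n = mesh.n_nodes
    nid = (np.arange(n, dtype=np.int64)
           .reshape(nz + 1, ny + 1, nx + 1).transpose(2, 1, 0))
    rows, cols, vals = [], [], []
    strides = {0: (1, 0, 0), 1: (0, 1, 0), 2: (0, 0, 1)}
    for axis in range(3):
        u = node_vel[:, axis]
        if not np.any(u):
            continue
        h = mesh.spacing[axis]
        grid_u = u[nid]
        di, dj, dk = strides[axis]
        # upwind neighbour exists except on the inflow-side lattice face
        idx = np.indices(shape_n)
        has_prev = idx[axis] >= 1
        has_next = idx[axis] <= shape_n[axis] - 2
        pos = (grid_u > 0) & has_prev
        neg = (grid_u < 0) & has_next
        for mask, sign in ((pos, 1), (neg, -1)):
            ii, jj, kk = np.nonzero(mask)
            center = nid[ii, jj, kk]
            neigh = nid[ii - sign * di, jj - sign * dj, kk - sign * dk]
            coeff = rho_c_blood * sign * grid_u[mask] / h
            rows.extend([center, center])
            cols.extend([center, neigh])
            vals.extend([coeff, -coeff])
    if not rows:
        return sp.csr_matrix((n, n))
    rows = np.concatenate([np.asarray(r) for r in rows])
    cols = np.concatenate([np.asarray(c) for c in cols])
    vals = np.concatenate([np.asarray(v) for v in vals])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _lumped_vectors(mesh: TissueMesh, materials: MaterialTable
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rho*c per element, k per element, lumped heat capacity per node)."""
    rho_c = np.empty(mesh.n_elements)
    k = np.empty(mesh.n_elements)
    for region in Region:
        mask = mesh.region_mask(region)
        rho_c[mask] = materials[region].rho_c
        k[mask] = materials[region].k
    cap = np.zeros(mesh.n_nodes)
    share = rho_c * mesh.element_volume / 8.0
    for i in range(8):
        np.add.at(cap, mesh.elements[:, i], share)
    return rho_c, k, cap


def _source_vector(mesh: TissueMesh, Q: np.ndarray) -> np.ndarray:
    """Lumped nodal load from the element power density, W per node."""
    f = np.zeros(mesh.n_nodes)
    share = Q * mesh.element_volume / 8.0
    for i in range(8):
        np.add.at(f, mesh.elements[:, i], share)
    return f


def _time_steps(protocol: PulseProtocol, mode: str, dt_on: float,
                dt_off: float):
    """Yield (t0, t1, source_fraction) backward-Euler steps."""
    sched = gating_schedule(protocol)
    if mode == "DUTY_AVERAGED":
        duty = protocol.duty_cycle
        t = 0.0
        while t < sched.total_duration - 1e-15:
            t1 = min(t + dt_off, sched.total_duration)
            yield t, t1, duty
            t = t1
        return
    span = protocol.train_active_span
    block = span + protocol.train_interval
    for train in range(protocol.n_trains):
        t0 = train * block
        t = t0
        while t < t0 + span - 1e-15:
            t1 = min(t + dt_on, t0 + span)
            yield t, t1, sched.on_fraction(t, t1)
            t = t1
        t = t0 + span
        end = (train + 1) * block
        while t < end - 1e-15:
            t1 = min(t + dt_off, end)
            yield t, t1, 0.0
            t = t1


def run_thermal_protocol(mesh: TissueMesh, field: FieldSolution,
                         protocol: PulseProtocol,
                         materials: MaterialTable | None = None,
                         velocity: np.ndarray | None = None,
                         mode: str = "GATED",
                         dt_on: float = 25e-6, dt_off: float = 2e-3,
                         T0: float = BODY_TEMPERATURE) -> ThermalState:
    """Step the bioheat equation through the full pulse protocol."""
    if mode not in ("GATED", "DUTY_AVERAGED"):
        raise DomainError(f"unknown thermal mode {mode!r}")
    if mode == "GATED" and dt_on > protocol.pulse_width:
        raise DomainError("dt_on must not exceed the pulse width")
    if field.mesh is not mesh and field.mesh.n_nodes != mesh.n_nodes:
        raise DomainError("field was solved on a different mesh")
    materials = materials or default_materials()
    if velocity is None:
        velocity = np.zeros((mesh.n_elements, 3))

    _, k_elem, cap = _lumped_vectors(mesh, materials)
    K = assemble_stiffness(mesh, k_elem)
    node_vel = _node_velocities(mesh, velocity)
    umax = np.abs(node_vel).max()
    h_min = min(mesh.spacing)
    dt_max = max(dt_on, dt_off)
    if umax > 0 and umax * dt_max / h_min > _COURANT_LIMIT:
        raise StabilityError(
            f"advective Courant number {umax * dt_max / h_min:.1f} exceeds "
            f"{_COURANT_LIMIT}; refine dt or the grid")
    A = _upwind_advection(mesh, node_vel,
                          materials[Region.BLOOD].rho_c)
    F = _source_vector(mesh, field.Q)
    inflow = (np.unique(mesh.boundary_facets[BLOOD_INFLOW])
              if BLOOD_INFLOW in mesh.boundary_facets else
              np.empty(0, dtype=np.int64))
    myo_nodes = mesh.region_nodes(Region.MYOCARDIUM)

    Cap = sp.diags(cap)
    direct = mesh.n_nodes <= 20_000
    sys_cache: dict[float, object] = {}

    def system_for(dt: float):
        key = round(dt, 12)
        if key not in sys_cache:
            Asys = (Cap / dt + K + A).tocsr()
            if inflow.size:
                # Dirichlet rows: identity
                mask = np.zeros(mesh.n_nodes, dtype=bool)
                mask[inflow] = True
                diag_fix = sp.diags(mask.astype(float))
                keep = sp.diags((~mask).astype(float))
                Asys = keep @ Asys + diag_fix
            if direct:
                sys_cache[key] = ("lu", spla.splu(Asys.tocsc()))
            else:
                d = Asys.diagonal()
                M = spla.LinearOperator(Asys.shape, lambda x, d=d: x / d)
                sys_cache[key] = ("it", Asys, M)
        return sys_cache[key]

    T = np.full(mesh.n_nodes, float(T0))
    trace = [(0.0, float(T[myo_nodes].max()))]
    t_end = 0.0
    for t0, t1, g in _time_steps(protocol, mode, dt_on, dt_off):
        dt = t1 - t0
        solver = system_for(dt)
        rhs = cap / dt * T + g * F
        if inflow.size:
            rhs[inflow] = T0
        if solver[0] == "lu":
            T = solver[1].solve(rhs)
        else:
            _, Asys, M = solver
            T_new, info = spla.bicgstab(Asys, rhs, x0=T, rtol=1e-9,
                                        atol=0.0, M=M, maxiter=2000)
            if info != 0:
                T_new = spla.spsolve(Asys.tocsc(), rhs)
            T = T_new
        t_end = t1
        trace.append((t_end, float(T[myo_nodes].max())))
    return ThermalState(T=T, t=t_end, max_T_trace=np.asarray(trace),
                        mode=mode)
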