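"""Synthetic tissue scenarios: myocardial slab, blood pool, two-electrode catheter.

The scenarios stand in for a patient left-atrial wall: a myocardial slab of
homogeneous thickness with a blood region above it and a straight two-electrode
catheter lying parallel to the endocardial surface, pressed 0.5 mm into the
tissue.  Meshing is a structured hexahedral grid with element-wise region
assignment by cell-centroid classification against the analytic solids
(dependency-light and exactly reproducible).

Coordinate convention: x runs along the catheter axis, z is the wall normal
(z < 0 is myocardium, z > 0 blood), origin at the insulator midpoint on the
endocardial surface.  All lengths are SI meters internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import GeometryError, ResolutionError

__all__ = [
    "Region",
    "ScenarioConfig",
    "TissueMesh",
    "build_slab_scenario",
    "build_ostium_scenario",
    "slab_myocardial_volume",
    "ostium_myocardial_volume",
    "catheter_segment_volume",
]

FRENCH = 1e-3 / 3.0  # 1 F = 1/3 mm


class Region(IntEnum):
    MYOCARDIUM = 1
    BLOOD = 2
    ELECTRODE_LEFT = 3
    ELECTRODE_RIGHT = 4
    INSULATOR = 5


#: Boundary / interface facet tags.  ENDOCARDIAL is the internal
#: myocardium-blood interface consumed by the surface-area lesion metric.
ELECTRODE_LEFT_SURFACE = "ELECTRODE_LEFT_SURFACE"
ELECTRODE_RIGHT_SURFACE = "ELECTRODE_RIGHT_SURFACE"
EPICARDIAL = "EPICARDIAL"
OUTER = "OUTER"
BLOOD_INFLOW = "BLOOD_INFLOW"
BLOOD_OUTFLOW = "BLOOD_OUTFLOW"
ENDOCARDIAL = "ENDOCARDIAL"


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the synthetic slab/ostium scenarios.

    Defaults reproduce the study conditions: 2.4 mm wall, 7 F catheter with
    2 mm electrodes and a 2.5 mm insulator gap, 0.5 mm insertion, 400 um grid.
    """

    wall_thickness: float = 2.4e-3
    lateral_extent: float = 28e-3
    blood_depth: float = 8e-3
    electrode_length: float = 2e-3
    insulator_length: float = 2.5e-3
    catheter_diameter: float = 7 * FRENCH
    catheter_tail: float = 2e-3       # plastic shaft beyond each electrode
    insertion_depth: float = 0.5e-3
    resolution: float = 0.4e-3
    fiber_pattern: str = "UNIFORM"
    pattern_params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("wall_thickness", "lateral_extent", "blood_depth",
                     "electrode_length", "insulator_length",
                     "catheter_diameter", "resolution"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.insertion_depth < 0:
            raise GeometryError("insertion_depth must be non-negative")
        if self.insertion_depth >= self.wall_thickness:
            raise GeometryError(
                f"insertion_depth {self.insertion_depth} must be smaller than "
                f"wall_thickness {self.wall_thickness}")
        if self.resolution > self.electrode_length / 2:
            raise ResolutionError(
                f"resolution {self.resolution} coarser than half the electrode "
                f"length {self.electrode_length / 2}")
        min_lateral = 4 * (2 * self.electrode_length + self.insulator_length)
        if self.lateral_extent < min_lateral - 1e-12:
            raise GeometryError(
                f"lateral_extent {self.lateral_extent} below the minimum "
                f"{min_lateral} needed to keep the catheter clear of the sides")

    @property
    def catheter_radius(self) -> float:
        return self.catheter_diameter / 2

    @property
    def catheter_half_length(self) -> float:
        return (self.insulator_length / 2 + self.electrode_length
                + self.catheter_tail)


@dataclass
class TissueMesh:
    """Structured hexahedral mesh with region and boundary tags.

    ``elements`` uses VTK hexahedron node ordering.  ``boundary_facets`` maps a
    tag name to an (F, 4) array of node quads; internal interfaces (electrode
    surfaces, endocardium) live in the same dict.
    """

    shape: tuple[int, int, int]              # cells per axis
    spacing: tuple[float, float, float]
    origin: np.ndarray                       # (3,) min corner
    node_coords: np.ndarray                  # (N, 3) float64
    elements: np.ndarray                     # (M, 8) int64
    element_region: np.ndarray               # (M,) int8
    boundary_facets: dict[str, np.ndarray]
    characteristic_edge_length: float
    config: ScenarioConfig | None = None

    # -- structured helpers ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def element_volume(self) -> float:
        hx, hy, hz = self.spacing
        return hx * hy * hz

    def element_centroids(self) -> np.ndarray:
        return self.node_coords[self.elements].mean(axis=1)

    def region_mask(self, region: Region) -> np.ndarray:
        return self.element_region == int(region)

    def region_volume(self, region: Region) -> float:
        return self.region_mask(region).sum() * self.element_volume

    def region_nodes(self, region: Region) -> np.ndarray:
        """Sorted unique node ids touched by elements of ``region``."""
        return np.unique(self.elements[self.region_mask(region)])

    def facet_nodes(self, tag: str) -> np.ndarray:
        from .errors import BoundaryTagError
        if tag not in self.boundary_facets:
            raise BoundaryTagError(tag)
        return np.unique(self.boundary_facets[tag])


def _node_grid(nx: int, ny: int, nz: int) -> np.ndarray:
    """Node id lookup table, shape (nx+1, ny+1, nz+1)."""
    return (np.arange((nx + 1) * (ny + 1) * (nz + 1), dtype=np.int64)
            .reshape(nz + 1, ny + 1, nx + 1).transpose(2, 1, 0))


def _build_box_mesh(nx: int, ny: int, nz: int,
                    spacing: tuple[float, float, float],
                    origin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Node coordinates and hex connectivity for a structured box."""
    hx, hy, hz = spacing
    xs = origin[0] + hx * np.arange(nx + 1)
    ys = origin[1] + hy * np.arange(ny + 1)
    zs = origin[2] + hz * np.arange(nz + 1)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    nid = _node_grid(nx, ny, nz)
    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    # cell id = ix + nx*(iy + ny*iz): transpose to (iz, iy, ix) then ravel
    def cell_order(a):
        return a.transpose(2, 1, 0).ravel()
    i, j, k = cell_order(i), cell_order(j), cell_order(k)
    elems = np.column_stack([
        nid[i, j, k], nid[i + 1, j, k], nid[i + 1, j + 1, k], nid[i, j + 1, k],
        nid[i, j, k + 1], nid[i + 1, j, k + 1], nid[i + 1, j + 1, k + 1],
        nid[i, j + 1, k + 1],
    ])
    return nodes, elems


def _facet_quads_x(nid: np.ndarray, i: np.ndarray, j: np.ndarray,
                   k: np.ndarray) -> np.ndarray:
    """Quads of faces normal to x at node-plane i, cell (j, k)."""
    return np.column_stack([nid[i, j, k], nid[i, j + 1, k],
                            nid[i, j + 1, k + 1], nid[i, j, k + 1]])


def _facet_quads_y(nid, i, j, k):
    return np.column_stack([nid[i, j, k], nid[i + 1, j, k],
                            nid[i + 1, j, k + 1], nid[i, j, k + 1]])


def _facet_quads_z(nid, i, j, k):
    return np.column_stack([nid[i, j, k], nid[i + 1, j, k],
                            nid[i + 1, j + 1, k], nid[i, j + 1, k]])


def _interface_facets(region3, nid, pair_a, pair_b):
    """Quads of internal faces separating region sets ``pair_a`` and ``pair_b``.

    ``region3`` is the region array reshaped (nz, ny, nx).
    """
    quads = []
    in_a = np.isin(region3, pair_a)
    in_b = np.isin(region3, pair_b)
    # x-direction neighbours
    m = (in_a[:, :, :-1] & in_b[:, :, 1:]) | (in_b[:, :, :-1] & in_a[:, :, 1:])
    kz, jy, ix = np.nonzero(m)
    quads.append(_facet_quads_x(nid, ix + 1, jy, kz))
    # y-direction
    m = (in_a[:, :-1, :] & in_b[:, 1:, :]) | (in_b[:, :-1, :] & in_a[:, 1:, :])
    kz, jy, ix = np.nonzero(m)
    quads.append(_facet_quads_y(nid, ix, jy + 1, kz))
    # z-direction
    m = (in_a[:-1, :, :] & in_b[1:, :, :]) | (in_b[:-1, :, :] & in_a[1:, :, :])
    kz, jy, ix = np.nonzero(m)
    quads.append(_facet_quads_z(nid, ix, jy, kz + 1))
    return np.concatenate(quads, axis=0) if quads else np.empty((0, 4), int)


def build_box(shape: tuple[int, int, int],
              spacing: tuple[float, float, float],
              origin=(0.0, 0.0, 0.0),
              region: Region = Region.MYOCARDIUM) -> TissueMesh:
    """Plain single-region box mesh (solver verification harness).

    The whole hull is tagged OUTER.
    """
    nx, ny, nz = shape
    origin = np.asarray(origin, dtype=float)
    nodes, elems = _build_box_mesh(nx, ny, nz, spacing, origin)
    region_arr = np.full(elems.shape[0], int(region), dtype=np.int8)
    nid = _node_grid(nx, ny, nz)
    jy, kz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    jy, kz = jy.ravel(), kz.ravel()
    ix, kz2 = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
    ix, kz2 = ix.ravel(), kz2.ravel()
    ix3, jy3 = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ix3, jy3 = ix3.ravel(), jy3.ravel()
    hull = np.concatenate([
        _facet_quads_x(nid, np.zeros_like(jy), jy, kz),
        _facet_quads_x(nid, np.full_like(jy, nx), jy, kz),
        _facet_quads_y(nid, ix, np.zeros_like(ix), kz2),
        _facet_quads_y(nid, ix, np.full_like(ix, ny), kz2),
        _facet_quads_z(nid, ix3, jy3, np.zeros_like(ix3)),
        _facet_quads_z(nid, ix3, jy3, np.full_like(ix3, nz)),
    ])
    return TissueMesh(shape=(nx, ny, nz), spacing=tuple(spacing),
                      origin=origin, node_coords=nodes, elements=elems,
                      element_region=region_arr,
                      boundary_facets={OUTER: hull},
                      characteristic_edge_length=float(np.mean(spacing)))


def _catheter_region_of(xc, yc, zc, cfg: ScenarioConfig):
    """Region id per centroid for the catheter solids, 0 where outside."""
    r = cfg.catheter_radius
    z_axis = r - cfg.insertion_depth
    half_gap = cfg.insulator_length / 2
    le = cfg.electrode_length
    inside_rad = yc ** 2 + (zc - z_axis) ** 2 <= r ** 2
    inside_len = np.abs(xc) <= cfg.catheter_half_length
    cath = inside_rad & inside_len
    out = np.zeros(xc.shape, dtype=np.int8)
    left = cath & (xc >= -half_gap - le) & (xc < -half_gap)
    right = cath & (xc > half_gap) & (xc <= half_gap + le)
    out[cath] = int(Region.INSULATOR)
    out[left] = int(Region.ELECTRODE_LEFT)
    out[right] = int(Region.ELECTRODE_RIGHT)
    return out


def _assemble_scenario(cfg: ScenarioConfig, ostium_diameter: float = 0.0,
                       ostium_center: tuple[float, float] | None = None
                       ) -> TissueMesh:
    cfg.validate()
    if ostium_diameter < 0:
        raise GeometryError("ostium_diameter must be non-negative")
    if ostium_diameter >= cfg.lateral_extent / 2:
        raise GeometryError("ostium_diameter must be below lateral_extent/2")

    res = cfg.resolution
    nx = max(2, round(cfg.lateral_extent / res))
    ny = nx
    nz_myo = max(1, round(cfg.wall_thickness / res))
    hz = cfg.wall_thickness / nz_myo
    nz_blood = max(1, round(cfg.blood_depth / hz))
    nz = nz_myo + nz_blood
    hx = cfg.lateral_extent / nx
    hy = hx
    origin = np.array([-cfg.lateral_extent / 2, -cfg.lateral_extent / 2,
                       -cfg.wall_thickness])
    nodes, elems = _build_box_mesh(nx, ny, nz, (hx, hy, hz), origin)

    # centroid classification
    cx = origin[0] + hx * (np.arange(nx) + 0.5)
    cy = origin[1] + hy * (np.arange(ny) + 0.5)
    cz = origin[2] + hz * (np.arange(nz) + 0.5)
    ZC, YC, XC = np.meshgrid(cz, cy, cx, indexing="ij")
    region3 = np.where(ZC < 0, int(Region.MYOCARDIUM),
                       int(Region.BLOOD)).astype(np.int8)
    if ostium_diameter > 0:
        if ostium_center is None:
            oc = (0.0, ostium_diameter / 2 + cfg.catheter_radius + 2 * res)
        else:
            oc = ostium_center
        hole = ((XC - oc[0]) ** 2 + (YC - oc[1]) ** 2
                <= (ostium_diameter / 2) ** 2)
        region3[hole & (region3 == int(Region.MYOCARDIUM))] = int(Region.BLOOD)
    cath = _catheter_region_of(XC, YC, ZC, cfg)
    region3 = np.where(cath > 0, cath, region3)
    region = region3.ravel()

    nid = _node_grid(nx, ny, nz)
    facets: dict[str, np.ndarray] = {}
    tissue = [int(Region.MYOCARDIUM), int(Region.BLOOD)]
    facets[ELECTRODE_LEFT_SURFACE] = _interface_facets(
        region3, nid, [int(Region.ELECTRODE_LEFT)], tissue)
    facets[ELECTRODE_RIGHT_SURFACE] = _interface_facets(
        region3, nid, [int(Region.ELECTRODE_RIGHT)], tissue)
    facets[ENDOCARDIAL] = _interface_facets(
        region3, nid, [int(Region.MYOCARDIUM)], [int(Region.BLOOD)])

    # hull facets
    jy, kz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    jy, kz = jy.ravel(), kz.ravel()
    xlo = _facet_quads_x(nid, np.zeros_like(jy), jy, kz)
    xhi = _facet_quads_x(nid, np.full_like(jy, nx), jy, kz)
    blood_lo = region3[kz, jy, 0] == int(Region.BLOOD)
    blood_hi = region3[kz, jy, nx - 1] == int(Region.BLOOD)
    facets[BLOOD_INFLOW] = xlo[blood_lo]
    facets[BLOOD_OUTFLOW] = xhi[blood_hi]

    ix, kz2 = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
    ix, kz2 = ix.ravel(), kz2.ravel()
    ix3, jy3 = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ix3, jy3 = ix3.ravel(), jy3.ravel()
    facets[EPICARDIAL] = _facet_quads_z(nid, ix3, jy3, np.zeros_like(ix3))
    facets[OUTER] = np.concatenate([
        xlo[~blood_lo], xhi[~blood_hi],
        _facet_quads_y(nid, ix, np.zeros_like(ix), kz2),
        _facet_quads_y(nid, ix, np.full_like(ix, ny), kz2),
        _facet_quads_z(nid, ix3, jy3, np.full_like(ix3, nz)),
    ])

    mesh = TissueMesh(shape=(nx, ny, nz), spacing=(hx, hy, hz), origin=origin,
                      node_coords=nodes, elements=elems, element_region=region,
                      boundary_facets=facets,
                      characteristic_edge_length=float((hx + hy + hz) / 3),
                      config=cfg)
    for tag in (ELECTRODE_LEFT_SURFACE, ELECTRODE_RIGHT_SURFACE):
        if len(mesh.boundary_facets[tag]) == 0:
            raise GeometryError(f"no facets tagged {tag}; catheter not meshed")
    return mesh


def build_slab_scenario(config: ScenarioConfig) -> TissueMesh:
    """Myocardial slab + blood pool + embedded two-electrode catheter."""
    return _assemble_scenario(config)


def build_ostium_scenario(config: ScenarioConfig, ostium_diameter: float,
                          ostium_center: tuple[float, float] | None = None
                          ) -> TissueMesh:
    """Slab scenario with a circular trans-mural hole emulating a PV ostium.

    The hole axis is wall-normal; by default its rim is offset from the
    catheter axis so the catheter lies on tissue parallel to the rim.
    ``ostium_diameter = 0`` degenerates to the plain slab.
    """
    return _assemble_scenario(config, ostium_diameter, ostium_center)


# -- analytic CSG volumes (closed-form oracles) ---------------------------

def catheter_segment_volume(config: ScenarioConfig) -> float:
    """Exact volume of the catheter portion embedded below the endocardium.

    Circular-segment cross section (chord at depth ``insertion_depth``) times
    the full catheter length (flat-ended cylinder).
    """
    r = config.catheter_radius
    d = config.insertion_depth
    if d <= 0:
        return 0.0
    if d > 2 * r:
        d = 2 * r
    a = r - d
    seg = r ** 2 * np.arccos(a / r) - a * np.sqrt(r ** 2 - a ** 2)
    return float(seg * 2 * config.catheter_half_length)


def slab_myocardial_volume(config: ScenarioConfig) -> float:
    """Exact myocardial volume of the slab scenario."""
    return (config.lateral_extent ** 2 * config.wall_thickness
            - catheter_segment_volume(config))


def ostium_myocardial_volume(config: ScenarioConfig,
                             ostium_diameter: float) -> float:
    """Exact myocardial volume of the ostium scenario.

    Valid while the hole does not overlap the embedded catheter (the default
    placement guarantees a clearance of at least one catheter radius).
    """
    hole = np.pi * (ostium_diameter / 2) ** 2 * config.wall_thickness
    return slab_myocardial_volume(config) - float(hole)
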