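"""Lesion metrics from the field solution.

Irreversible electroporation is assumed above a field-strength threshold
(default 1000 V/cm = 1e5 V/m).  The element-wise |E| is volume-averaged to the
nodes of the myocardial region, and all metrics are evaluated on the resulting
piecewise-linear nodal field:

* ablation volume — the myocardial volume where |E| > threshold, integrated
  with sub-element resolution (each hexahedron split into six Kuhn tetrahedra,
  exact partial volumes of the linear field per tetrahedron);
* surface ablation area — same integral on the tagged endocardial interface;
* ablation isosurface — marching tetrahedra at |E| = threshold, with per-axis
  extents (max - min of the vertex coordinates), the lesion-size measure;
* paired AC-vs-IC differences with the significance thresholds (1 mm for
  extents, 5% for area/volume, 4 C for temperature).

Metrics are reported in mm / mm^2 / mm^3 (SI meters internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (DegenerateIsosurfaceError, DomainError,
                     InsufficientDataError, UndefinedPercentError)
from .geometry import ENDOCARDIAL, Region, TissueMesh

__all__ = ["AblationMetrics", "PairedDifference", "Isosurface",
           "nodal_field_magnitude", "ablation_volume",
           "surface_ablation_area", "extract_isosurface",
           "isosurface_extents", "paired_difference", "aggregate_stats",
           "compute_metrics", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 1e5  # V/m == 1000 V/cm

# Kuhn decomposition of the VTK hexahedron into 6 conforming tetrahedra
# (fan around the 0-6 diagonal; opposite faces get translated diagonals).
_KUHN_TETS = np.array([(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
                       (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)])


def nodal_field_magnitude(mesh: TissueMesh, e_mag: np.ndarray,
                          region: Region = Region.MYOCARDIUM) -> np.ndarray:
    """Volume-weighted average of element |E| to nodes, restricted to one
    region (uniform elements, so a plain mean over attached elements).
    Nodes not touching the region get 0."""
    elems = mesh.elements[mesh.region_mask(region)]
    vals = np.asarray(e_mag)[mesh.region_mask(region)]
    acc = np.zeros(mesh.n_nodes)
    cnt = np.zeros(mesh.n_nodes)
    for i in range(8):
        np.add.at(acc, elems[:, i], vals)
        np.add.at(cnt, elems[:, i], 1.0)
    return acc / np.maximum(cnt, 1.0)


def _region_tets(mesh: TissueMesh, region: Region) -> np.ndarray:
    """(T, 4) node ids of the Kuhn tetrahedra of one region."""
    elems = mesh.elements[mesh.region_mask(region)]
    return elems[:, _KUHN_TETS].reshape(-1, 4)


def _tet_volume(coords: np.ndarray) -> np.ndarray:
    """Volumes of (T, 4, 3) tetrahedra."""
    a = coords[:, 1] - coords[:, 0]
    b = coords[:, 2] - coords[:, 0]
    c = coords[:, 3] - coords[:, 0]
    return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0


def _wedge_volume(a1, a2, p11, p12, p21, p22) -> np.ndarray:
    """Volume of the convex wedge above the cut plane (two vertices above).

    Prism-style decomposition with triangles (a1, p11, p12) / (a2, p21, p22).
    """
    def vol(p, q, r, s):
        return np.abs(np.einsum("ij,ij->i", q - p,
                                np.cross(r - p, s - p))) / 6.0
    return (vol(a1, p11, p12, a2) + vol(p11, p12, a2, p21)
            + vol(p12, a2, p21, p22))


def _cut_points(xa, da, xb, db):
    """Plane crossings on edges a-b for (K, 3) endpoints and signed values."""
    t = (da / (da - db))[:, None]
    return xa + t * (xb - xa)


def ablation_volume(mesh: TissueMesh, e_mag: np.ndarray,
                    threshold: float = DEFAULT_THRESHOLD,
                    nodal: np.ndarray | None = None) -> float:
    """Myocardial volume with |E| > threshold, in mm^3 (sub-element exact
    for the piecewise-linear nodal field)."""
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    v = nodal if nodal is not None \
        else nodal_field_magnitude(mesh, e_mag)
    tets = _region_tets(mesh, Region.MYOCARDIUM)
    d = v[tets] - threshold
    above = d > 0
    nab = above.sum(axis=1)
    vol_full = mesh.element_volume / 6.0
    total = float(np.count_nonzero(nab == 4)) * vol_full

    coords = mesh.node_coords

    def corner_fraction(rows, invert):
        """Fraction cut off at a single odd vertex (1 above or 1 below)."""
        dd = d[rows]
        odd_above = not invert
        odd = np.argmax(dd > 0 if odd_above else dd <= 0, axis=1)
        r = np.arange(rows.size)
        d_odd = dd[r, odd]
        frac = np.ones(rows.size)
        for j in range(4):
            sel = j != odd
            dj = dd[r, j]
            denom = np.where(sel, d_odd - dj, 1.0)
            frac = np.where(sel, frac * d_odd / denom, frac)
        return frac

    rows1 = np.flatnonzero(nab == 1)
    if rows1.size:
        total += float(np.sum(corner_fraction(rows1, invert=False))) * vol_full
    rows3 = np.flatnonzero(nab == 3)
    if rows3.size:
        total += float(np.sum(1.0 - corner_fraction(rows3, invert=True))) \
            * vol_full
    rows2 = np.flatnonzero(nab == 2)
    if rows2.size:
        dd = d[rows2]
        tt = tets[rows2]
        order = np.argsort(~(dd > 0), axis=1, kind="stable")  # above first
        r = np.arange(rows2.size)[:, None]
        a_idx, b_idx = order[:, :2], order[:, 2:]
        xa1 = coords[tt[r[:, 0], a_idx[:, 0]]]
        xa2 = coords[tt[r[:, 0], a_idx[:, 1]]]
        xb1 = coords[tt[r[:, 0], b_idx[:, 0]]]
        xb2 = coords[tt[r[:, 0], b_idx[:, 1]]]
        da1, da2 = dd[r[:, 0], a_idx[:, 0]], dd[r[:, 0], a_idx[:, 1]]
        db1, db2 = dd[r[:, 0], b_idx[:, 0]], dd[r[:, 0], b_idx[:, 1]]
        p11 = _cut_points(xa1, da1, xb1, db1)
        p12 = _cut_points(xa1, da1, xb2, db2)
        p21 = _cut_points(xa2, da2, xb1, db1)
        p22 = _cut_points(xa2, da2, xb2, db2)
        total += float(np.sum(_wedge_volume(xa1, xa2, p11, p12, p21, p22)))
    return total * 1e9  # m^3 -> mm^3


def whole_element_volume(mesh: TissueMesh, e_mag: np.ndarray,
                         threshold: float = DEFAULT_THRESHOLD) -> float:
    """Coarse whole-element counting of the supra-threshold myocardial
    volume (mm^3); brackets the sub-element integral on smooth fields."""
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    myo = mesh.region_mask(Region.MYOCARDIUM)
    n = np.count_nonzero(np.asarray(e_mag)[myo] > threshold)
    return n * mesh.element_volume * 1e9


def surface_ablation_area(mesh: TissueMesh, surface_tag: str,
                          e_mag: np.ndarray,
                          threshold: float = DEFAULT_THRESHOLD,
                          nodal: np.ndarray | None = None) -> float:
    """Area with |E| > threshold on the tagged surface, mm^2."""
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    quads = mesh.boundary_facets.get(surface_tag)
    if quads is None:
        from .errors import BoundaryTagError
        raise BoundaryTagError(surface_tag)
    if len(quads) == 0:
        return 0.0
    v = nodal if nodal is not None \
        else nodal_field_magnitude(mesh, e_mag)
    tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])
    x = mesh.node_coords[tris]
    area = 0.5 * np.linalg.norm(
        np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)
    d = v[tris] - threshold
    nab = (d > 0).sum(axis=1)
    frac = np.zeros(tris.shape[0])
    frac[nab == 3] = 1.0

    def one_odd(rows, odd_above):
        dd = d[rows]
        odd = np.argmax(dd > 0 if odd_above else dd <= 0, axis=1)
        r = np.arange(rows.size)
        d_odd = dd[r, odd]
        f = np.ones(rows.size)
        for j in range(3):
            sel = j != odd
            dj = dd[r, j]
            denom = np.where(sel, d_odd - dj, 1.0)
            f = np.where(sel, f * d_odd / denom, f)
        return f

    rows1 = np.flatnonzero(nab == 1)
    if rows1.size:
        frac[rows1] = one_odd(rows1, odd_above=True)
    rows2 = np.flatnonzero(nab == 2)
    if rows2.size:
        frac[rows2] = 1.0 - one_odd(rows2, odd_above=False)
    return float(np.sum(area * frac)) * 1e6  # m^2 -> mm^2


@dataclass
class Isosurface:
    """Triangle soup of the |E| = threshold surface (coordinates in m)."""

    vertices: np.ndarray          # (3*T, 3)
    triangles: np.ndarray         # (T, 3) indices into vertices
    threshold: float

    @property
    def is_empty(self) -> bool:
        return self.triangles.shape[0] == 0


def extract_isosurface(mesh: TissueMesh, e_mag: np.ndarray,
                       threshold: float = DEFAULT_THRESHOLD,
                       nodal: np.ndarray | None = None) -> Isosurface:
    """Marching tetrahedra over the myocardial Kuhn decomposition."""
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    v = nodal if nodal is not None \
        else nodal_field_magnitude(mesh, e_mag)
    myo_nodes = np.unique(mesh.elements[mesh.region_mask(Region.MYOCARDIUM)])
    if myo_nodes.size and np.all(v[myo_nodes] == threshold):
        raise DegenerateIsosurfaceError(
            "field is constant and exactly at the threshold")
    tets = _region_tets(mesh, Region.MYOCARDIUM)
    d = v[tets] - threshold
    above = d > 0
    nab = above.sum(axis=1)
    coords = mesh.node_coords
    tri_pts = []

    def odd_cut(rows, odd_above):
        """Triangle per tet: cut points on the three edges of the odd
        vertex."""
        dd = d[rows]
        tt = tets[rows]
        odd = np.argmax(dd > 0 if odd_above else dd <= 0, axis=1)
        r = np.arange(rows.size)
        others = np.argsort(np.eye(4)[odd], axis=1, kind="stable")[:, :3]
        xo = coords[tt[r, odd]]
        do = dd[r, odd]
        pts = []
        for j in range(3):
            oj = others[:, j]
            pts.append(_cut_points(xo, do, coords[tt[r, oj]], dd[r, oj]))
        return np.stack(pts, axis=1)  # (K, 3, 3)

    rows1 = np.flatnonzero(nab == 1)
    if rows1.size:
        tri_pts.append(odd_cut(rows1, odd_above=True))
    rows3 = np.flatnonzero(nab == 3)
    if rows3.size:
        tri_pts.append(odd_cut(rows3, odd_above=False))
    rows2 = np.flatnonzero(nab == 2)
    if rows2.size:
        dd = d[rows2]
        tt = tets[rows2]
        order = np.argsort(~(dd > 0), axis=1, kind="stable")
        r = np.arange(rows2.size)
        a1, a2 = tt[r, order[:, 0]], tt[r, order[:, 1]]
        b1, b2 = tt[r, order[:, 2]], tt[r, order[:, 3]]
        da1, da2 = dd[r, order[:, 0]], dd[r, order[:, 1]]
        db1, db2 = dd[r, order[:, 2]], dd[r, order[:, 3]]
        p11 = _cut_points(coords[a1], da1, coords[b1], db1)
        p12 = _cut_points(coords[a1], da1, coords[b2], db2)
        p21 = _cut_points(coords[a2], da2, coords[b1], db1)
        p22 = _cut_points(coords[a2], da2, coords[b2], db2)
        # planar quad cycle p11 -> p21 -> p22 -> p12
        tri_pts.append(np.stack([p11, p21, p22], axis=1))
        tri_pts.append(np.stack([p11, p22, p12], axis=1))
    if not tri_pts:
        return Isosurface(vertices=np.empty((0, 3)),
                          triangles=np.empty((0, 3), dtype=np.int64),
                          threshold=threshold)
    pts = np.concatenate(tri_pts, axis=0)          # (T, 3, 3)
    verts = pts.reshape(-1, 3)
    tris = np.arange(verts.shape[0], dtype=np.int64).reshape(-1, 3)
    return Isosurface(vertices=verts, triangles=tris, threshold=threshold)


def isosurface_extents(iso: Isosurface) -> tuple[np.ndarray, bool]:
    """Per-axis max - min of the isosurface vertices, mm.

    Returns (extents, empty_flag); an empty surface reports zeros with the
    flag set.
    """
    if iso.is_empty:
        return np.zeros(3), True
    span = iso.vertices.max(axis=0) - iso.vertices.min(axis=0)
    return span * 1e3, False


@dataclass(frozen=True)
class PairedDifference:
    """AC-vs-IC difference of one metric with its significance call."""

    kind: str                # "extent" | "area" | "volume" | "temperature"
    value_ac: float
    value_ic: float
    absolute: float
    percent: float
    significant: bool


_SIGNIFICANCE = {"extent": ("absolute", 1.0),       # mm
                 "area": ("percent", 5.0),          # %
                 "volume": ("percent", 5.0),        # %
                 "temperature": ("absolute", 4.0)}  # C


def paired_difference(metric_ac: float, metric_ic: float,
                      kind: str) -> PairedDifference:
    """(X_AC - X_IC) absolute and percent-of-IC, flagged significant above
    the per-kind threshold (1 mm extents, 5% area/volume, 4 C temperature)."""
    if kind not in _SIGNIFICANCE:
        raise DomainError(f"unknown metric kind {kind!r}")
    absolute = metric_ac - metric_ic
    basis, cut = _SIGNIFICANCE[kind]
    if metric_ic == 0:
        if basis == "percent":
            raise UndefinedPercentError(
                f"percent difference undefined for zero IC {kind}")
        percent = np.nan
    else:
        percent = absolute / metric_ic * 100.0
    test_value = abs(absolute) if basis == "absolute" else abs(percent)
    return PairedDifference(kind=kind, value_ac=metric_ac,
                            value_ic=metric_ic, absolute=absolute,
                            percent=percent,
                            significant=bool(test_value >= cut))


def aggregate_stats(values) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need at least two values")
    return float(v.mean()), float(v.std(ddof=1))


@dataclass
class AblationMetrics:
    """Lesion metrics of one field solution (mm units)."""

    surface_area: float       # mm^2
    volume: float             # mm^3
    extent_x: float           # mm
    extent_y: float
    extent_z: float
    threshold: float          # V/m
    empty: bool
    isosurface: Isosurface = field(repr=False, default=None)

    def extents(self) -> np.ndarray:
        return np.array([self.extent_x, self.extent_y, self.extent_z])


def compute_metrics(mesh: TissueMesh, e_mag: np.ndarray,
                    threshold: float = DEFAULT_THRESHOLD,
                    surface_tag: str = ENDOCARDIAL,
                    keep_isosurface: bool = True) -> AblationMetrics:
    """All lesion metrics of one solution in a single pass."""
    nodal = nodal_field_magnitude(mesh, e_mag)
    vol = ablation_volume(mesh, e_mag, threshold, nodal=nodal)
    area = surface_ablation_area(mesh, surface_tag, e_mag, threshold,
                                 nodal=nodal)
    iso = extract_isosurface(mesh, e_mag, threshold, nodal=nodal)
    ext, empty = isosurface_extents(iso)
    return AblationMetrics(surface_area=area, volume=vol,
                           extent_x=float(ext[0]), extent_y=float(ext[1]),
                           extent_z=float(ext[2]), threshold=threshold,
                           empty=empty,
                           isosurface=iso if keep_isosurface else None)
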