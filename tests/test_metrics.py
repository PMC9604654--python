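"""Lesion metrics on analytic fields: threshold volumes, surface areas,
isosurfaces and paired statistics."""

import numpy as np
import pytest

from pfasim.errors import (DegenerateIsosurfaceError, DomainError,
                           InsufficientDataError, UndefinedPercentError)
from pfasim.geometry import ENDOCARDIAL, OUTER, Region, build_box
from pfasim.metrics import (ablation_volume, aggregate_stats,
                            extract_isosurface, isosurface_extents,
                            nodal_field_magnitude, paired_difference,
                            surface_ablation_area, whole_element_volume)

THRESHOLD = 1e5


def _box_with_nodal_field(n, h, func):
    """All-myocardium box plus an element field whose nodal average is not
    needed: tests pass the nodal values directly."""
    mesh = build_box((n, n, n), (h, h, h),
                     origin=(-n * h / 2, -n * h / 2, -n * h / 2))
    nodal = func(mesh.node_coords)
    return mesh, nodal


def test_uniform_fields_trivial_volumes():
    mesh = build_box((5, 5, 5), (1e-3,) * 3)  # 125 mm^3
    above = np.full(mesh.n_elements, 2 * THRESHOLD)
    below = np.full(mesh.n_elements, THRESHOLD / 2)
    assert ablation_volume(mesh, above) == pytest.approx(125.0, rel=1e-9)
    assert ablation_volume(mesh, below) == 0.0
    with pytest.raises(DomainError):
        ablation_volume(mesh, above, threshold=-1.0)


def test_point_source_ball_volume_closed_form_and_monte_carlo():
    """|E| = c / r^2: supra-threshold region is the ball r < sqrt(c/thr)."""
    c = THRESHOLD * (4e-3) ** 2        # r* = 4 mm
    r_star = np.sqrt(c / THRESHOLD)
    mesh, nodal = _box_with_nodal_field(
        48, 0.5e-3,
        lambda x: c / np.maximum(np.linalg.norm(x, axis=1), 1e-6) ** 2)
    vol = ablation_volume(mesh, None, THRESHOLD, nodal=nodal)
    exact = 4 / 3 * np.pi * (r_star * 1e3) ** 3
    assert vol == pytest.approx(exact, rel=0.02)
    # independent Monte-Carlo oracle of the supra-threshold ball
    rng = np.random.default_rng(42)
    pts = rng.uniform(-12e-3, 12e-3, size=(1_500_000, 3))
    frac = np.mean(np.linalg.norm(pts, axis=1) < r_star)
    mc = frac * (24e-3 * 1e3) ** 3
    assert vol == pytest.approx(mc, rel=0.02)


def test_volume_monotone_in_threshold():
    mesh, nodal = _box_with_nodal_field(
        16, 1e-3,
        lambda x: 3e5 * np.exp(-np.linalg.norm(x, axis=1) / 4e-3))
    vols = [ablation_volume(mesh, None, thr, nodal=nodal)
            for thr in (0.6e5, 1e5, 1.5e5, 2.2e5)]
    assert all(a >= b for a, b in zip(vols, vols[1:]))
    assert vols[0] > vols[-1] > 0


def test_sub_element_and_whole_element_volumes_bracket():
    """On a smooth field the marching-tetrahedra integral sits close to the
    whole-element count and converges with it."""
    c = THRESHOLD * (4e-3) ** 2
    gaps = []
    for n, h in ((12, 2e-3), (24, 1e-3)):
        mesh = build_box((n, n, n), (h, h, h),
                         origin=(-n * h / 2,) * 3)
        cen = mesh.element_centroids()
        e_elem = c / np.maximum(np.linalg.norm(cen, axis=1), 1e-6) ** 2
        sub = ablation_volume(mesh, e_elem, THRESHOLD)
        whole = whole_element_volume(mesh, e_elem, THRESHOLD)
        gaps.append(abs(sub - whole) / sub)
    assert gaps[1] < gaps[0]
    assert gaps[1] < 0.05


def test_surface_area_uniform_and_half_patch():
    n, h = 10, 0.5e-3  # 5 x 5 mm surface patch
    mesh = build_box((n, n, 2), (h, h, h))
    quads = mesh.boundary_facets[OUTER]
    z0 = mesh.node_coords[quads][:, :, 2]
    bottom = quads[np.all(z0 < 1e-12, axis=1)]
    mesh.boundary_facets["PATCH"] = bottom
    nodal = np.full(mesh.n_nodes, 2 * THRESHOLD)
    assert surface_ablation_area(mesh, "PATCH", None, THRESHOLD,
                                 nodal=nodal) == pytest.approx(25.0,
                                                               rel=1e-9)
    # step at the midline, nodes on the line exactly at threshold
    x = mesh.node_coords[:, 0]
    nodal = np.where(x < 2.5e-3 - 1e-12, 2 * THRESHOLD,
                     np.where(x > 2.5e-3 + 1e-12, THRESHOLD / 2,
                              float(THRESHOLD)))
    area = surface_ablation_area(mesh, "PATCH", None, THRESHOLD, nodal=nodal)
    assert area == pytest.approx(12.5, rel=1e-9)


def test_surface_area_radial_disc():
    """Smooth radial fall-off: supra-threshold area is the disc at the
    threshold radius."""
    n, h = 40, 0.5e-3
    mesh = build_box((n, n, 2), (h, h, h),
                     origin=(-10e-3, -10e-3, 0.0))
    quads = mesh.boundary_facets[OUTER]
    z0 = mesh.node_coords[quads][:, :, 2]
    bottom = quads[np.all(z0 < 1e-12, axis=1)]
    mesh.boundary_facets["PATCH"] = bottom
    r_star = 6e-3
    c = THRESHOLD * r_star ** 2
    rho = np.linalg.norm(mesh.node_coords[:, :2], axis=1)
    nodal = c / np.maximum(rho, 1e-6) ** 2
    area = surface_ablation_area(mesh, "PATCH", None, THRESHOLD, nodal=nodal)
    assert area == pytest.approx(np.pi * (r_star * 1e3) ** 2, rel=0.02)
    from pfasim.errors import BoundaryTagError
    with pytest.raises(BoundaryTagError):
        surface_ablation_area(mesh, "NOPE", None, THRESHOLD, nodal=nodal)


def test_isosurface_planar_cut():
    n, h = 10, 1e-3
    mesh = build_box((n, n, n), (h, h, h))
    x0 = 4.2e-3
    nodal = THRESHOLD * (1 + (x0 - mesh.node_coords[:, 0]) / 10e-3)
    iso = extract_isosurface(mesh, None, THRESHOLD, nodal=nodal)
    assert not iso.is_empty
    assert np.allclose(iso.vertices[:, 0], x0, atol=1e-9)
    ext, empty = isosurface_extents(iso)
    assert not empty
    assert ext == pytest.approx([0.0, 10.0, 10.0], abs=1e-6)


def test_isosurface_sphere_radii_and_extents():
    c = THRESHOLD * (4e-3) ** 2
    mesh, nodal = _box_with_nodal_field(
        48, 0.5e-3,
        lambda x: c / np.maximum(np.linalg.norm(x, axis=1), 1e-6) ** 2)
    iso = extract_isosurface(mesh, None, THRESHOLD, nodal=nodal)
    radii = np.linalg.norm(iso.vertices, axis=1)
    assert np.all(np.abs(radii - 4e-3) < 0.02 * 4e-3)
    ext, _ = isosurface_extents(iso)
    assert ext == pytest.approx([8.0, 8.0, 8.0], rel=0.02)
    # extents never exceed the mesh bounding box
    assert np.all(ext <= 24.0 + 1e-9)


def test_isosurface_empty_and_degenerate():
    mesh = build_box((4, 4, 4), (1e-3,) * 3)
    nodal = np.full(mesh.n_nodes, THRESHOLD / 3)
    iso = extract_isosurface(mesh, None, THRESHOLD, nodal=nodal)
    assert iso.is_empty
    ext, empty = isosurface_extents(iso)
    assert empty and np.all(ext == 0.0)
    with pytest.raises(DegenerateIsosurfaceError):
        extract_isosurface(mesh, None, THRESHOLD,
                           nodal=np.full(mesh.n_nodes, float(THRESHOLD)))


def _kuhn_interpolate(nodal, u):
    """Piecewise-linear interpolant of the Kuhn 6-tet split on a unit cube.

    Independent per-point evaluation: sort the coordinates descending and
    walk the staircase path (0,0,0) -> ... -> (1,1,1), which is exactly the
    simplex containing the point.
    """
    grid = nodal.reshape(2, 2, 2)  # (z, y, x)

    def value(bits):
        bx, by, bz = bits
        return grid[bz, by, bx]

    out = np.empty(len(u))
    for p, (ux, uy, uz) in enumerate(u):
        order = np.argsort([-ux, -uy, -uz], kind="stable")
        us = np.array([ux, uy, uz])[order]
        bits = np.zeros(3, dtype=int)
        val = (1 - us[0]) * value(bits)
        for step in range(3):
            bits[order[step]] = 1
            frac = us[step] - (us[step + 1] if step < 2 else 0.0)
            val += frac * value(bits)
        out[p] = val
    return out


def test_wedge_partial_volume_against_monte_carlo():
    """Random nodal fields exercise every marching-tet case; the exact
    sub-element volume must match Monte-Carlo sampling of the same
    piecewise-linear interpolant."""
    rng = np.random.default_rng(3)
    mesh = build_box((1, 1, 1), (1e-3,) * 3)
    u = rng.uniform(0, 1, size=(60_000, 3))
    for _ in range(5):
        nodal = rng.uniform(0.2, 1.8, size=mesh.n_nodes) * THRESHOLD
        vol = ablation_volume(mesh, None, THRESHOLD, nodal=nodal)
        vals = _kuhn_interpolate(nodal, u)
        mc = np.mean(vals > THRESHOLD) * 1.0  # mm^3
        assert vol == pytest.approx(mc, abs=0.012)


def test_nodal_averaging_restricted_to_region(ref_slab, ref_solution_ac):
    mesh, _ = ref_slab
    nodal = nodal_field_magnitude(mesh, ref_solution_ac.e_mag)
    blood_only = np.setdiff1d(mesh.region_nodes(Region.BLOOD),
                              mesh.region_nodes(Region.MYOCARDIUM))
    assert np.all(nodal[blood_only] == 0.0)
    myo_nodes = mesh.region_nodes(Region.MYOCARDIUM)
    assert nodal[myo_nodes].max() > 0


def test_paired_difference_kinds():
    d = paired_difference(2.0, 1.0, "volume")
    assert d.percent == pytest.approx(100.0) and d.significant
    d = paired_difference(1.04, 1.0, "volume")
    assert d.percent == pytest.approx(4.0, rel=1e-12)
    assert not d.significant
    d = paired_difference(5.0, 5.0, "area")
    assert d.absolute == 0.0 and not d.significant
    d = paired_difference(12.4, 10.9, "extent")
    assert d.significant and d.absolute == pytest.approx(1.5)
    d = paired_difference(39.0, 42.5, "temperature")
    assert not d.significant
    with pytest.raises(UndefinedPercentError):
        paired_difference(1.0, 0.0, "volume")
    with pytest.raises(DomainError):
        paired_difference(1.0, 1.0, "entropy")


def test_aggregate_stats():
    mean, sd = aggregate_stats([1.0, 2.0, 3.0])
    assert (mean, sd) == (2.0, 1.0)
    with pytest.raises(InsufficientDataError):
        aggregate_stats([5.0])
    rng = np.random.default_rng(11)
    v = rng.normal(size=100)
    mean, sd = aggregate_stats(v)
    brute_mean = sum(v) / len(v)
    brute_sd = np.sqrt(sum((x - brute_mean) ** 2 for x in v) / (len(v) - 1))
    assert mean == pytest.approx(brute_mean, rel=1e-12)
    assert sd == pytest.approx(brute_sd, rel=1e-12)
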