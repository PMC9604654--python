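"""Parametric fiber-direction fields for the synthetic scenarios.

Each myocardial element carries one unit direction-cosine vector (alpha, beta,
gamma) — the local myocyte bundle direction.  Three parametric patterns emulate
the fiber architecture at the study's ablation targets: a uniform in-plane
direction (roof-line analogue), circumferential rings around an ostium (PV
antrum analogue), and two oblique bundles blended across a dividing line
(posterior-wall analogue of the diverging septopulmonary/septoatrial bundles).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DegenerateFiberError, GeometryError
from .geometry import Region, TissueMesh

__all__ = ["FiberPattern", "FiberField", "make_fiber_field"]

_UNIT_TOL = 1e-12


class FiberPattern(str, Enum):
    UNIFORM = "UNIFORM"
    CIRCUMFERENTIAL = "CIRCUMFERENTIAL"
    CROSSING_BUNDLES = "CROSSING_BUNDLES"


@dataclass
class FiberField:
    """Unit fiber direction per myocardial element.

    ``element_ids`` are indices into ``mesh.elements`` (myocardium only, in
    ascending order); ``directions`` is the matching (K, 3) array.
    """

    element_ids: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.all(np.abs(norms - 1.0) <= _UNIT_TOL):
            raise DegenerateFiberError(
                f"fiber norms deviate from 1 by up to "
                f"{np.abs(norms - 1).max():.3e}")

    def as_element_array(self, mesh: TissueMesh) -> np.ndarray:
        """(M, 3) array over all elements, zero outside the myocardium."""
        out = np.zeros((mesh.n_elements, 3))
        out[self.element_ids] = self.directions
        return out


def _renormalize(v: np.ndarray, context: str) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-9):
        raise DegenerateFiberError(f"zero-norm fiber direction in {context}")
    return v / norms[:, None]


def make_fiber_field(mesh: TissueMesh,
                     pattern: FiberPattern | str,
                     pattern_params: dict | None = None) -> FiberField:
    """Build a fiber field on the myocardial elements of ``mesh``.

    Parameters (``pattern_params``):

    UNIFORM
        ``theta`` (rad, default 0): in-plane angle to the catheter (x) axis.
    CIRCUMFERENTIAL
        ``center`` ((x, y), default the mesh ostium placement or origin):
        fibers follow in-plane tangents of circles around the wall-normal axis
        through ``center``.
    CROSSING_BUNDLES
        ``theta_a``/``theta_b`` (rad, defaults +/- pi/4): bundle angles on the
        y > divide / y < divide sides; ``divide_y`` (m, default 0);
        ``blend_width`` (m, default 2 edge lengths): the two unit directions
        are linearly blended across the band and renormalized.
    """
    params = dict(pattern_params or {})
    pattern = FiberPattern(pattern)
    myo = np.flatnonzero(mesh.region_mask(Region.MYOCARDIUM))
    if myo.size == 0:
        raise GeometryError("mesh has no myocardial elements")
    c = mesh.element_centroids()[myo]

    if pattern is FiberPattern.UNIFORM:
        theta = float(params.get("theta", 0.0))
        d = np.tile([np.cos(theta), np.sin(theta), 0.0], (myo.size, 1))
    elif pattern is FiberPattern.CIRCUMFERENTIAL:
        cx, cy = params.get("center", (0.0, 0.0))
        rad = np.column_stack([c[:, 0] - cx, c[:, 1] - cy, np.zeros(myo.size)])
        d = _renormalize(np.column_stack([-rad[:, 1], rad[:, 0],
                                          np.zeros(myo.size)]),
                         "CIRCUMFERENTIAL tangent (element on the axis)")
    else:  # CROSSING_BUNDLES
        ta = float(params.get("theta_a", np.pi / 4))
        tb = float(params.get("theta_b", -np.pi / 4))
        y0 = float(params.get("divide_y", 0.0))
        w = float(params.get("blend_width",
                             2 * mesh.characteristic_edge_length))
        da = np.array([np.cos(ta), np.sin(ta), 0.0])
        db = np.array([np.cos(tb), np.sin(tb), 0.0])
        lam = np.clip((c[:, 1] - y0) / w + 0.5, 0.0, 1.0)
        d = _renormalize(lam[:, None] * da + (1 - lam)[:, None] * db,
                         "CROSSING_BUNDLES blend (antiparallel bundles)")

    # exact unit norm for the constant patterns too
    d = d / np.linalg.norm(d, axis=1)[:, None]
    return FiberField(element_ids=myo, directions=d)
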