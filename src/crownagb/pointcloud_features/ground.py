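"""Progressive TIN densification ground filter.

Seeds are block minima over a coarse grid; a triangulated ground surface
grows by admitting points whose perpendicular distance to the containing
facet and whose angles to the facet's vertices both stay below the
configured thresholds.  Facets steeper than the terrain inclination cap
never accept points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from ..core import GROUND, UNCLASSIFIED, PointCloud

__all__ = ["GroundFilterParams", "DegenerateCloudError", "filter_ground"]


class DegenerateCloudError(ValueError):
    """Raised when the cloud cannot support a ground triangulation."""


@dataclass
class GroundFilterParams:
    """Thresholds for progressive TIN densification (angles in degrees)."""

    terrain_inclination: float = 60.0
    iterative_angle: float = 6.0
    iterative_distance: float = 0.6
    seed_cell_size: float = 5.0
    max_iterations: int = 30

    def __post_init__(self) -> None:
        for name in ("terrain_inclination", "iterative_angle"):
            v = getattr(self, name)
            if not 0 < v < 90:
                raise ValueError(f"{name} must be in (0, 90), got {v}")
        if self.iterative_distance <= 0:
            raise ValueError("iterative_distance must be > 0")
        if self.seed_cell_size <= 0:
            raise ValueError("seed_cell_size must be > 0")


def _seed_indices(points: np.ndarray, cell: float) -> np.ndarray:
    """Index of the lowest point in every occupied coarse-grid cell."""
    ix = np.floor(points[:, 0] / cell).astype(np.int64)
    iy = np.floor(points[:, 1] / cell).astype(np.int64)
    key = (ix - ix.min()) * (iy.max() - iy.min() + 1) + (iy - iy.min())
    order = np.lexsort((points[:, 2], key))
    key_sorted = key[order]
    first = np.ones(len(key_sorted), dtype=bool)
    first[1:] = key_sorted[1:] != key_sorted[:-1]
    return order[first]


def _facet_planes(tri: Delaunay, z: np.ndarray):
    """Per-simplex plane coefficients z = a*x + b*y + c and slope cosines."""
    simplices = tri.simplices
    p = tri.points[simplices]  # (m, 3, 2)
    zz = z[simplices]  # (m, 3)
    # Solve the 3x3 system for each facet.
    ones = np.ones(p.shape[:2])
    design = np.dstack([p, ones])  # (m, 3, 3)
    coef = np.linalg.solve(design, zz[..., None])[..., 0]  # (m, 3): a, b, c
    slope = np.degrees(np.arctan(np.hypot(coef[:, 0], coef[:, 1])))
    return coef, slope


def filter_ground(cloud: PointCloud, params: GroundFilterParams = None
                  ) -> PointCloud:
    """Classify every point as ground or unclassified.

    Returns a new cloud carrying GROUND / UNCLASSIFIED labels; the input
    is untouched.  Raises :class:`DegenerateCloudError` when the seed
    points are collinear (no triangulation exists).
    """
    params = params or GroundFilterParams()
    n = len(cloud)
    if n == 0:
        return cloud.with_labels(np.empty(0, dtype=np.int32))

    pts = cloud.points
    is_ground = np.zeros(n, dtype=bool)
    seeds = _seed_indices(pts, params.seed_cell_size)
    is_ground[seeds] = True

    if len(seeds) < 3:
        raise DegenerateCloudError(
            "fewer than 3 seed points; enlarge the cloud or shrink "
            "seed_cell_size")

    tan_angle = np.tan(np.radians(params.iterative_angle))

    for _ in range(params.max_iterations):
        g_idx = np.flatnonzero(is_ground)
        try:
            tri = Delaunay(pts[g_idx, :2])
        except QhullError as exc:
            raise DegenerateCloudError(
                "ground seed points are collinear; cannot build a "
                "triangulation") from exc
        coef, slope = _facet_planes(tri, pts[g_idx, 2])

        cand = np.flatnonzero(~is_ground)
        if len(cand) == 0:
            break
        simplex = tri.find_simplex(pts[cand, :2])
        inside = simplex >= 0
        accepted = np.zeros(len(cand), dtype=bool)

        if inside.any():
            ci = cand[inside]
            si = simplex[inside]
            a, b, c = coef[si, 0], coef[si, 1], coef[si, 2]
            plane_z = a * pts[ci, 0] + b * pts[ci, 1] + c
            dz = np.abs(pts[ci, 2] - plane_z)
            # Perpendicular distance to the (unit-normalised) plane.
            dist = dz / np.sqrt(a ** 2 + b ** 2 + 1.0)
            # Angle to each facet vertex: arctan(dz / horizontal reach).
            verts = tri.points[tri.simplices[si]]  # (k, 3, 2)
            reach = np.hypot(verts[:, :, 0] - pts[ci, 0, None],
                             verts[:, :, 1] - pts[ci, 1, None])
            max_tan = np.max(dz[:, None] / np.maximum(reach, 1e-9), axis=1)
            ok = ((dist <= params.iterative_distance)
                  & (max_tan <= tan_angle)
                  & (slope[si] <= params.terrain_inclination))
            accepted[inside] = ok

        # Points outside the seed hull (extent margins): compare against
        # the nearest ground point instead of a facet.
        outside = ~inside
        if outside.any():
            co = cand[outside]
            tree = cKDTree(pts[g_idx, :2])
            d_xy, nn = tree.query(pts[co, :2])
            dz = np.abs(pts[co, 2] - pts[g_idx[nn], 2])
            ok = ((dz <= params.iterative_distance)
                  & (dz <= tan_angle * np.maximum(d_xy, 1e-9)))
            accepted[outside] = ok

        if not accepted.any():
            break
        is_ground[cand[accepted]] = True

    labels = np.where(is_ground, GROUND, UNCLASSIFIED).astype(np.int32)
    return cloud.with_labels(labels)
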