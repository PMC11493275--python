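"""Stem diameter from a breast-height slice of a TLS cloud.

A horizontal slice of normalised heights around 1.3 m is fitted with a
circle: algebraic (Taubin) fit, geometric Levenberg refinement, one
robust refit after trimming points more than 3 MAD from the circle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from ..core import PointCloud

__all__ = ["DbhEstimate", "fit_circle", "circumcircle", "estimate_dbh"]

BREAST_HEIGHT = 1.3


@dataclass
class DbhEstimate:
    """Fitted stem cross-section at breast height."""

    dbh_cm: float
    center: tuple  # (x, y) in metres
    n_points: int
    rms_residual: float  # metres


def _taubin_fit(x: np.ndarray, y: np.ndarray):
    """Algebraic circle fit (Taubin); returns (cx, cy, r)."""
    xm, ym = x.mean(), y.mean()
    u, v = x - xm, y - ym
    z = u ** 2 + v ** 2
    zm = z.mean()
    z0 = (z - zm) / (2.0 * np.sqrt(zm)) if zm > 0 else z - zm
    data = np.column_stack([z0, u, v])
    _, _, vt = np.linalg.svd(data, full_matrices=False)
    a0, a1, a2 = vt[2]
    a0 = a0 / (2.0 * np.sqrt(zm)) if zm > 0 else a0
    a3 = -zm * a0
    if abs(a0) < 1e-12:
        raise ValueError("degenerate circle fit (points nearly collinear)")
    cx = -a1 / (2.0 * a0)
    cy = -a2 / (2.0 * a0)
    r = np.sqrt(cx ** 2 + cy ** 2 - a3 / a0)
    return cx + xm, cy + ym, r


def fit_circle(x, y, refine: bool = True):
    """Least-squares circle through 2-D points; returns (cx, cy, r).

    Algebraic fit followed by geometric (orthogonal-residual) refinement.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    cx, cy, r = _taubin_fit(x, y)
    if refine:
        def resid(p):
            return np.hypot(x - p[0], y - p[1]) - p[2]
        res = least_squares(resid, (cx, cy, r), method="lm")
        cx, cy, r = res.x
    return float(cx), float(cy), float(abs(r))


def circumcircle(p1, p2, p3):
    """Closed-form circle through three points; returns (cx, cy, r)."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        raise ValueError("points are collinear")
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    r = np.hypot(ax - ux, ay - uy)
    return float(ux), float(uy), float(r)


def estimate_dbh(
    cloud: PointCloud,
    seed_xy,
    slice_center: float = BREAST_HEIGHT,
    slice_halfwidth: float = 0.05,
    search_radius: float = 1.0,
    min_points: int = 10,
) -> Optional[DbhEstimate]:
    """DBH (cm) from a height-normalised TLS cloud near a trunk seed.

    Points with z in ``slice_center +/- slice_halfwidth`` and within
    ``search_radius`` of the seed are circle-fitted; outliers beyond
    3 MAD of the radial residual are trimmed once and the circle refit.
    Returns None when the slice holds fewer than ``min_points`` points
    (DBH unavailable — not fatal).
    """
    sx, sy = float(seed_xy[0]), float(seed_xy[1])
    z = cloud.z
    sel = (np.abs(z - slice_center) <= slice_halfwidth) \
        & (np.hypot(cloud.x - sx, cloud.y - sy) <= search_radius)
    if sel.sum() < min_points:
        return None
    x, y = cloud.x[sel], cloud.y[sel]
    cx, cy, r = fit_circle(x, y)
    resid = np.hypot(x - cx, y - cy) - r
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = np.abs(resid - np.median(resid)) <= 3.0 * mad
        if keep.sum() >= min_points and keep.sum() < len(x):
            x, y = x[keep], y[keep]
            cx, cy, r = fit_circle(x, y)
            resid = np.hypot(x - cx, y - cy) - r
    return DbhEstimate(dbh_cm=200.0 * r, center=(cx, cy),
                       n_points=len(x),
                       rms_residual=float(np.sqrt(np.mean(resid ** 2))))
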