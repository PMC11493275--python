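"""Core data containers shared across the pipeline.

Coordinate conventions
----------------------
Continuous coordinates are metric (x east, y north, z up).  Rasters are
row-major from the north-west corner: row ``i`` maps to
``y = origin_y - (i + 0.5) * cell_size`` and column ``j`` to
``x = origin_x + (j + 0.5) * cell_size``.  All binning intervals are
closed-open ``[min, max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# Point classification codes (ASPRS LAS convention).
UNCLASSIFIED = 1
GROUND = 2
HIGH_VEGETATION = 5

CLASS_NAMES = {
    UNCLASSIFIED: "unclassified",
    GROUND: "ground",
    HIGH_VEGETATION: "high_vegetation",
}


@dataclass
class TreeRecord:
    """A single tree with its position and structural attributes.

    Units: ``x``/``y``/``H``/``R`` in metres, ``DBH`` in centimetres,
    ``W_ref`` in kilograms.
    """

    tree_id: int
    plot_id: int
    species: str
    x: float
    y: float
    H: float
    DBH: float
    R: float
    W_ref: Optional[float] = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("H", "DBH", "R"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if self.W_ref is not None and self.W_ref < 0:
            raise ValueError(f"W_ref must be >= 0, got {self.W_ref!r}")

    def replace(self, **kwargs) -> "TreeRecord":
        return replace(self, **kwargs)


@dataclass
class PointCloud:
    """An (n, 3) array of x, y, z points with per-point class labels."""

    points: np.ndarray
    labels: np.ndarray = None  # type: ignore[assignment]
    source: str = "ALS"
    nominal_density: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.labels is None:
            self.labels = np.full(len(self.points), UNCLASSIFIED, dtype=np.int32)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int32).reshape(-1)
        if len(self.labels) != len(self.points):
            raise ValueError("labels length must match point count")
        if self.nominal_density < 0:
            raise ValueError("nominal_density must be >= 0")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.points[mask], self.labels[mask],
                          self.source, self.nominal_density)

    def with_labels(self, labels: np.ndarray) -> "PointCloud":
        return PointCloud(self.points, labels, self.source, self.nominal_density)


@dataclass
class RasterGrid:
    """Regular float raster anchored at its north-west corner."""

    origin: tuple  # (x_min, y_max)
    cell_size: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple:
        """(x_min, y_min, x_max, y_max) of the covered area."""
        x0, y1 = self.origin
        return (x0, y1 - self.n_rows * self.cell_size,
                x0 + self.n_cols * self.cell_size, y1)

    def world_to_index(self, x, y):
        """Map world coordinates to (row, col); no bounds clipping."""
        x0, y1 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((y1 - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def index_to_world(self, row, col):
        """Cell-centre world coordinates of (row, col)."""
        x0, y1 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y1 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def sample(self, x, y):
        """Nearest-cell lookup, NaN outside the grid.

        Coordinates exactly on the south/east boundary fall into the
        last row/column rather than off the grid.
        """
        row, col = self.world_to_index(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        x_min, y_min, x_max, y_max = self.bounds
        eps = 1e-9
        inb = ((np.atleast_1d(x) >= x_min - eps)
               & (np.atleast_1d(x) <= x_max + eps)
               & (np.atleast_1d(y) >= y_min - eps)
               & (np.atleast_1d(y) <= y_max + eps))
        row = np.clip(row, 0, self.n_rows - 1)
        col = np.clip(col, 0, self.n_cols - 1)
        out = np.full(row.shape, np.nan)
        out[inb] = self.values[row[inb], col[inb]]
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out[0])
        return out

    def sample_bilinear(self, x, y):
        """Bilinearly interpolated lookup between cell centres; clamped
        to the edge value outside the centre lattice, NaN off-grid."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        x0, y1 = self.origin
        fc = np.clip((x - x0) / self.cell_size - 0.5, 0, self.n_cols - 1)
        fr = np.clip((y1 - y) / self.cell_size - 0.5, 0, self.n_rows - 1)
        c0 = np.floor(fc).astype(int)
        r0 = np.floor(fr).astype(int)
        c1 = np.minimum(c0 + 1, self.n_cols - 1)
        r1 = np.minimum(r0 + 1, self.n_rows - 1)
        tc = fc - c0
        tr = fr - r0
        v = ((1 - tr) * ((1 - tc) * self.values[r0, c0]
                         + tc * self.values[r0, c1])
             + tr * ((1 - tc) * self.values[r1, c0]
                     + tc * self.values[r1, c1]))
        x_min, y_min, x_max, y_max = self.bounds
        eps = 1e-9
        off = ((x < x_min - eps) | (x > x_max + eps)
               | (y < y_min - eps) | (y > y_max + eps))
        v = np.where(off, np.nan, v)
        if v.size == 1 and np.ndim(v) <= 1:
            return float(v[0])
        return v

    @classmethod
    def from_bounds(cls, bounds, cell_size, fill=np.nan) -> "RasterGrid":
        x_min, y_min, x_max, y_max = bounds
        n_cols = max(1, int(np.ceil((x_max - x_min) / cell_size)))
        n_rows = max(1, int(np.ceil((y_max - y_min) / cell_size)))
        vals = np.full((n_rows, n_cols), fill, dtype=float)
        return cls(origin=(x_min, y_min + n_rows * cell_size),
                   cell_size=cell_size, values=vals)
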