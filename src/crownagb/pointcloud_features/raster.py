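"""DEM / CHM construction and height normalisation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from ..core import GROUND, PointCloud, RasterGrid

__all__ = ["VegetationParams", "build_dem", "build_chm", "normalize_heights",
           "detect_high_vegetation"]


@dataclass
class VegetationParams:
    """Inclusive normalised-height band treated as tall vegetation."""

    lower_height: float = 2.0
    upper_height: float = 80.0

    def __post_init__(self) -> None:
        if not 0 <= self.lower_height < self.upper_height:
            raise ValueError("need 0 <= lower_height < upper_height")


def _cell_reduce(grid: RasterGrid, x, y, z, reduce: str) -> None:
    row, col = grid.world_to_index(x, y)
    ok = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    flat = row[ok] * grid.n_cols + col[ok]
    vals = np.full(grid.n_rows * grid.n_cols, np.nan)
    func = np.fmin if reduce == "min" else np.fmax
    func.at(vals, flat, z[ok])
    grid.values[:] = vals.reshape(grid.n_rows, grid.n_cols)


def build_dem(cloud: PointCloud, cell_size: float = 0.5,
              bounds=None) -> RasterGrid:
    """Ground raster: per-cell lowest ground return, TIN-interpolated
    into empty cells (nearest-neighbour outside the ground hull)."""
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    ground = cloud.labels == GROUND
    if not ground.any():
        raise ValueError("no ground-classified points; run filter_ground first")
    gx, gy, gz = cloud.x[ground], cloud.y[ground], cloud.z[ground]
    if bounds is None:
        bounds = (cloud.x.min(), cloud.y.min(), cloud.x.max(), cloud.y.max())
    dem = RasterGrid.from_bounds(bounds, cell_size)
    _cell_reduce(dem, gx, gy, gz, "min")

    empty = np.isnan(dem.values)
    if empty.any():
        rows, cols = np.nonzero(empty)
        cx, cy = dem.index_to_world(rows, cols)
        fill = np.full(len(rows), np.nan)
        if len(gz) >= 3:
            try:
                lin = LinearNDInterpolator(np.column_stack([gx, gy]), gz)
                fill = lin(cx, cy)
            except Exception:
                pass
        miss = np.isnan(fill)
        if miss.any():
            near = NearestNDInterpolator(np.column_stack([gx, gy]), gz)
            fill[miss] = near(cx[miss], cy[miss])
        dem.values[rows, cols] = fill
    return dem


def build_chm(cloud: PointCloud, dem: RasterGrid,
              cell_size: float = None) -> RasterGrid:
    """Canopy height raster: per-cell max z minus DEM, floored at 0.

    Cells with no returns are 0 (no canopy evidence).  ``cell_size``
    defaults to the DEM's; a finer CHM resamples the DEM by nearest cell.
    """
    cell_size = cell_size or dem.cell_size
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    chm = RasterGrid.from_bounds(dem.bounds, cell_size)
    _cell_reduce(chm, cloud.x, cloud.y, cloud.z, "max")
    rows, cols = np.meshgrid(np.arange(chm.n_rows), np.arange(chm.n_cols),
                             indexing="ij")
    cx, cy = chm.index_to_world(rows.ravel(), cols.ravel())
    dem_z = dem.sample(cx, cy).reshape(chm.values.shape)
    chm.values[:] = np.maximum(np.nan_to_num(chm.values - dem_z, nan=0.0), 0.0)
    return chm


def normalize_heights(cloud: PointCloud, dem: RasterGrid) -> PointCloud:
    """Subtract the interpolated ground elevation from every point's z."""
    dem_z = dem.sample(cloud.x, cloud.y)
    dem_z = np.nan_to_num(dem_z, nan=0.0)
    pts = cloud.points.copy()
    pts[:, 2] = pts[:, 2] - dem_z
    return PointCloud(pts, cloud.labels.copy(), cloud.source,
                      cloud.nominal_density)


def detect_high_vegetation(normalized_z, params: VegetationParams
                           ) -> np.ndarray:
    """Boolean mask of heights within [lower, upper], bounds inclusive.

    Accepts a normalised cloud's z array or a CHM's value array.
    """
    z = np.asarray(normalized_z, dtype=float)
    return (z >= params.lower_height) & (z <= params.upper_height)
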