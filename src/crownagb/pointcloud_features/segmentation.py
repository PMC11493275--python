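"""Individual-crown segmentation on a canopy height raster.

Marker-controlled watershed: the CHM is pit-filled (3x3 median),
Gaussian-smoothed, local maxima above the vegetation floor become
markers, and the inverted smoothed surface is flooded within the
vegetation mask.  Crown radius is the radius of the circle with the
segment's footprint area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from ..core import PointCloud, RasterGrid

__all__ = ["SegmentationParams", "CrownSegment", "equivalent_radius",
           "segment_crowns", "extract_tree_height"]


@dataclass
class SegmentationParams:
    """Knobs for CHM smoothing, treetop detection and region filtering."""

    chm_cell_size: float = 0.25
    chm_smoothing_sigma: float = 1.0  # cells
    local_max_min_distance: float = 2.0  # metres between treetops
    trunk_step: float = 2.0
    growth_step: float = 1.0
    min_points_per_object: int = 20
    veg_lower: float = 2.0  # metres; vegetation floor for markers/mask

    def __post_init__(self) -> None:
        if self.chm_cell_size <= 0:
            raise ValueError("chm_cell_size must be > 0")
        if self.min_points_per_object < 1:
            raise ValueError("min_points_per_object must be >= 1")


@dataclass
class CrownSegment:
    """One delineated crown with its footprint statistics."""

    segment_id: int
    cells: np.ndarray  # (k, 2) row/col indices into the CHM
    apex_xy: tuple
    crown_area: float
    equivalent_radius: float
    max_normalized_z: float
    n_support: int = 0


def equivalent_radius(area: float) -> float:
    """Radius of the circle whose area equals ``area``."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return math.sqrt(area / math.pi)


def segment_crowns(chm: RasterGrid, params: SegmentationParams = None,
                   cloud: Optional[PointCloud] = None
                   ) -> List[CrownSegment]:
    """Delineate crowns on a CHM; optionally count supporting cloud points.

    Segments with fewer than ``min_points_per_object`` supports (cloud
    points when a normalised cloud is supplied, cells otherwise) are
    discarded.  Returns an empty list for a CHM with no vegetation cells.
    """
    params = params or SegmentationParams()
    values = chm.values
    veg_mask = values >= params.veg_lower
    if not veg_mask.any():
        return []

    # Pit-fill then smooth; raw values keep exact apex heights.
    filled = np.maximum(values, ndimage.median_filter(values, size=3))
    smoothed = ndimage.gaussian_filter(filled, sigma=params.chm_smoothing_sigma)

    min_dist_cells = max(1, int(round(params.local_max_min_distance
                                      / chm.cell_size)))
    peaks = peak_local_max(smoothed, min_distance=min_dist_cells,
                           threshold_abs=params.veg_lower,
                           exclude_border=False, labels=veg_mask)
    if len(peaks) == 0:
        return []
    markers = np.zeros(values.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    label_img = watershed(-smoothed, markers=markers, mask=veg_mask)

    support_counts = None
    if cloud is not None:
        row, col = chm.world_to_index(cloud.x, cloud.y)
        ok = ((row >= 0) & (row < chm.n_rows)
              & (col >= 0) & (col < chm.n_cols))
        pt_labels = np.zeros(len(cloud), dtype=np.int32)
        pt_labels[ok] = label_img[row[ok], col[ok]]
        support_counts = np.bincount(pt_labels, minlength=len(peaks) + 1)

    segments: List[CrownSegment] = []
    seg_id = 0
    cell_area = chm.cell_size ** 2
    for lab in range(1, len(peaks) + 1):
        cells = np.argwhere(label_img == lab)
        if len(cells) == 0:
            continue
        n_support = (int(support_counts[lab]) if support_counts is not None
                     else len(cells))
        if n_support < params.min_points_per_object:
            continue
        zvals = values[cells[:, 0], cells[:, 1]]
        apex_cell = cells[np.argmax(zvals)]
        ax, ay = chm.index_to_world(int(apex_cell[0]), int(apex_cell[1]))
        area = len(cells) * cell_area
        seg_id += 1
        segments.append(CrownSegment(
            segment_id=seg_id, cells=cells, apex_xy=(float(ax), float(ay)),
            crown_area=area, equivalent_radius=equivalent_radius(area),
            max_normalized_z=float(zvals.max()), n_support=n_support))
    return segments


def extract_tree_height(segment: CrownSegment, chm: RasterGrid) -> float:
    """Tree height: maximum normalised height over the crown footprint."""
    z = chm.values[segment.cells[:, 0], segment.cells[:, 1]]
    h = float(np.max(z))
    if h <= 0:
        raise ValueError("segment has no positive canopy height")
    return h
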