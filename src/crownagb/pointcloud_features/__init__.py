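"""Per-tree feature extraction from ALS / TLS point clouds.

The stages mirror a standard LiDAR forest-inventory chain: progressive
TIN ground filtering, DEM/CHM rasterisation, tall-vegetation masking,
marker-controlled watershed crown segmentation, and (for TLS) circle
fitting of the breast-height stem slice.
"""

from dataclasses import dataclass, field
from typing import List, Optional

from ..core import TreeRecord
from .dbh import DbhEstimate, circumcircle, estimate_dbh, fit_circle
from .ground import DegenerateCloudError, GroundFilterParams, filter_ground
from .raster import (VegetationParams, build_chm, build_dem,
                     detect_high_vegetation, normalize_heights)
from .segmentation import (CrownSegment, SegmentationParams,
                           equivalent_radius, extract_tree_height,
                           segment_crowns)

__all__ = [
    "GroundFilterParams", "VegetationParams", "SegmentationParams",
    "ExtractionParams", "ALS_DEFAULTS", "TLS_DEFAULTS",
    "DegenerateCloudError", "CrownSegment", "DbhEstimate",
    "filter_ground", "build_dem", "build_chm", "normalize_heights",
    "detect_high_vegetation", "segment_crowns", "extract_tree_height",
    "equivalent_radius", "estimate_dbh", "fit_circle", "circumcircle",
    "extract_trees",
]


@dataclass
class ExtractionParams:
    """Bundle of the per-stage parameters for one scanning mode."""

    ground: GroundFilterParams = field(default_factory=GroundFilterParams)
    vegetation: VegetationParams = field(default_factory=VegetationParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    dem_cell_size: float = 0.5


def ALS_DEFAULTS() -> ExtractionParams:
    return ExtractionParams(
        ground=GroundFilterParams(60.0, 6.0, 0.6),
        vegetation=VegetationParams(2.0, 80.0),
        segmentation=SegmentationParams(
            chm_cell_size=0.25, local_max_min_distance=2.0, trunk_step=2.0,
            growth_step=1.0, min_points_per_object=20, veg_lower=2.0),
        dem_cell_size=0.5)


def TLS_DEFAULTS() -> ExtractionParams:
    return ExtractionParams(
        ground=GroundFilterParams(60.0, 6.0, 0.6),
        vegetation=VegetationParams(0.2, 50.0),
        segmentation=SegmentationParams(
            chm_cell_size=0.10, local_max_min_distance=0.15, trunk_step=0.15,
            growth_step=0.5, min_points_per_object=40, veg_lower=0.2),
        dem_cell_size=0.5)


def extract_trees(cloud, params: Optional[ExtractionParams] = None,
                  mode: str = "ALS", plot_id: int = 0,
                  with_dbh: bool = None) -> List[TreeRecord]:
    """Full chain: cloud in, per-tree records out.

    H and R come from the CHM segmentation; DBH (TLS mode, or
    ``with_dbh=True``) from circle fitting at each segment's apex.
    Trees without a recoverable DBH carry ``DBH = NaN``.
    """
    import math

    if params is None:
        params = TLS_DEFAULTS() if mode.upper() == "TLS" else ALS_DEFAULTS()
    if with_dbh is None:
        with_dbh = mode.upper() == "TLS"

    classified = filter_ground(cloud, params.ground)
    dem = build_dem(classified, params.dem_cell_size)
    norm = normalize_heights(classified, dem)
    chm = build_chm(classified, dem, params.segmentation.chm_cell_size)
    veg = norm.subset(detect_high_vegetation(norm.z, params.vegetation))
    segments = segment_crowns(chm, params.segmentation, cloud=veg)

    trees: List[TreeRecord] = []
    for seg in segments:
        h = extract_tree_height(seg, chm)
        dbh = math.nan
        if with_dbh:
            est = estimate_dbh(norm, seg.apex_xy)
            if est is not None:
                dbh = est.dbh_cm
        trees.append(TreeRecord(
            tree_id=seg.segment_id, plot_id=plot_id, species="unknown",
            x=seg.apex_xy[0], y=seg.apex_xy[1], H=h, DBH=dbh,
            R=seg.equivalent_radius, source=mode.upper()))
    return trees
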