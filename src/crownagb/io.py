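"""Readers and writers for the pipeline's table, cloud and raster formats.

Tree tables travel as CSV with the schema
``tree_id,plot_id,species,x,y,H_m,DBH_cm,R_m[,W_ref_kg,source]``;
spreadsheet input (.xlsx) is supported through a column-mapping dict.
Point clouds are plain XYZ text (``x y z [class]``); rasters are
single-band float TIFF with NaN nodata.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import PointCloud, RasterGrid, TreeRecord

TREE_COLUMNS = ["tree_id", "plot_id", "species", "x", "y",
                "H_m", "DBH_cm", "R_m"]


def trees_to_dataframe(trees: Sequence[TreeRecord]) -> pd.DataFrame:
    rows = [{
        "tree_id": t.tree_id, "plot_id": t.plot_id, "species": t.species,
        "x": t.x, "y": t.y, "H_m": t.H, "DBH_cm": t.DBH, "R_m": t.R,
        "W_ref_kg": np.nan if t.W_ref is None else t.W_ref,
        "source": t.source,
    } for t in trees]
    return pd.DataFrame(rows, columns=TREE_COLUMNS + ["W_ref_kg", "source"])


def dataframe_to_trees(df: pd.DataFrame) -> List[TreeRecord]:
    trees = []
    for _, row in df.iterrows():
        w = row.get("W_ref_kg")
        trees.append(TreeRecord(
            tree_id=int(row["tree_id"]), plot_id=int(row["plot_id"]),
            species=str(row["species"]), x=float(row["x"]), y=float(row["y"]),
            H=float(row["H_m"]), DBH=float(row["DBH_cm"]), R=float(row["R_m"]),
            W_ref=None if w is None or pd.isna(w) else float(w),
            source=str(row.get("source", "synthetic"))))
    return trees


def write_tree_csv(trees, path) -> None:
    df = trees if isinstance(trees, pd.DataFrame) else trees_to_dataframe(trees)
    df.to_csv(path, index=False)


def load_trees(path, column_map: Optional[Dict[str, str]] = None
               ) -> pd.DataFrame:
    """Load a tree table from CSV or XLSX, renaming via ``column_map``
    (maps source column names to the canonical schema)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("plot_id", "species", "H_m", "DBH_cm", "R_m")
               if c not in df.columns]
    if missing:
        raise ValueError(f"tree table missing columns: {missing}")
    if "tree_id" not in df.columns:
        df["tree_id"] = np.arange(len(df))
    for c in ("x", "y"):
        if c not in df.columns:
            df[c] = np.nan
    return df


def write_xyz(cloud: PointCloud, path, with_labels: bool = True) -> None:
    """Plain-text cloud: ``x y z class`` per line."""
    if with_labels:
        data = np.column_stack([cloud.points, cloud.labels])
        fmt = ["%.4f", "%.4f", "%.4f", "%d"]
    else:
        data = cloud.points
        fmt = "%.4f"
    np.savetxt(path, data, fmt=fmt)


def read_xyz(path, source: str = "ALS") -> PointCloud:
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 3:
        raise ValueError("XYZ file needs at least 3 columns")
    labels = data[:, 3].astype(np.int32) if data.shape[1] >= 4 else None
    return PointCloud(points=data[:, :3], labels=labels, source=source)


def write_raster(grid: RasterGrid, path) -> None:
    """Single-band float32 TIFF; cell geometry in a sidecar-free tag set
    is out of scope — the origin/cell size travel in the JSON metadata."""
    import tifffile

    tifffile.imwrite(
        path, grid.values.astype(np.float32),
        metadata={"origin_x": grid.origin[0], "origin_y": grid.origin[1],
                  "cell_size": grid.cell_size})


def read_raster(path, origin=(0.0, 0.0), cell_size: float = 1.0
                ) -> RasterGrid:
    import tifffile

    values = tifffile.imread(path).astype(float)
    return RasterGrid(origin=tuple(origin), cell_size=cell_size,
                      values=values)
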