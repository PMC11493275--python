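# crownagb

Individual-tree above-ground biomass (AGB) estimation from LiDAR-derived
tree height (H) and crown radius (R), with a full synthetic test bed.

The package implements an end-to-end forest-inventory pipeline:

1. **`crownagb.synthetic_forest`** — generates tree populations for four
   reference plots (two conifer, two broadleaf) with coupled H / DBH / R
   attributes, and renders ALS/TLS-style point clouds (cone or ellipsoid
   crowns, trunk cylinders, ground returns) so every downstream stage is
   testable without field data.
2. **`crownagb.pointcloud_features`** — progressive TIN densification
   ground filtering, DEM/CHM rasterisation, tall-vegetation masking,
   marker-controlled watershed crown segmentation (per-tree H and
   equivalent-circle R), and least-squares circle fitting of the 1.3 m
   stem slice for DBH from TLS clouds.
3. **`crownagb.fusion`** — one-to-one optimal-assignment matching of ALS
   and TLS tree lists by trunk/apex proximity; fused records take H and R
   from ALS and DBH/position from TLS.
4. **`crownagb.allometry`** — species-group reference AGB
   (`W = a (DBH² H)^b`, DBH in cm, H in m, W in kg) and nine candidate
   H/R model forms (`Eq1`–`Eq9`: power, exponential, linear, logarithmic
   and quadratic families), fitted by closed-form OLS or nonlinear least
   squares, scored with R², RMSE and rRMSE.
5. **`crownagb.evaluation`** — seven plot-combination scenarios, 70/30
   train/test split, the full 7 × 9 fit matrix and report writers.

## CLI

```bash
# synthesize the default 4-plot forest (625 trees) and per-plot clouds
crownagb simulate --out-dir out/ --seed 1 --render --mode ALS --density 600

# extract per-tree features from an XYZ cloud
crownagb extract out/plot1_als.xyz --mode als --out out/als_trees.csv

# fuse ALS and TLS tree tables
crownagb fuse out/als_trees.csv out/tls_trees.csv --max-dist 1.0 --out out/fused.csv

# run the scenario x model evaluation matrix
crownagb evaluate --trees out/fused.csv --scenarios 1-7 --models Eq1-Eq9 \
    --seed 0 --out out/results
```

`evaluate` accepts CSV (schema
`tree_id,plot_id,species,x,y,H_m,DBH_cm,R_m[,W_ref_kg]`) or XLSX input;
see `crownagb.io.load_trees` for column mapping. Species must be one of
`larch`, `ash`, `sophora` (or the group name `broadleaf`).

## Layout

```
src/crownagb/
  core.py                 TreeRecord / PointCloud / RasterGrid containers
  synthetic_forest.py     population sampling + point-cloud rendering
  pointcloud_features/    ground, raster, segmentation, dbh stages
  fusion.py               ALS-TLS tree matching
  allometry.py            reference AGB, model forms, fitting, metrics
  evaluation.py           scenarios, splits, 7x9 matrix, reports
  io.py                   CSV / XLSX / XYZ / TIFF readers and writers
  cli.py                  typer CLI (simulate, extract, fuse, evaluate)
tests/                    pytest suite incl. acceptance criteria
scripts/acceptance.py     acceptance report generator
```
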