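#!/usr/bin/env python
"""Project the best fitted virulence model onto the monthly climate grids.

Evaluates the winning temperature-mortality expression in every grid
cell at each month's midpoint temperature, clips to [0, 1], averages the
12 months into an annual virulence surface, classifies it into the five
mortality bands, and writes .asc rasters plus a per-point summary for a
small set of demonstration occurrence points.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from thermovir import spatial, tpc_models
from thermovir.cli import load_model_config

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    params = load_model_config(ROOT / "best_model.txt")
    name = tpc_models.params_to_dict(params)["model"]
    evaluator = tpc_models.model_evaluator(name)

    sim = ROOT / "sim"
    stack = spatial.load_raster_stack(
        [sim / f"tmin_{m:02d}.asc" for m in range(1, 13)],
        [sim / f"tmax_{m:02d}.asc" for m in range(1, 13)],
    )
    vmap = spatial.project_virulence(stack, lambda t: evaluator(params, t))
    spatial.classify(vmap)

    out = ROOT / "maps"
    out.mkdir(parents=True, exist_ok=True)
    spatial.write_asc(vmap.values, out / "virulence_annual.asc")
    classes = spatial.RasterGrid(
        np.where(vmap.classes < 0, np.nan, vmap.classes.astype(float)),
        vmap.values.xllcorner, vmap.values.yllcorner, vmap.values.cellsize,
        nodata=vmap.values.nodata,
    )
    spatial.write_asc(classes, out / "virulence_classes.asc", fmt="%.0f")

    # a handful of demonstration release sites inside the synthetic extent
    grid = vmap.values
    lats = grid.yllcorner + grid.cellsize * np.array([1.5, 8.5, 15.5, 18.5])
    lons = grid.xllcorner + grid.cellsize * np.array([2.5, 5.5, 8.5, 3.5])
    pts = spatial.OccurrencePoints(lons, lats)
    tbl = spatial.overlay_points(vmap, pts)
    tbl.to_csv(out / "points_virulence.csv", index=False)

    vals = grid.values[~np.isnan(grid.values)]
    counts = {lbl: int((vmap.classes == i).sum())
              for i, lbl in enumerate(spatial.BAND_LABELS)}
    print(f"projected {name} model onto {vals.size} valid cells: "
          f"annual mortality {vals.min():.2f}-{vals.max():.2f} (mean {vals.mean():.2f})")
    print(f"band occupancy: {counts}")
    print(tbl[["lon", "lat", "value", "band_label"]].to_string(index=False))


if __name__ == "__main__":
    main()
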