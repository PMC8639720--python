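"""Spatial projection of a fitted temperature-virulence model onto climate grids.

A fitted temperature-to-mortality expression is evaluated per grid cell
of monthly minimum/maximum temperature rasters (WorldClim-style layout:
12 monthly t_min grids + 12 monthly t_max grids sharing one
geotransform).  Each month is evaluated at the midpoint
``(t_min + t_max)/2``, clipped to [0, 1], and the 12 monthly predictions
are averaged into an annual virulence surface, which can then be
classified into mortality bands and written out as ESRI ASCII grids for
GIS visualization.

Rasters are plain-text ESRI ASCII grids (.asc): a six-line
``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header over a
row-major value matrix, row 0 at the northern edge, cell-center
registration.  Coordinates are carried as an opaque CRS label (WGS84
assumed for WorldClim-style inputs); no reprojection is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "RasterGrid",
    "TemperatureRasterStack",
    "VirulenceMap",
    "OccurrencePoints",
    "read_asc",
    "write_asc",
    "load_raster_stack",
    "project_virulence",
    "classify",
    "overlay_points",
    "DEFAULT_BAND_EDGES",
    "BAND_LABELS",
]

# Mortality bands: very-low <16%, low 16-34%, low-moderate 34-45%,
# moderate 45-63%, high >=63% (half-open intervals, top band closed at 1).
DEFAULT_BAND_EDGES: tuple[float, ...] = (0.16, 0.34, 0.45, 0.63)
BAND_LABELS: tuple[str, ...] = ("very-low", "low", "low-moderate", "moderate", "high")


@dataclass
class RasterGrid:
    """A single grid with its geotransform; nodata cells are np.nan internally."""

    values: np.ndarray  # 2-D float array, nan = nodata
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0
    crs: str = "WGS84"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def geometry(self) -> tuple:
        return (self.shape, self.xllcorner, self.yllcorner, self.cellsize)

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol
            for a, b in zip(self.geometry()[1:], other.geometry()[1:])
        )


@dataclass
class TemperatureRasterStack:
    """12 monthly minimum + 12 monthly maximum temperature grids (degC)."""

    tmin: list
    tmax: list

    def __post_init__(self) -> None:
        if len(self.tmin) != 12 or len(self.tmax) != 12:
            raise ValueError("need 12 monthly t_min and 12 monthly t_max grids")
        ref = self.tmin[0]
        for g in [*self.tmin, *self.tmax]:
            if not ref.same_geometry(g):
                raise ValueError("all 24 grids must share shape and geotransform")
        for lo, hi in zip(self.tmin, self.tmax):
            both = ~np.isnan(lo.values) & ~np.isnan(hi.values)
            if (lo.values[both] > hi.values[both] + 1e-9).any():
                raise ValueError("t_min exceeds t_max in some cells")
        allvals = np.concatenate([g.values[~np.isnan(g.values)].ravel()
                                  for g in [*self.tmin, *self.tmax]])
        if allvals.size and (allvals.min() < -60 or allvals.max() > 60):
            warnings.warn("temperatures outside plausible [-60, 60] degC range")

    @property
    def grid(self) -> RasterGrid:
        return self.tmin[0]

    def monthly_means(self) -> np.ndarray:
        """(12, nrows, ncols) midpoint temperatures; nan where either input is nodata."""
        return np.stack([(lo.values + hi.values) / 2.0
                         for lo, hi in zip(self.tmin, self.tmax)])


@dataclass
class VirulenceMap:
    """Annual predicted-mortality surface (proportions in [0,1], nan = nodata)."""

    values: RasterGrid
    monthly: np.ndarray | None = None  # (12, nr, nc), clipped monthly predictions
    classes: np.ndarray | None = None  # int band index, -1 = nodata
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES


@dataclass
class OccurrencePoints:
    """Pest occurrence records as (longitude, latitude) degree pairs."""

    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.lon.shape != self.lat.shape:
            raise ValueError("lon and lat must align")
        if (np.abs(self.lon) > 180).any() or (np.abs(self.lat) > 90).any():
            raise ValueError("coordinates out of range")

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrencePoints":
        df = pd.read_csv(path)
        return cls(df["lon"].to_numpy(), df["lat"].to_numpy())


# --- ESRI ASCII grid I/O ---------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_asc(path: str | Path, crs: str = "WGS84") -> RasterGrid:
    """Read an ESRI ASCII grid; nodata cells become nan."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header line {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    values = np.where(values == nodata, np.nan, values)
    return RasterGrid(values, header["xllcorner"], header["yllcorner"],
                      header["cellsize"], nodata=nodata, crs=crs)


def write_asc(grid: RasterGrid, path: str | Path, fmt: str = "%.6f") -> Path:
    """Write a grid as an ESRI ASCII file; nan cells become the nodata sentinel."""
    path = Path(path)
    nr, nc = grid.shape
    out = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with path.open("w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, out, fmt=fmt)
    return path


def load_raster_stack(
    tmin_paths: Sequence[str | Path], tmax_paths: Sequence[str | Path]
) -> TemperatureRasterStack:
    """Load 12 + 12 monthly .asc files into a validated stack."""
    if len(tmin_paths) != 12 or len(tmax_paths) != 12:
        raise ValueError("expected 12 t_min and 12 t_max paths (months in order)")
    return TemperatureRasterStack(
        [read_asc(p) for p in tmin_paths], [read_asc(p) for p in tmax_paths]
    )


def project_virulence(
    stack: TemperatureRasterStack, model_fn: Callable[[np.ndarray], np.ndarray]
) -> VirulenceMap:
    """Apply a temperature-to-mortality expression cellwise and average the year.

    ``model_fn`` maps temperature arrays (degC) to predicted mortality on
    the proportion scale; predictions are clipped to [0, 1] here (the
    reporting layer) before the annual mean over the 12 months is taken.
    Nodata propagates: a cell missing in any month stays nodata.
    """
    means = stack.monthly_means()
    valid = ~np.isnan(means)
    monthly = np.full_like(means, np.nan)
    monthly[valid] = np.clip(np.asarray(model_fn(means[valid]), dtype=float), 0.0, 1.0)
    annual = np.where(valid.all(axis=0), monthly.mean(axis=0), np.nan)
    ref = stack.grid
    return VirulenceMap(
        values=RasterGrid(annual, ref.xllcorner, ref.yllcorner, ref.cellsize,
                          nodata=ref.nodata, crs=ref.crs),
        monthly=monthly,
    )


def classify(
    vmap: VirulenceMap, band_edges: Sequence[float] = DEFAULT_BAND_EDGES
) -> VirulenceMap:
    """Assign each valid cell a mortality band by half-open intervals.

    Bands are ``[0, e1), [e1, e2), ..., [ek, 1]`` (top band closed);
    nodata cells get class -1.  Returns the map with ``classes`` and
    ``band_edges`` filled in.
    """
    edges = [float(e) for e in band_edges]
    if any(x >= y for x, y in zip(edges, edges[1:])) or not edges:
        raise ValueError("band edges must be strictly increasing")
    if edges[0] <= 0 or edges[-1] >= 1:
        raise ValueError("band edges must lie strictly inside (0, 1)")
    vals = vmap.values.values
    cls = np.digitize(vals, edges, right=False)
    cls = np.where(np.isnan(vals), -1, cls).astype(int)
    vmap.classes = cls
    vmap.band_edges = tuple(edges)
    return vmap


def overlay_points(vmap: VirulenceMap, pts: OccurrencePoints) -> pd.DataFrame:
    """Nearest-cell lookup of map value/class for each occurrence point.

    Cell indices come straight from the geotransform
    (``col = floor((lon - xll)/cellsize)``, rows counted from the
    northern edge); points on a cell edge fall to the higher index by the
    floor convention, and points outside the extent are flagged with no
    value.
    """
    grid = vmap.values
    nr, nc = grid.shape
    col = np.floor((pts.lon - grid.xllcorner) / grid.cellsize).astype(int)
    row_from_south = np.floor((pts.lat - grid.yllcorner) / grid.cellsize).astype(int)
    row = nr - 1 - row_from_south
    inside = (col >= 0) & (col < nc) & (row >= 0) & (row < nr)
    value = np.full(len(pts.lon), np.nan)
    cls = np.full(len(pts.lon), -1)
    value[inside] = grid.values[row[inside], col[inside]]
    if vmap.classes is not None:
        cls[inside] = vmap.classes[row[inside], col[inside]]
    label = [
        BAND_LABELS[c] if 0 <= c < len(BAND_LABELS) else ""
        for c in cls
    ]
    return pd.DataFrame(
        {
            "lon": pts.lon, "lat": pts.lat, "inside_extent": inside,
            "row": np.where(inside, row, -1), "col": np.where(inside, col, -1),
            "value": value, "band": cls, "band_label": label,
        }
    )
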