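"""Plain-array distance rasters (ESRI ASCII grid text format).

Distance-to-feature covariates (distance to the river, distance to the
nearest household) are computed as planar Euclidean distance surfaces on
a regular grid (500 m cells by default) and sampled at station locations
by containing cell.  Rasters are serialized as ESRI ASCII grids, a plain
text format readable by any GIS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["DistanceRaster", "distance_raster", "sample_raster_at_stations",
           "write_ascii_grid", "read_ascii_grid"]


@dataclass
class DistanceRaster:
    """Regular grid of distances (metres) to the nearest feature.

    ``values[row, col]`` with row 0 at the *south* edge; the cell (0, 0)
    covers ``[xll, xll + cell_size) x [yll, yll + cell_size)``.
    """

    xll: float
    yll: float
    cell_size: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nrows, ncols = self.shape
        xs = self.xll + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.yll + (np.arange(nrows) + 0.5) * self.cell_size
        return xs, ys


def distance_raster(features, bbox, cell_size: float = 500.0) -> DistanceRaster:
    """Euclidean distance from every cell centre to the nearest feature.

    ``features`` is either an (n, 2) array of points or a shapely geometry
    (e.g. a LineString for a river); ``bbox`` is (xmin, ymin, xmax, ymax).
    """
    xmin, ymin, xmax, ymax = map(float, bbox)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("bbox must have positive extent")
    ncols = int(np.ceil((xmax - xmin) / cell_size))
    nrows = int(np.ceil((ymax - ymin) / cell_size))
    xs = xmin + (np.arange(ncols) + 0.5) * cell_size
    ys = ymin + (np.arange(nrows) + 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)  # (nrows, ncols)

    if hasattr(features, "geom_type"):  # shapely geometry
        import shapely

        if features.is_empty:
            raise ValueError("empty feature set")
        pts = shapely.points(gx.ravel(), gy.ravel())
        dist = shapely.distance(pts, features).reshape(nrows, ncols)
    else:
        pts = np.atleast_2d(np.asarray(features, dtype=float))
        if pts.size == 0:
            raise ValueError("empty feature set")
        if pts.shape[1] != 2:
            raise ValueError("features must be an (n, 2) array of points")
        tree = cKDTree(pts)
        dist, _ = tree.query(np.column_stack([gx.ravel(), gy.ravel()]))
        dist = dist.reshape(nrows, ncols)
    return DistanceRaster(xmin, ymin, cell_size, dist)


def _containing_cell(offset: np.ndarray, cell: float) -> np.ndarray:
    # Boundary coordinates belong to the lower-index cell; the lower bbox
    # edge itself belongs to cell 0.
    idx = np.ceil(offset / cell).astype(int) - 1
    return np.where((idx == -1) & (offset == 0.0), 0, idx)


def sample_raster_at_stations(raster: DistanceRaster, stations) -> np.ndarray:
    """Raster value of the cell containing each station (no interpolation).

    A station exactly on a cell edge is assigned to the lower-index cell.
    Raises, naming the station, if any station falls outside the grid.
    """
    ids = [getattr(s, "station_id", str(k)) for k, s in enumerate(stations)]
    xy = np.array([(s.x, s.y) for s in stations], dtype=float)
    nrows, ncols = raster.shape
    col = _containing_cell(xy[:, 0] - raster.xll, raster.cell_size)
    row = _containing_cell(xy[:, 1] - raster.yll, raster.cell_size)
    bad = (col < 0) | (col >= ncols) | (row < 0) | (row >= nrows)
    if bad.any():
        names = [ids[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"station(s) outside raster bounds: {names}")
    return raster.values[row, col]


def write_ascii_grid(raster: DistanceRaster, path, nodata: float = -9999.0) -> None:
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xll}\n")
        fh.write(f"yllcorner {raster.yll}\n")
        fh.write(f"cellsize {raster.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for r in range(nrows - 1, -1, -1):  # north row first, per format
            fh.write(" ".join(f"{v:.6g}" for v in raster.values[r]) + "\n")


def read_ascii_grid(path) -> DistanceRaster:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1]  # back to south-row-first
    return DistanceRaster(header["xllcorner"], header["yllcorner"],
                          header["cellsize"], vals)
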