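"""Georeferenced raster grids and plain-text (ESRI ASCII) raster I/O.

Rasters are stored row-major with row 0 at the northern edge, matching the
on-disk layout of the ESRI ASCII grid format.  Values are floats; nodata
cells are represented internally as NaN.  Coordinates are WGS84 decimal
degrees throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class RasterGrid:
    """A rectangular grid of cell values anchored at its lower-left corner.

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row.  NaN marks nodata.
    cellsize
        Cell edge length in decimal degrees (square cells).
    xllcorner, yllcorner
        Longitude / latitude of the lower-left corner of the grid.
    crs
        Free-text coordinate-reference label (informational).
    """

    values: np.ndarray
    cellsize: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    crs: str = "EPSG:4326"
    nodata: float = field(default=-9999.0, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def x_centers(self) -> np.ndarray:
        """Longitudes of cell centers, west to east."""
        return self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """Latitudes of cell centers ordered as the rows are (north to south)."""
        return self.yllcorner + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; raises if off-grid."""
        col = int(np.floor((lon - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yllcorner) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({lon}, {lat}) falls outside the raster extent")
        return row, col

    def crop(self, lon_min: float, lat_min: float, lon_max: float, lat_max: float) -> "RasterGrid":
        """Sub-grid covering the bounding box (clipped to the raster extent)."""
        c0 = max(0, int(np.floor((lon_min - self.xllcorner) / self.cellsize)))
        c1 = min(self.ncols, int(np.ceil((lon_max - self.xllcorner) / self.cellsize)))
        rb0 = max(0, int(np.floor((lat_min - self.yllcorner) / self.cellsize)))
        rb1 = min(self.nrows, int(np.ceil((lat_max - self.yllcorner) / self.cellsize)))
        r0 = self.nrows - rb1
        r1 = self.nrows - rb0
        if r0 >= r1 or c0 >= c1:
            raise ValueError("crop window does not intersect the raster")
        return RasterGrid(
            values=self.values[r0:r1, c0:c1].copy(),
            cellsize=self.cellsize,
            xllcorner=self.xllcorner + c0 * self.cellsize,
            yllcorner=self.yllcorner + rb0 * self.cellsize,
            crs=self.crs,
            nodata=self.nodata,
        )

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.values.copy(), self.cellsize, self.xllcorner,
                          self.yllcorner, self.crs, self.nodata)


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc) file."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII grid missing header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match the declared dimensions")
    data[data == nodata] = np.nan
    return RasterGrid(
        values=data,
        cellsize=header["cellsize"],
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        nodata=nodata,
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc) file; NaN becomes the nodata marker."""
    body = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, body, fmt="%.8g")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
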