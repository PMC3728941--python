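"""A minimal regular lon/lat raster with bilinear sampling and ASCII-grid I/O.

Rasters are stored south-up (row 0 = southernmost row) with square cells in
degrees. Serialization uses the plain-text ESRI ASCII grid format, which any
GIS can read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Raster:
    """Regular lon/lat grid of values.

    ``lon0``/``lat0`` are the coordinates of the *lower-left cell corner*;
    ``cell`` is the cell size in degrees (square cells). ``values`` has shape
    ``(nrows, ncols)`` with row 0 at the south edge.
    """

    lon0: float
    lat0: float
    cell: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self):
        return self.values.shape

    @property
    def bounds(self):
        ny, nx = self.values.shape
        return (self.lon0, self.lat0, self.lon0 + nx * self.cell, self.lat0 + ny * self.cell)

    def cell_centers(self):
        ny, nx = self.values.shape
        lons = self.lon0 + (np.arange(nx) + 0.5) * self.cell
        lats = self.lat0 + (np.arange(ny) + 0.5) * self.cell
        return lons, lats

    def sample(self, lon, lat, method: str = "bilinear"):
        """Sample values at lon/lat points; NaN outside coverage."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        scalar = lon.ndim == 0
        lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
        ny, nx = self.values.shape
        # fractional index relative to cell centers
        fx = (lon - self.lon0) / self.cell - 0.5
        fy = (lat - self.lat0) / self.cell - 0.5
        out = np.full(lon.shape, np.nan)
        if method == "nearest":
            ix = np.rint(fx).astype(int)
            iy = np.rint(fy).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            out[ok] = self.values[iy[ok], ix[ok]]
        elif method == "bilinear":
            x0 = np.floor(fx).astype(int)
            y0 = np.floor(fy).astype(int)
            # clamp so edge points (within the outer half-cell) still sample
            inside = (fx >= -0.5) & (fx <= nx - 0.5) & (fy >= -0.5) & (fy <= ny - 0.5)
            x0c = np.clip(x0, 0, nx - 2)
            y0c = np.clip(y0, 0, ny - 2)
            tx = np.clip(fx - x0c, 0.0, 1.0)
            ty = np.clip(fy - y0c, 0.0, 1.0)
            v00 = self.values[y0c, x0c]
            v01 = self.values[y0c, x0c + 1]
            v10 = self.values[y0c + 1, x0c]
            v11 = self.values[y0c + 1, x0c + 1]
            val = (v00 * (1 - tx) * (1 - ty) + v01 * tx * (1 - ty)
                   + v10 * (1 - tx) * ty + v11 * tx * ty)
            out[inside] = val[inside]
        else:
            raise ValueError(f"unknown sampling method {method!r}")
        return float(out[0]) if scalar else out

    def to_ascii(self, path, nodata: float = -9999.0) -> None:
        ny, nx = self.values.shape
        vals = np.where(np.isfinite(self.values), self.values, nodata)
        with open(path, "w") as fh:
            fh.write(f"NCOLS {nx}\nNROWS {ny}\n")
            fh.write(f"XLLCORNER {self.lon0:.10f}\nYLLCORNER {self.lat0:.10f}\n")
            fh.write(f"CELLSIZE {self.cell:.10f}\nNODATA_VALUE {nodata}\n")
            # ESRI ASCII rows run north -> south
            np.savetxt(fh, vals[::-1], fmt="%.6g")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        header = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.upper()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)[::-1].copy()
        nodata = header.get("NODATA_VALUE", -9999.0)
        vals[vals == nodata] = np.nan
        return cls(lon0=header["XLLCORNER"], lat0=header["YLLCORNER"],
                   cell=header["CELLSIZE"], values=vals)
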