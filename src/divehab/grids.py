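"""Raster grids, great-circle geometry and the local map projection.

Rasters are plain latitude/longitude grids (WGS84 decimal degrees) with
0-based, cell-centre indexing and row 0 at the southern edge.  Files are
read and written as ESRI ASCII grids (``.asc``) — a plain-text raster
format that keeps every artifact human-readable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: kilometres per degree of latitude on the spherical Earth
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEG",
    "Grid",
    "EnvStack",
    "haversine_km",
    "AzimuthalEquidistant",
    "slope_degrees",
    "read_ascii_grid",
    "write_ascii_grid",
]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class AzimuthalEquidistant:
    """Azimuthal-equidistant projection about a reference point.

    Distances from the centre are preserved exactly, which is the property
    that matters for a central-place forager whose space use is organised
    around its colony.  Coordinates are in kilometres.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._sin0 = np.sin(np.radians(lat0))
        self._cos0 = np.cos(np.radians(lat0))

    def forward(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        dlon = lon - np.radians(self.lon0)
        cos_c = self._sin0 * np.sin(lat) + self._cos0 * np.cos(lat) * np.cos(dlon)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), with the removable singularity at the centre
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlon)
        y = EARTH_RADIUS_KM * k * (self._cos0 * np.sin(lat) - self._sin0 * np.cos(lat) * np.cos(dlon))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        c = np.hypot(x, y)
        safe_c = np.where(c > 1e-12, c, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        lat = np.arcsin(np.clip(cos_c * self._sin0 + y * sin_c * self._cos0 / safe_c, -1.0, 1.0))
        lon = np.radians(self.lon0) + np.arctan2(
            x * sin_c, safe_c * self._cos0 * cos_c - y * self._sin0 * sin_c
        )
        lat = np.where(c > 1e-12, lat, np.radians(self.lat0))
        lon = np.where(c > 1e-12, lon, np.radians(self.lon0))
        return np.degrees(lon), np.degrees(lat)


@dataclass
class Grid:
    """A lat/lon raster: south-west corner, square cell size in degrees, data.

    ``data[i, j]`` is the cell whose centre is at
    ``(lon0 + (j + 0.5) * cell, lat0 + (i + 0.5) * cell)`` — row 0 south.
    """

    lon0: float
    lat0: float
    cell: float
    data: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.data.ndim != 2:
            raise ValueError("grid data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def lon_max(self) -> float:
        return self.lon0 + self.shape[1] * self.cell

    @property
    def lat_max(self) -> float:
        return self.lat0 + self.shape[0] * self.cell

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon2d, lat2d) arrays of cell-centre coordinates."""
        lons = self.lon0 + (np.arange(self.shape[1]) + 0.5) * self.cell
        lats = self.lat0 + (np.arange(self.shape[0]) + 0.5) * self.cell
        return np.meshgrid(lons, lats)

    def index_of(self, lon, lat):
        """Row/col of the cell containing each point; -1 where outside."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        j = np.floor((lon - self.lon0) / self.cell).astype(int)
        i = np.floor((lat - self.lat0) / self.cell).astype(int)
        ok = (j >= 0) & (j < self.shape[1]) & (i >= 0) & (i < self.shape[0])
        return np.where(ok, i, -1), np.where(ok, j, -1)

    def value_at(self, lon, lat, fill=np.nan):
        i, j = self.index_of(lon, lat)
        out = np.full(np.shape(i), fill, dtype=float)
        ok = i >= 0
        out[ok] = self.data[i[ok], j[ok]]
        return out

    def like(self, data: np.ndarray) -> "Grid":
        if data.shape != self.shape:
            raise ValueError("shape mismatch")
        return Grid(self.lon0, self.lat0, self.cell, data, self.nodata)


def slope_degrees(bathy: Grid) -> Grid:
    """Seafloor slope (degrees) from a positive-down bathymetry grid.

    Central finite differences with metric spacing: one degree of latitude
    is ~111.2 km everywhere, one degree of longitude shrinks with cos(lat).
    Interior cells of a planar ramp with gradient g per metre therefore
    return atan(g) exactly.
    """
    if min(bathy.shape) < 2:
        raise ValueError("slope needs at least a 2x2 grid")
    dy_m = bathy.cell * KM_PER_DEG * 1000.0
    lats = bathy.lat0 + (np.arange(bathy.shape[0]) + 0.5) * bathy.cell
    dx_m = dy_m * np.cos(np.radians(lats))[:, None]
    dz_di, dz_dj = np.gradient(bathy.data.astype(float))
    grad = np.hypot(dz_di / dy_m, dz_dj / dx_m)
    return bathy.like(np.degrees(np.arctan(grad)))


@dataclass
class EnvStack:
    """Static environmental layers plus a daily SST stack on one grid.

    bathy: depth in metres, positive down.  slope: degrees.  sea: boolean
    mask (True = water).  sst: one °C layer per calendar day.
    """

    bathy: Grid
    slope: Grid
    sea: Grid
    sst: dict[dt.date, Grid] = field(default_factory=dict)

    @property
    def dates(self) -> list[dt.date]:
        return sorted(self.sst)

    @property
    def grid(self) -> Grid:
        return self.bathy

    def sst_on(self, date: dt.date) -> Grid:
        """SST layer for ``date``; nearest available day if absent."""
        if date in self.sst:
            return self.sst[date]
        if not self.sst:
            raise KeyError("environment has no SST layers")
        nearest = min(self.dates, key=lambda d: abs((d - date).days))
        return self.sst[nearest]

    def sea_mask(self) -> np.ndarray:
        return self.sea.data.astype(bool)


def write_ascii_grid(path, grid: Grid) -> None:
    """Write a grid as an ESRI ASCII raster (top row first on disk)."""
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        f"xllcorner {grid.lon0!r}\n"
        f"yllcorner {grid.lat0!r}\n"
        f"cellsize {grid.cell!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    body = np.where(np.isfinite(grid.data), grid.data, grid.nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body[::-1], fmt="%.10g")


def read_ascii_grid(path) -> Grid:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    nodata = hdr.get("nodata_value", -9999.0)
    data[data == nodata] = np.nan
    return Grid(hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"], data, nodata)
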