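"""Kernel utilization distributions of dive locations.

Dive locations are projected to an azimuthal-equidistant plane centred
on the colony (distances from the central place are preserved) and
smoothed with an isotropic bivariate Gaussian kernel of bandwidth h on a
regular km grid.  The p% isopleth is the smallest set of highest-density
cells holding p of the probability mass: the 50% isopleth delineates
core areas, the 95% isopleth the range.

The smoothing scale follows the conservative central-place rule
h = 2 x ln(mean foraging range in km), where the foraging range of a
trip is its maximum great-circle distance from the colony.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .grids import AzimuthalEquidistant, haversine_km

__all__ = ["UDGrid", "foraging_range", "smoothing_scale", "kde_ud", "isopleth",
           "isopleth_mass", "isopleth_geojson"]


@dataclass
class UDGrid:
    """Kernel density surface on a projected km grid (row 0 = south)."""

    x0: float  # west edge, km in the projected plane
    y0: float  # south edge, km
    cell_km: float
    density: np.ndarray  # per-km^2, integrates to 1
    h_km: float
    projection: AzimuthalEquidistant

    @property
    def cell_area(self) -> float:
        return self.cell_km ** 2

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.density.shape[1]) + 0.5) * self.cell_km
        ys = self.y0 + (np.arange(self.density.shape[0]) + 0.5) * self.cell_km
        return np.meshgrid(xs, ys)


def foraging_range(fixes: pd.DataFrame, colony: tuple[float, float],
                   trip_col: str = "trip_id") -> float:
    """Mean over trips of the maximum great-circle distance (km) from the
    colony reached on that trip."""
    if fixes.empty:
        raise ValueError("no fixes")
    d = haversine_km(colony[0], colony[1], fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    per_trip = pd.Series(d).groupby(fixes[trip_col].to_numpy()).max()
    return float(per_trip.mean())


def smoothing_scale(mean_range_km: float, base: float = math.e) -> float:
    """Kernel bandwidth h = 2 x log(mean foraging range).

    Natural log by default (a ~55 km mean range gives the canonical
    h = 8 km); the base is configurable.
    """
    if mean_range_km <= 1.0:
        raise ValueError("mean foraging range must exceed 1 km (log must be positive)")
    return 2.0 * math.log(mean_range_km) / math.log(base)


def kde_ud(lon, lat, colony: tuple[float, float], h_km: float,
           cell_km: float = 1.0, pad_factor: float = 3.0) -> UDGrid:
    """Gaussian-kernel utilization distribution of points.

    Points are projected about the colony, binned on a ``cell_km`` grid
    padded ``pad_factor x h`` beyond the point extent, and convolved with
    an isotropic Gaussian of sd ``h_km`` on both axes.  The surface is
    normalised to unit mass.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.size == 0:
        raise ValueError("need at least one point")
    if h_km <= 0:
        raise ValueError("bandwidth must be positive")
    proj = AzimuthalEquidistant(*colony)
    x, y = proj.forward(lon, lat)
    pad = pad_factor * h_km
    x0 = math.floor((x.min() - pad) / cell_km) * cell_km
    y0 = math.floor((y.min() - pad) / cell_km) * cell_km
    nx = int(math.ceil((x.max() + pad - x0) / cell_km)) + 1
    ny = int(math.ceil((y.max() + pad - y0) / cell_km)) + 1
    counts = np.zeros((ny, nx))
    j = ((x - x0) / cell_km).astype(int)
    i = ((y - y0) / cell_km).astype(int)
    np.add.at(counts, (i, j), 1.0)
    dens = ndimage.gaussian_filter(counts, sigma=h_km / cell_km, mode="constant", truncate=6.0)
    dens /= dens.sum() * cell_km ** 2
    return UDGrid(x0, y0, cell_km, dens, h_km, proj)


def isopleth(ud: UDGrid, p: float) -> np.ndarray:
    """Boolean mask of the smallest set of highest-density cells whose
    probability mass reaches ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    flat = ud.density.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    cum = np.cumsum(flat[order]) * ud.cell_area
    k = int(np.searchsorted(cum, p)) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.density.shape)


def isopleth_mass(ud: UDGrid, mask: np.ndarray) -> float:
    return float(ud.density[mask].sum() * ud.cell_area)


def isopleth_geojson(ud: UDGrid, levels=(0.5, 0.95)) -> dict:
    """Isopleth outlines as a GeoJSON FeatureCollection (lon/lat, WGS84).

    Contours are traced by marching squares at each level's density
    threshold and unprojected back to geographic coordinates.
    """
    features = []
    for p in levels:
        mask = isopleth(ud, p)
        thresh = ud.density[mask].min()
        rings = []
        for contour in measure.find_contours(ud.density, thresh):
            xs = ud.x0 + (contour[:, 1] + 0.5) * ud.cell_km
            ys = ud.y0 + (contour[:, 0] + 0.5) * ud.cell_km
            lon, lat = ud.projection.inverse(xs, ys)
            rings.append([[float(a), float(b)] for a, b in zip(lon, lat)])
        features.append({
            "type": "Feature",
            "properties": {"level": p, "h_km": ud.h_km},
            "geometry": {"type": "MultiLineString", "coordinates": rings},
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path, collection: dict) -> None:
    with open(path, "w") as fh:
        json.dump(collection, fh)
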