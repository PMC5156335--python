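"""Kernel density surfaces and occupancy contours in an equal-area projection.

The utilization distribution is estimated with a quartic (biweight) kernel
of compact support equal to the 200 km search radius, on a 10 km grid, in
a spherical Albers equal-area conic projection fitted to the point set
(named presets for South America and Africa are provided). Occupancy
contours are highest-density regions: the p% contour encloses the
smallest-volume set of cells capturing at least p% of the surface volume.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union

from .types import norm_lon

EARTH_RADIUS_KM = 6371.0


@dataclass
class AlbersEqualArea:
    """Spherical Albers equal-area conic projection (Snyder 1987, ch. 14).

    Coordinates are in km. ``lat1``/``lat2`` are the standard parallels,
    (``lat0``, ``lon0``) the origin.
    """

    lat0: float
    lon0: float
    lat1: float
    lat2: float
    radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self):
        p1, p2 = math.radians(self.lat1), math.radians(self.lat2)
        self._n = (math.sin(p1) + math.sin(p2)) / 2.0
        if abs(self._n) < 1e-9:
            raise ValueError("standard parallels symmetric about the equator are degenerate")
        self._C = math.cos(p1) ** 2 + 2.0 * self._n * math.sin(p1)
        self._rho0 = self._rho(math.radians(self.lat0))

    def _rho(self, phi_rad):
        return self.radius_km * np.sqrt(np.maximum(self._C - 2.0 * self._n * np.sin(phi_rad), 0.0)) / self._n

    def forward(self, lat, lon):
        """(lat, lon) degrees -> (x, y) km."""
        phi = np.radians(np.asarray(lat, dtype=float))
        lam = np.radians(norm_lon(np.asarray(lon, dtype=float) - self.lon0))
        rho = self._rho(phi)
        theta = self._n * lam
        return rho * np.sin(theta), self._rho0 - rho * np.cos(theta)

    def inverse(self, x, y):
        """(x, y) km -> (lat, lon) degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        sgn = np.sign(self._n)
        rho = np.hypot(x, self._rho0 - y) * sgn
        theta = np.arctan2(sgn * x, sgn * (self._rho0 - y))
        s = (self._C - (rho * self._n / self.radius_km) ** 2) / (2.0 * self._n)
        lat = np.degrees(np.arcsin(np.clip(s, -1.0, 1.0)))
        lon = norm_lon(self.lon0 + np.degrees(theta / self._n))
        return lat, lon

    def to_dict(self) -> dict:
        return {
            "lat0": self.lat0,
            "lon0": self.lon0,
            "lat1": self.lat1,
            "lat2": self.lat2,
            "radius_km": self.radius_km,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlbersEqualArea":
        return cls(**d)


#: Conventional continental presets (parameters of the standard
#: South America and Africa Albers equal-area conic definitions).
SOUTH_AMERICA_ALBERS = AlbersEqualArea(lat0=-32.0, lon0=-60.0, lat1=-5.0, lat2=-42.0)
AFRICA_ALBERS = AlbersEqualArea(lat0=0.0, lon0=25.0, lat1=20.0, lat2=-23.0)
PRESETS = {"south-america": SOUTH_AMERICA_ALBERS, "africa": AFRICA_ALBERS}


def to_equal_area(
    lats: Sequence[float], lons: Sequence[float], preset: Optional[str] = None
) -> tuple[np.ndarray, np.ndarray, AlbersEqualArea]:
    """Project points into an Albers equal-area conic fitted to them.

    With ``preset`` in {'south-america', 'africa'} the corresponding
    continental projection is used; otherwise the cone is centred on the
    point set with standard parallels at the 1/6 and 5/6 latitude
    quantiles. Points spanning more than 160 deg of longitude are rejected
    (split per basin first).
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if len(lats) < 1:
        raise ValueError("need at least one point")
    ref = float(np.median(lons))
    unwrapped = ref + np.array([((l - ref + 180.0) % 360.0) - 180.0 for l in lons])
    if np.ptp(unwrapped) > 160.0:
        raise ValueError("points span more than 160 deg of longitude; split per basin")
    if preset is not None:
        proj = PRESETS[preset]
    else:
        lat1, lat2 = np.quantile(lats, [1.0 / 6.0, 5.0 / 6.0])
        if abs(lat2 - lat1) < 1.0:  # nearly coincident parallels: widen the cone
            mid = (lat1 + lat2) / 2.0
            lat1, lat2 = mid - 1.0, mid + 1.0
        if abs(math.sin(math.radians(lat1)) + math.sin(math.radians(lat2))) < 1e-6:
            lat2 += 1.0
        proj = AlbersEqualArea(
            lat0=float(np.mean(lats)), lon0=float(norm_lon(np.mean(unwrapped))),
            lat1=float(lat1), lat2=float(lat2),
        )
    x, y = proj.forward(lats, lons)
    return np.asarray(x), np.asarray(y), proj


@dataclass
class KernelSurface:
    """A normalized kernel density raster in projected km coordinates."""

    x0: float  # west edge of cell (0,0)
    y0: float  # south edge of cell (0,0)
    cell_km: float
    bandwidth_km: float
    density: np.ndarray  # shape (ny, nx); integrates to 1 over the grid
    projection: Optional[AlbersEqualArea] = None

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.density.shape[1]) + 0.5) * self.cell_km

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.density.shape[0]) + 0.5) * self.cell_km

    @property
    def volume(self) -> float:
        return float(self.density.sum() * self.cell_km**2)

    def cell_index(self, x, y):
        ix = np.floor((np.asarray(x) - self.x0) / self.cell_km).astype(int)
        iy = np.floor((np.asarray(y) - self.y0) / self.cell_km).astype(int)
        return iy, ix


def kernel_density(
    x: Sequence[float],
    y: Sequence[float],
    bandwidth_km: float = 200.0,
    cell_km: float = 10.0,
    kernel: str = "quartic",
    projection: Optional[AlbersEqualArea] = None,
) -> KernelSurface:
    """Kernel density surface of projected points.

    The quartic (biweight) kernel ``(3/(pi h^2)) (1 - r^2/h^2)^2`` has
    compact support of radius ``bandwidth_km``, matching the search-radius
    semantics of GIS kernel density tools. A Gaussian option uses sigma =
    bandwidth/2.58 (the radius then covers ~99% of kernel mass). The grid
    extends one bandwidth beyond the point bounding box and the surface is
    normalized to unit volume.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1:
        raise ValueError("need at least one point")
    h = float(bandwidth_km)
    pad = h if kernel == "quartic" else 3.0 * h / 2.58
    x0 = np.floor((x.min() - pad) / cell_km) * cell_km
    y0 = np.floor((y.min() - pad) / cell_km) * cell_km
    nx = int(np.ceil((x.max() + pad - x0) / cell_km)) + 1
    ny = int(np.ceil((y.max() + pad - y0) / cell_km)) + 1
    dens = np.zeros((ny, nx))
    xc = x0 + (np.arange(nx) + 0.5) * cell_km
    yc = y0 + (np.arange(ny) + 0.5) * cell_km
    if kernel == "quartic":
        reach = h
    elif kernel == "gaussian":
        sigma = h / 2.58
        reach = 4.0 * sigma
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    for px, py in zip(x, y):
        i0 = max(0, int((px - reach - x0) / cell_km))
        i1 = min(nx, int((px + reach - x0) / cell_km) + 2)
        j0 = max(0, int((py - reach - y0) / cell_km))
        j1 = min(ny, int((py + reach - y0) / cell_km) + 2)
        dx = xc[i0:i1] - px
        dy = yc[j0:j1] - py
        r2 = dy[:, None] ** 2 + dx[None, :] ** 2
        if kernel == "quartic":
            u = 1.0 - r2 / h**2
            k = np.where(u > 0.0, 3.0 / (math.pi * h**2) * u**2, 0.0)
        else:
            k = np.exp(-r2 / (2.0 * sigma**2)) / (2.0 * math.pi * sigma**2)
        dens[j0:j1, i0:i1] += k
    vol = dens.sum() * cell_km**2
    if vol <= 0:
        raise ValueError("degenerate density surface")
    dens /= vol
    return KernelSurface(
        x0=float(x0), y0=float(y0), cell_km=float(cell_km), bandwidth_km=h,
        density=dens, projection=projection,
    )


@dataclass
class OccupancyContour:
    """A highest-density occupancy region at one percentage level."""

    level: float  # percent of surface volume
    threshold: float  # density threshold defining the region
    captured_fraction: float  # volume fraction actually enclosed
    mask: np.ndarray  # boolean cell membership on the surface grid
    polygon_projected: MultiPolygon
    polygon_geographic: Optional[MultiPolygon] = None  # WGS84 lon/lat

    def contains_points(self, surface: KernelSurface, x, y) -> np.ndarray:
        """Membership of projected points via the cell mask (cheap, exact
        with respect to the thresholded grid)."""
        iy, ix = surface.cell_index(x, y)
        ny, nx = self.mask.shape
        ok = (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        out = np.zeros(np.shape(ix), dtype=bool)
        out[ok] = self.mask[iy[ok], ix[ok]]
        return out


def _polygonize_mask(surface: KernelSurface, mask: np.ndarray, simplify_km: float) -> MultiPolygon:
    cells = np.argwhere(mask)
    boxes = [
        box(
            surface.x0 + ix * surface.cell_km,
            surface.y0 + iy * surface.cell_km,
            surface.x0 + (ix + 1) * surface.cell_km,
            surface.y0 + (iy + 1) * surface.cell_km,
        )
        for iy, ix in cells
    ]
    geom = unary_union(boxes)
    if simplify_km > 0:
        geom = geom.simplify(simplify_km, preserve_topology=True)
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return geom


def occupancy_contours(
    surface: KernelSurface,
    levels: Sequence[float] = (25.0, 50.0, 75.0),
    simplify_km: float = 10.0,
) -> list[OccupancyContour]:
    """Highest-density occupancy contours of a surface.

    For level p the density threshold t is chosen so that the cells with
    density >= t form the smallest volume >= p/100; regions therefore nest
    exactly across levels. Polygons follow cell boundaries and are
    simplified with the given tolerance; geographic polygons are attached
    when the surface carries a projection.
    """
    for lv in levels:
        if not (0.0 < lv <= 100.0):
            raise ValueError(f"contour level {lv} outside (0, 100]")
    flat = np.sort(surface.density.ravel())[::-1]
    cumvol = np.cumsum(flat) * surface.cell_km**2
    out = []
    for lv in sorted(levels):
        target = lv / 100.0
        k = int(np.searchsorted(cumvol, target * (1.0 - 1e-12), side="left"))
        k = min(k, len(flat) - 1)
        thr = flat[k]
        if thr <= 0.0:  # p = 100 with compact support: full support region
            thr = np.min(flat[flat > 0.0])
        mask = surface.density >= thr
        captured = float(surface.density[mask].sum() * surface.cell_km**2)
        poly = _polygonize_mask(surface, mask, simplify_km)
        geo = None
        if surface.projection is not None:
            def _to_geo(coords):
                lat, lon = surface.projection.inverse(coords[:, 0], coords[:, 1])
                return np.column_stack([lon, lat])
            geo = shapely.transform(poly, _to_geo)
            if isinstance(geo, Polygon):
                geo = MultiPolygon([geo])
        out.append(
            OccupancyContour(
                level=float(lv), threshold=float(thr), captured_fraction=captured,
                mask=mask, polygon_projected=poly, polygon_geographic=geo,
            )
        )
    return out
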