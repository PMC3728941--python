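"""Spherical distance, equal-area projection, and polygon utilities.

All planar work downstream (kernel densities, mean-squared displacement,
grid cells) happens in a meter/kilometre-based equal-area plane so that
areas in km^2 are meaningful. The default projection is an Albers
equal-area conic centred on the Gulf of Mexico.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point
from shapely.ops import transform as shp_transform

EARTH_RADIUS_KM = 6371.0


def great_circle_km(p1, p2) -> np.ndarray | float:
    """Haversine great-circle distance in km.

    Parameters are ``(lon, lat)`` pairs in decimal degrees; arrays broadcast.
    """
    lon1, lat1 = np.radians(np.asarray(p1, dtype=float).T)
    lon2, lat2 = np.radians(np.asarray(p2, dtype=float).T)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


@dataclass(frozen=True)
class ProjectionSpec:
    """Albers equal-area conic on a sphere of radius 6371 km.

    Equal-area by construction, so polygon areas computed in the projected
    plane are true areas (km^2) up to the spherical approximation. The
    closed-form inverse makes round trips exact to machine precision.

    Defaults centre the projection on the Gulf of Mexico with standard
    parallels at 20N and 30N.
    """

    center_lon: float = -90.0
    center_lat: float = 25.0
    std_parallel_1: float = 20.0
    std_parallel_2: float = 30.0

    def _constants(self):
        phi1 = np.radians(self.std_parallel_1)
        phi2 = np.radians(self.std_parallel_2)
        phi0 = np.radians(self.center_lat)
        n = 0.5 * (np.sin(phi1) + np.sin(phi2))
        c = np.cos(phi1) ** 2 + 2.0 * n * np.sin(phi1)
        rho0 = EARTH_RADIUS_KM / n * np.sqrt(c - 2.0 * n * np.sin(phi0))
        return n, c, rho0

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to planar (x, y) in km."""
        n, c, rho0 = self._constants()
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        rho = EARTH_RADIUS_KM / n * np.sqrt(c - 2.0 * n * np.sin(phi))
        theta = n * (lam - np.radians(self.center_lon))
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y):
        """Planar km back to lon/lat degrees."""
        n, c, rho0 = self._constants()
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(x, rho0 - y)
        lam = np.radians(self.center_lon) + theta / n
        sinphi = (c - (rho * n / EARTH_RADIUS_KM) ** 2) / (2.0 * n)
        phi = np.arcsin(np.clip(sinphi, -1.0, 1.0))
        return np.degrees(lam), np.degrees(phi)


DEFAULT_PROJECTION = ProjectionSpec()


def project_points(points, projection: ProjectionSpec = DEFAULT_PROJECTION):
    """Project an (n, 2) array of lon/lat to an (n, 2) array of km."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = projection.forward(pts[:, 0], pts[:, 1])
    return np.column_stack([x, y])


def unproject_points(points_km, projection: ProjectionSpec = DEFAULT_PROJECTION):
    """Inverse of :func:`project_points`."""
    pts = np.atleast_2d(np.asarray(points_km, dtype=float))
    lon, lat = projection.inverse(pts[:, 0], pts[:, 1])
    return np.column_stack([lon, lat])


def project_geometry(geom, projection: ProjectionSpec = DEFAULT_PROJECTION):
    """Project a shapely geometry from lon/lat into the planar km system."""
    return shp_transform(lambda x, y: projection.forward(x, y), geom)


def unproject_geometry(geom, projection: ProjectionSpec = DEFAULT_PROJECTION):
    return shp_transform(lambda x, y: projection.inverse(x, y), geom)


def distance_to_polygon_km(point, polygon, projection: ProjectionSpec = DEFAULT_PROJECTION) -> float:
    """Minimum planar distance (km) from a lon/lat point to a lon/lat polygon.

    Returns 0 for points inside the polygon. The polygon must be a valid
    shapely (Multi)Polygon in geographic coordinates.
    """
    if polygon.is_empty:
        raise ValueError("empty polygon")
    if not polygon.is_valid:
        polygon = polygon.buffer(0)
        if not polygon.is_valid:
            raise ValueError("invalid polygon")
    x, y = projection.forward(point[0], point[1])
    p = Point(float(x), float(y))
    # densify long geographic edges so they stay faithful once projected
    poly_km = project_geometry(shapely.segmentize(polygon, 0.02), projection)
    if poly_km.contains(p):
        return 0.0
    return float(shapely.distance(poly_km, p))
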