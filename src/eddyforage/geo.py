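"""Great-circle geometry on a spherical Earth.

All distances are in kilometers unless noted; longitudes are kept in
[-180, 180). The sphere radius is the conventional 6371 km used by
eddy-atlas products.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between points in degrees, vectorized."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def tangent_plane_xy(lon, lat, lon0, lat0):
    """Project lon/lat (deg) to a local tangent plane about (lon0, lat0).

    Equirectangular projection scaled by cos(lat0): adequate at eddy scale
    (<~300 km) where the distortion is far below one profile spacing.
    Longitudes are unwrapped relative to lon0 first, so polygons straddling
    the dateline project continuously. Returns (x, y) in km.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    dlon = (lon - lon0 + 180.0) % 360.0 - 180.0
    x = np.radians(dlon) * np.cos(np.radians(lat0)) * EARTH_RADIUS_KM
    y = np.radians(lat - lat0) * EARTH_RADIUS_KM
    return x, y


def tangent_plane_lonlat(x, y, lon0, lat0):
    """Inverse of :func:`tangent_plane_xy`."""
    lat = lat0 + np.degrees(np.asarray(y, dtype=float) / EARTH_RADIUS_KM)
    lon = lon0 + np.degrees(
        np.asarray(x, dtype=float) / (EARTH_RADIUS_KM * np.cos(np.radians(lat0)))
    )
    return normalize_lon(lon), lat


def _to_unit_xyz(lon, lat):
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.stack([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1)


def great_circle_interpolate(lon1, lat1, lon2, lat2, fractions):
    """Points along the great circle from P1 to P2 at the given fractions.

    Uses slerp on the unit sphere. Returns (lon, lat) arrays in degrees.
    """
    f = np.asarray(fractions, dtype=float)
    a = _to_unit_xyz(lon1, lat1)
    b = _to_unit_xyz(lon2, lat2)
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    if omega < 1e-12:
        lon = np.full_like(f, float(lon1))
        lat = np.full_like(f, float(lat1))
        return normalize_lon(lon), lat
    p = (np.sin((1.0 - f)[:, None] * omega) * a + np.sin(f[:, None] * omega) * b) / np.sin(omega)
    lat = np.degrees(np.arcsin(np.clip(p[:, 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    return normalize_lon(lon), lat


def circle_polygon(lon0, lat0, radius_km, n_vertices=64):
    """Closed polygon approximating a geodesic circle about (lon0, lat0).

    Vertices are placed on the local tangent plane and mapped back to
    lon/lat; the first vertex is repeated last so the ring is closed.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = radius_km * np.cos(theta)
    y = radius_km * np.sin(theta)
    lon, lat = tangent_plane_lonlat(x, y, lon0, lat0)
    lon = np.append(lon, lon[0])
    lat = np.append(lat, lat[0])
    return lon, lat
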