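"""Independent oracles and small builders shared by the tests.

Everything here is deliberately implemented from scratch (or from a
different algorithm family) so the tests cross-check the package rather
than re-run it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EARTH_R_KM = 6371.0


# --- independent low-precision Astronomical Almanac (Meeus) solar ephemeris ---

def meeus_solar_elevation(lon_deg: float, lat_deg: float, t_utc: pd.Timestamp) -> float:
    """Solar elevation via the almanac's low-accuracy ecliptic formulae.

    Independent of the NOAA fractional-year algorithm: works from the
    Julian date with solar ecliptic longitude, obliquity, right ascension /
    declination and Greenwich sidereal time. Accuracy ~0.01 degrees.
    """
    jd = t_utc.to_julian_date()
    n = jd - 2451545.0
    ll = np.radians((280.460 + 0.9856474 * n) % 360.0)
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = ll + np.radians(1.915) * np.sin(g) + np.radians(0.020) * np.sin(2 * g)
    eps = np.radians(23.439 - 0.0000004 * n)
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    gmst_hours = (18.697374558 + 24.06570982441908 * n) % 24.0
    lst_deg = gmst_hours * 15.0 + lon_deg
    ha = np.radians(lst_deg) - ra
    lat = np.radians(lat_deg)
    sin_elev = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(ha)
    return float(np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0))))


def meeus_declination_eqtime(t_utc: pd.Timestamp) -> tuple[float, float]:
    """(declination deg, equation of time minutes) from the same almanac model."""
    jd = t_utc.to_julian_date()
    n = jd - 2451545.0
    ll = (280.460 + 0.9856474 * n) % 360.0
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = np.radians(ll) + np.radians(1.915) * np.sin(g) + np.radians(0.020) * np.sin(2 * g)
    eps = np.radians(23.439 - 0.0000004 * n)
    ra = np.degrees(np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))) % 360.0
    dec = np.degrees(np.arcsin(np.sin(eps) * np.sin(lam)))
    # apparent sun minus mean sun, in minutes of time
    eqtime_min = 4.0 * (((ll - ra) + 180.0) % 360.0 - 180.0)
    return dec, eqtime_min


# --- winding-number point-in-polygon oracle ---

def winding_number_inside(lon: float, lat: float, poly_lon, poly_lat) -> bool:
    """Signed-angle winding-number test in an unwrapped equirectangular plane."""
    poly_lon = np.asarray(poly_lon, dtype=float)
    poly_lat = np.asarray(poly_lat, dtype=float)
    lon0 = poly_lon[0]
    lat0 = float(np.mean(poly_lat))
    scale = np.cos(np.radians(lat0))
    px = ((lon - lon0 + 180.0) % 360.0 - 180.0) * scale
    py = lat - lat0
    vx = ((poly_lon - lon0 + 180.0) % 360.0 - 180.0) * scale
    vy = poly_lat - lat0
    dx = vx - px
    dy = vy - py
    ang = np.arctan2(dy, dx)
    dang = np.diff(ang)
    dang = (dang + np.pi) % (2 * np.pi) - np.pi
    winding = np.sum(dang) / (2 * np.pi)
    return bool(abs(winding) > 0.5)


# --- spherical rigid motions (great-circle distances exactly preserved) ---

def rotate_on_sphere(lon, lat, axis, angle_rad):
    """Rotate points about an arbitrary axis through the sphere center."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    p = np.stack([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1)
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    cos_a, sin_a = np.cos(angle_rad), np.sin(angle_rad)
    rotated = (p * cos_a + np.cross(np.broadcast_to(k, p.shape), p) * sin_a
               + np.outer(p @ k, k) * (1 - cos_a))
    lat_out = np.degrees(np.arcsin(np.clip(rotated[..., 2], -1, 1)))
    lon_out = np.degrees(np.arctan2(rotated[..., 1], rotated[..., 0]))
    return lon_out, lat_out


# --- builders ---

def make_eddy(eddy_id=0, lon=-140.0, lat=-30.0, r_eff_km=50.0, r_spd_km=30.0,
              polarity="AE", amplitude_m=0.1, date="2015-01-15",
              first_detection="2015-01-01", lifespan_days=60,
              rotational_speed_ms=0.3, n_vertices=64) -> pd.Series:
    """One circular atlas record as a Series (row of the atlas schema)."""
    from eddyforage.geo import circle_polygon

    eff_lon, eff_lat = circle_polygon(lon, lat, r_eff_km, n_vertices)
    spd_lon, spd_lat = circle_polygon(lon, lat, r_spd_km, n_vertices)
    return pd.Series({
        "eddy_id": eddy_id, "date": pd.Timestamp(date), "polarity": polarity,
        "lon": lon, "lat": lat, "amplitude_m": amplitude_m,
        "effective_radius_km": r_eff_km,
        "effective_area_km2": float(np.pi * r_eff_km**2),
        "speed_radius_km": r_spd_km, "rotational_speed_ms": rotational_speed_ms,
        "first_detection_date": pd.Timestamp(first_detection),
        "lifespan_days": lifespan_days,
        "contour_eff_lon": eff_lon, "contour_eff_lat": eff_lat,
        "contour_spd_lon": spd_lon, "contour_spd_lat": spd_lat,
    })


def wobbly_polygon(rng, center_lon, center_lat, radius_deg=1.0, n=40):
    """Closed star-shaped polygon with irregular radii (lon/lat degrees)."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    k = rng.integers(2, 6)
    phase = rng.uniform(0, 2 * np.pi)
    r = radius_deg * (1.0 + 0.3 * np.sin(k * theta + phase))
    lon = center_lon + r * np.cos(theta)
    lat = center_lat + r * np.sin(theta)
    lon = np.append(lon, lon[0])
    lat = np.append(lat, lat[0])
    return (lon + 180.0) % 360.0 - 180.0, lat
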