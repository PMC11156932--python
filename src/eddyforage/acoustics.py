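"""Preparation of georeferenced 38 kHz acoustic (NASC) profiles.

Turns raw backscatter profiles into the analysis-ready set: a common 10-m
vertical grid over 20-750 m, astronomical day/night/twilight labels from
solar elevation, and the shelf (seabed < 1000 m) and twilight exclusions.

NASC (Nautical Area Scattering Coefficient, m^2 nmi^-2) is the
echo-integrated backscatter used as a proxy of forage-fauna density.
Hull-mounted echosounders cannot sample the top ~20 m (bubble layer), so
the grid floor is 20 m even though the epipelagic layer is nominally 0-200 m.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEPTH_MIN_M = 20.0
DEPTH_MAX_M = 750.0
BIN_WIDTH_M = 10.0
#: Centers of the 73 half-open 10-m bins [20,30), [30,40), ... [740,750].
BIN_CENTERS_M = np.arange(DEPTH_MIN_M + BIN_WIDTH_M / 2, DEPTH_MAX_M, BIN_WIDTH_M)
NASC_COLUMNS = [f"nasc_{int(c)}" for c in BIN_CENTERS_M]

TWILIGHT_UPPER_DEG = 0.0
TWILIGHT_LOWER_DEG = -18.0
MIN_SEABED_M = 1000.0


def regrid_vertical(depths, values):
    """Linearly interpolate a raw profile onto the 10-m bin centers.

    Samples outside [20, 750] m are discarded first; bins outside the raw
    depth coverage are left missing (no extrapolation).

    Parameters
    ----------
    depths : array-like
        Strictly increasing sample depths in meters (positive down).
    values : array-like
        NASC values at those depths.

    Returns
    -------
    ndarray of shape (73,) with NaN where the raw profile has no coverage.
    """
    depths = np.asarray(depths, dtype=float)
    values = np.asarray(values, dtype=float)
    if depths.ndim != 1 or depths.shape != values.shape:
        raise ValueError("depths and values must be 1-D and the same length")
    if np.any(np.diff(depths) <= 0):
        raise ValueError("raw depths must be strictly increasing")
    keep = (depths >= DEPTH_MIN_M) & (depths <= DEPTH_MAX_M)
    depths, values = depths[keep], values[keep]
    if depths.size < 2:
        raise ValueError("need at least 2 raw samples within [20, 750] m")
    out = np.interp(BIN_CENTERS_M, depths, values, left=np.nan, right=np.nan)
    out[BIN_CENTERS_M < depths[0]] = np.nan
    out[BIN_CENTERS_M > depths[-1]] = np.nan
    return out


def _check_utc(times: pd.DatetimeIndex) -> pd.DatetimeIndex:
    if times.tz is None:
        raise ValueError("timestamps must be timezone-aware UTC (naive input rejected)")
    return times.tz_convert("UTC")


def solar_elevation(lon, lat, timestamp):
    """Solar elevation angle (degrees) via the NOAA solar position algorithm.

    Implements the NOAA solar-calculator series: geometric mean
    longitude/anomaly and the equation of center on Julian centuries give
    the apparent ecliptic longitude, declination and equation of time; the
    local hour angle then comes from true solar time. Atmospheric
    refraction is ignored: the twilight band is 18 degrees wide, refraction
    is ~0.5 degrees at the horizon and irrelevant to the day/night split.
    Accuracy is ~0.01 degrees over 1950-2050, well inside the 0.5 degree
    contract.

    `timestamp` must be timezone-aware UTC; scalars or arrays accepted.
    """
    times = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(timestamp)))
    times = _check_utc(times)
    lon = np.broadcast_to(np.asarray(lon, dtype=float), times.shape).astype(float)
    lat = np.broadcast_to(np.asarray(lat, dtype=float), times.shape).astype(float)

    jd = times.tz_localize(None).to_julian_date().to_numpy()
    t = (jd - 2451545.0) / 36525.0  # Julian centuries since J2000
    minutes = np.asarray(times.hour * 60.0 + times.minute
                         + (times.second + times.microsecond / 1e6) / 60.0, dtype=float)

    l0 = np.radians((280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0)
    m = np.radians(357.52911 + t * (35999.05029 - 0.0001537 * t))
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    center = (np.radians(1.914602 - t * (0.004817 + 0.000014 * t)) * np.sin(m)
              + np.radians(0.019993 - 0.000101 * t) * np.sin(2 * m)
              + np.radians(0.000289) * np.sin(3 * m))
    omega = np.radians(125.04 - 1934.136 * t)
    app_long = l0 + center - np.radians(0.00569 + 0.00478 * np.sin(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - 0.001813 * t))) / 60.0) / 60.0
    obliq = np.radians(mean_obliq + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(obliq) * np.sin(app_long))

    var_y = np.tan(obliq / 2.0) ** 2
    eqtime = 4.0 * np.degrees(
        var_y * np.sin(2 * l0) - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * var_y * np.sin(m) * np.cos(2 * l0)
        - 0.5 * var_y**2 * np.sin(4 * l0) - 1.25 * ecc**2 * np.sin(2 * m))

    tst = minutes + eqtime + 4.0 * lon  # true solar time, minutes (UTC input)
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle

    lat_r = np.radians(lat)
    cos_zen = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    elev = 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    if np.isscalar(timestamp) or getattr(timestamp, "ndim", 0) == 0:
        return float(elev[0])
    return elev


def classify_period(elevation):
    """Map solar elevation to 'day', 'night' or 'twilight'.

    Astronomical twilight is the inclusive band [-18, 0] degrees; twilight
    profiles are removed downstream to avoid sampling diel vertical migration
    in transit.
    """
    elev = np.asarray(elevation, dtype=float)
    out = np.where(elev > TWILIGHT_UPPER_DEG, "day",
                   np.where(elev < TWILIGHT_LOWER_DEG, "night", "twilight"))
    if out.ndim == 0:
        return str(out)
    return out


def annotate_period(profiles: pd.DataFrame) -> pd.DataFrame:
    """Add `solar_elevation_deg` and `period` columns from time and position."""
    out = profiles.copy()
    elev = solar_elevation(out["lon"].to_numpy(), out["lat"].to_numpy(),
                           pd.DatetimeIndex(out["time"]))
    out["solar_elevation_deg"] = elev
    out["period"] = classify_period(elev)
    return out


def filter_profiles(profiles: pd.DataFrame, min_seabed: float = MIN_SEABED_M,
                    drop_unknown_seabed: bool = False) -> pd.DataFrame:
    """Apply the twilight and continental-shelf exclusions.

    Drops twilight profiles and profiles whose seabed is shallower than
    `min_seabed` (strictly; a seabed exactly at 1000 m is retained). Profiles
    with unknown (NaN) seabed depth are retained and flagged in a
    `seabed_unknown` column unless `drop_unknown_seabed`. Row order is
    preserved; the operation is idempotent.
    """
    if "period" not in profiles.columns:
        raise ValueError("profiles must carry a 'period' column (run annotate_period)")
    out = profiles[profiles["period"] != "twilight"]
    seabed = out["seabed_depth_m"]
    unknown = seabed.isna()
    if drop_unknown_seabed:
        out = out[~unknown & (seabed >= min_seabed)]
        out = out.copy()
        out["seabed_unknown"] = False
    else:
        n_unknown = int(unknown.sum())
        if n_unknown and "seabed_unknown" not in out.columns:
            warnings.warn(f"{n_unknown} profiles have unknown seabed depth; retained and flagged")
        out = out[unknown | (seabed >= min_seabed)].copy()
        out["seabed_unknown"] = unknown.loc[out.index]
    return out.reset_index(drop=True)


def read_profiles(path) -> pd.DataFrame:
    """Read the wide per-profile CSV schema.

    Required columns: profile_id, time (ISO 8601 UTC), lon, lat,
    seabed_depth_m, and the 73 NASC columns nasc_25 ... nasc_745.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"profile_id", "time", "lon", "lat", "seabed_depth_m"} - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    absent = [c for c in NASC_COLUMNS if c not in df.columns]
    if absent:
        raise ValueError(f"profile table missing NASC bins: {absent[:3]}...")
    df["time"] = pd.DatetimeIndex(pd.to_datetime(df["time"], utc=True, format="ISO8601"))
    return df


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=False)
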