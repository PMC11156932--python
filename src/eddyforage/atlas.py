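"""Eddy-trajectory atlas: reading, filtering, and kinematic characteristics.

The atlas is a table with one record per eddy per day, emulating the daily
altimetric eddy-trajectory products: center position, polarity (AE
anticyclonic / CE cyclonic), amplitude (absolute-dynamic-topography
difference between edge and center, meters), the effective contour (the
outermost closed boundary) and the speed contour (where the rotational
current peaks), radii, area, rotational speed, first detection date and
lifespan.

In memory the atlas is a pandas DataFrame whose contour columns hold numpy
lon/lat arrays; on disk it is a CSV with the vertices space-joined (schema
in :data:`ATLAS_SCALAR_COLUMNS` / :data:`ATLAS_CONTOUR_COLUMNS`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geo import haversine_km, normalize_lon

ATLAS_SCALAR_COLUMNS = [
    "eddy_id", "date", "polarity", "lon", "lat", "amplitude_m",
    "effective_radius_km", "effective_area_km2", "speed_radius_km",
    "rotational_speed_ms", "first_detection_date", "lifespan_days",
]
ATLAS_CONTOUR_COLUMNS = [
    "contour_eff_lon", "contour_eff_lat", "contour_spd_lon", "contour_spd_lat",
]

MIN_LIFESPAN_DAYS = 14
TRAPPING_WINDOW_DAYS = 5


def _encode_contour(arr) -> str:
    return " ".join(f"{v:.6f}" for v in np.asarray(arr, dtype=float))


def _decode_contour(s) -> np.ndarray:
    if isinstance(s, str):
        return np.array(s.split(), dtype=float)
    return np.asarray(s, dtype=float)


def write_atlas(atlas: pd.DataFrame, path) -> None:
    """Write the atlas CSV; contour vertex arrays are space-joined."""
    out = atlas.copy()
    for col in ATLAS_CONTOUR_COLUMNS:
        out[col] = out[col].map(_encode_contour)
    out.to_csv(path, index=False)


def _validate(atlas: pd.DataFrame) -> None:
    from .collocation import point_in_contour  # deferred: avoids import cycle

    for i, rec in atlas.iterrows():
        loc = f"record {i} (eddy {rec['eddy_id']}, {rec['date']})"
        for field, cond in [
            ("amplitude_m", rec["amplitude_m"] >= 0),
            ("effective_radius_km", rec["effective_radius_km"] > 0),
            ("effective_area_km2", rec["effective_area_km2"] > 0),
            ("lifespan_days", rec["lifespan_days"] >= 1),
        ]:
            if not cond:
                raise ValueError(f"{loc}: invalid {field} = {rec[field]}")
        if rec["polarity"] not in ("AE", "CE"):
            raise ValueError(f"{loc}: polarity must be AE or CE")
        for lon_c, lat_c in (("contour_eff_lon", "contour_eff_lat"),
                             ("contour_spd_lon", "contour_spd_lat")):
            lon, lat = rec[lon_c], rec[lat_c]
            if len(lon) < 4 or lon[0] != lon[-1] or lat[0] != lat[-1]:
                raise ValueError(f"{loc}: contour {lon_c[:11]} is not a closed polygon")
        # speed contour must sit inside the effective contour
        for plon, plat in zip(rec["contour_spd_lon"][:-1], rec["contour_spd_lat"][:-1]):
            if not point_in_contour(plon, plat, rec["contour_eff_lon"], rec["contour_eff_lat"]):
                raise ValueError(f"{loc}: speed contour extends outside the effective contour")
        age = (rec["date"] - rec["first_detection_date"]).days
        if not 0 <= age <= rec["lifespan_days"]:
            raise ValueError(f"{loc}: age {age} outside [0, lifespan]")


def read_atlas(source, validate: bool = True) -> pd.DataFrame:
    """Read an atlas CSV into the in-memory schema.

    Records are grouped by eddy_id and sorted by date; invariants are
    validated with a record locator in the error message. An empty file
    yields an empty atlas with a warning.
    """
    try:
        df = pd.read_csv(source, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn("atlas source is empty")
        return pd.DataFrame(columns=ATLAS_SCALAR_COLUMNS + ATLAS_CONTOUR_COLUMNS)
    if df.empty:
        warnings.warn("atlas source is empty")
        return pd.DataFrame(columns=ATLAS_SCALAR_COLUMNS + ATLAS_CONTOUR_COLUMNS)
    missing = set(ATLAS_SCALAR_COLUMNS + ATLAS_CONTOUR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"atlas source missing mandatory fields: {sorted(missing)}")
    for col in ("date", "first_detection_date"):
        df[col] = pd.to_datetime(df[col])
    for col in ATLAS_CONTOUR_COLUMNS:
        df[col] = df[col].map(_decode_contour)
    df["lon"] = normalize_lon(df["lon"])
    df = df.sort_values(["eddy_id", "date"], kind="mergesort").reset_index(drop=True)
    if validate:
        _validate(df)
    return df


def filter_lifespan(atlas: pd.DataFrame, min_days: int = MIN_LIFESPAN_DAYS) -> pd.DataFrame:
    """Keep eddies whose lifespan is at least `min_days` (inclusive bound).

    Short-lived detections are likely tracking noise; the conventional
    threshold is 14 days. Idempotent.
    """
    if atlas.empty:
        return atlas
    return atlas[atlas["lifespan_days"] >= min_days].reset_index(drop=True)


def eddy_age(record) -> int:
    """Eddy age in whole days at the record's date (0 on the detection day)."""
    age = (record["date"] - record["first_detection_date"]).days
    if age < 0:
        raise ValueError("record date precedes first detection date")
    return int(age)


def compute_trapping(atlas: pd.DataFrame, window_days: int = TRAPPING_WINDOW_DAYS,
                     definition: str = "U_over_c") -> pd.Series:
    """Water-mass-trapping (non-linearity) metric per record.

    The standard non-linearity ratio U/c compares the eddy's rotational
    speed U with its translation speed c; values above 1 mean the eddy
    rotates faster than it moves and can carry a trapped water mass. The
    translation speed is the great-circle path length of the center over a
    centered `window_days` window divided by the elapsed time; windows are
    truncated at the trajectory ends.

    `definition="paper_literal"` instead returns path-length-km divided by
    rotational speed (m/s) — an audit switch for the alternative reading of
    "distance covered over rotational speed"; it is not dimensionless.

    Returns a Series aligned with the atlas index; +inf (flagged via a
    warning) where the center is stationary over the window.
    """
    if definition not in ("U_over_c", "paper_literal"):
        raise ValueError(f"unknown trapping definition: {definition}")
    half = pd.Timedelta(days=window_days / 2.0)
    out = pd.Series(np.nan, index=atlas.index, dtype=float)
    n_inf = 0
    for _, traj in atlas.groupby("eddy_id", sort=False):
        traj = traj.sort_values("date")
        dates = traj["date"]
        for idx, rec in traj.iterrows():
            in_win = traj[(dates >= rec["date"] - half) & (dates <= rec["date"] + half)]
            if len(in_win) < 2:
                continue
            path_km = float(np.sum(haversine_km(
                in_win["lon"].to_numpy()[:-1], in_win["lat"].to_numpy()[:-1],
                in_win["lon"].to_numpy()[1:], in_win["lat"].to_numpy()[1:])))
            elapsed_s = (in_win["date"].iloc[-1] - in_win["date"].iloc[0]).total_seconds()
            if elapsed_s <= 0:
                raise ValueError(f"zero elapsed time in trapping window at index {idx}")
            if definition == "paper_literal":
                out.loc[idx] = path_km / rec["rotational_speed_ms"]
                continue
            c_ms = path_km * 1000.0 / elapsed_s
            if c_ms == 0.0:
                out.loc[idx] = np.inf
                n_inf += 1
            else:
                out.loc[idx] = rec["rotational_speed_ms"] / c_ms
    if n_inf:
        warnings.warn(f"{n_inf} stationary windows: trapping set to +inf")
    return out


def eddy_characteristics(atlas: pd.DataFrame, trapping: pd.Series | None = None) -> pd.DataFrame:
    """Per-record table of the six characteristics used in effect-group
    comparisons: amplitude, trapping, effective area, SST anomaly, Chl
    anomaly and age. Surface anomalies are filled downstream (NaN here)."""
    if trapping is None:
        trapping = compute_trapping(atlas)
    return pd.DataFrame({
        "eddy_id": atlas["eddy_id"],
        "date": atlas["date"],
        "amplitude_m": atlas["amplitude_m"],
        "trapping": trapping,
        "effective_area_km2": atlas["effective_area_km2"],
        "age_days": [(d - f).days for d, f in zip(atlas["date"], atlas["first_detection_date"])],
    })
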