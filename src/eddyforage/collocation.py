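"""Collocating acoustic profiles with eddies.

Each retained profile is attributed to the nearest eddy (by great-circle
center distance) on its calendar day, tested against the eddy's effective
contour, and labelled:

* ``inside`` — within the effective contour, with one of four zones:
  ``core``, ``intern``, ``speed_border`` (outer 30% band inside the speed
  contour) and ``effective_border`` (outer 30% band between speed and
  effective contours);
* ``control`` — in the ribbon outside the effective contour but within
  twice the effective radius of the center, and (by default) outside every
  other eddy's effective contour, so a neighboring eddy cannot contaminate
  the "outside" reference;
* ``unused`` — everything else.

An eddy enters the analysis only if its profiles cover at least two
distinct inside zones and the control ribbon.

Polygon work is done in a local tangent plane about the eddy center
(dateline-safe unwrap) with shapely; boundary points count as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .geo import haversine_km, tangent_plane_xy

ZONES = ("core", "intern", "speed_border", "effective_border")
BORDER_FRACTION = 0.30
RIBBON_FACTOR = 2.0


def _contour_polygon(lon, lat, lon0, lat0) -> Polygon:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if len(np.unique(np.column_stack([lon, lat]), axis=0)) < 3:
        raise ValueError("degenerate contour: fewer than 3 distinct vertices")
    x, y = tangent_plane_xy(lon, lat, lon0, lat0)
    return Polygon(np.column_stack([x, y]))


def point_in_contour(lon, lat, contour_lon, contour_lat) -> bool:
    """Even-odd inside test for a lon/lat point against a closed contour.

    The contour is unwrapped and projected to a tangent plane about its
    centroid before testing, so dateline-crossing polygons work; boundary
    points are inside.
    """
    clon = np.asarray(contour_lon, dtype=float)
    clat = np.asarray(contour_lat, dtype=float)
    # anchor the unwrap on a vertex so the centroid is meaningful after projection
    lon0, lat0 = float(clon[0]), float(np.mean(clat))
    poly = _contour_polygon(clon, clat, lon0, lat0)
    x, y = tangent_plane_xy(lon, lat, lon0, lat0)
    return bool(poly.covers(Point(float(x), float(y))))


def _ray_distance(poly: Polygon, x: float, y: float) -> float:
    """Distance from the origin (eddy center) to the contour along the ray
    through (x, y). Assumes the center lies inside the polygon."""
    r = float(np.hypot(x, y))
    if r == 0.0:
        # any ray; use +x
        ux, uy = 1.0, 0.0
    else:
        ux, uy = x / r, y / r
    bounds = poly.bounds
    reach = 4.0 * max(abs(b) for b in bounds) + 1.0
    ray = LineString([(0.0, 0.0), (ux * reach, uy * reach)])
    hit = poly.exterior.intersection(ray)
    if hit.is_empty:
        raise ValueError("ray does not intersect contour (center outside polygon?)")
    pts = getattr(hit, "geoms", [hit])
    dists = []
    for g in pts:
        coords = getattr(g, "coords", None)
        if coords is None:
            continue
        for cx, cy in coords:
            dists.append(float(np.hypot(cx, cy)))
    return max(dists)


def assign_zone(lon, lat, eddy) -> tuple[str, float]:
    """Zone and normalized radial position r/D_eff of an inside point.

    With D_eff (D_spd) the center-to-contour distance along the center ray
    and d = D - r the inward distance from the contour: the outer 30% of
    each contour's radial span is its border band; the innermost 30% of the
    speed-contour span is the core; the rest is the intern. Precedence
    core > speed_border > effective_border > intern. For circular contours
    this reduces to plain radius fractions.
    """
    lon0, lat0 = float(eddy["lon"]), float(eddy["lat"])
    poly_eff = _contour_polygon(eddy["contour_eff_lon"], eddy["contour_eff_lat"], lon0, lat0)
    poly_spd = _contour_polygon(eddy["contour_spd_lon"], eddy["contour_spd_lat"], lon0, lat0)
    x, y = tangent_plane_xy(lon, lat, lon0, lat0)
    x, y = float(x), float(y)
    p = Point(x, y)
    if not poly_eff.covers(p):
        raise ValueError("position outside the effective contour")
    r = float(np.hypot(x, y))
    d_eff_total = _ray_distance(poly_eff, x, y)
    r_norm = r / d_eff_total if d_eff_total > 0 else 0.0
    inside_spd = poly_spd.covers(p)
    if inside_spd:
        d_spd_total = _ray_distance(poly_spd, x, y)
        if d_spd_total <= 0 or r <= BORDER_FRACTION * d_spd_total:
            return "core", r_norm
        if (d_spd_total - r) / d_spd_total <= BORDER_FRACTION:
            return "speed_border", r_norm
        return "intern", r_norm
    if (d_eff_total - r) / d_eff_total <= BORDER_FRACTION:
        return "effective_border", r_norm
    return "intern", r_norm


def nearest_eddy(lon, lat, eddies_on_date: pd.DataFrame):
    """Id of the eddy whose center is nearest, or None.

    The search is capped at twice the largest effective radius present that
    day; exact distance ties break to the smaller eddy_id so attribution is
    deterministic.
    """
    if eddies_on_date.empty:
        return None
    d = haversine_km(lon, lat, eddies_on_date["lon"].to_numpy(),
                     eddies_on_date["lat"].to_numpy())
    cap = 2.0 * float(eddies_on_date["effective_radius_km"].max())
    ids = eddies_on_date["eddy_id"].to_numpy()
    order = np.lexsort((ids, d))
    best = order[0]
    if d[best] > cap:
        return None
    return ids[best]


def control_membership(lon, lat, eddy, others: pd.DataFrame,
                       guard: bool = True, ribbon_factor: float = RIBBON_FACTOR) -> bool:
    """Is an outside point in the eddy's control ribbon?

    True iff the center distance is within `ribbon_factor` (default 2) times
    the effective radius and, when the contamination guard is on, the point
    is outside every other eddy's effective contour.
    """
    d = float(haversine_km(lon, lat, eddy["lon"], eddy["lat"]))
    if d > ribbon_factor * float(eddy["effective_radius_km"]):
        return False
    if guard:
        for _, other in others.iterrows():
            if other["eddy_id"] == eddy["eddy_id"]:
                continue
            if point_in_contour(lon, lat, other["contour_eff_lon"], other["contour_eff_lat"]):
                return False
    return True


def collocate_profiles(profiles: pd.DataFrame, atlas: pd.DataFrame,
                       guard: bool = True, ribbon_factor: float = RIBBON_FACTOR) -> pd.DataFrame:
    """Collocation table: one row per profile with eddy attribution.

    Attribution uses the same-day atlas record only. A profile inside some
    eddy's effective contour is `inside` that eddy (the containing contour
    wins even if another center is nearer); otherwise, if it falls in the
    nearest eddy's control ribbon it is `control` for that eddy; otherwise
    `unused`.

    Columns: profile_id, eddy_id, relation, zone, r_norm, period.
    """
    dates = pd.DatetimeIndex(profiles["time"]).tz_convert("UTC").normalize().tz_localize(None)
    atlas_by_date = dict(tuple(atlas.groupby("date"))) if not atlas.empty else {}
    geom_cache: dict = {}

    def day_geoms(day, todays):
        if day not in geom_cache:
            geoms = []
            for _, e in todays.iterrows():
                lon0, lat0 = float(e["lon"]), float(e["lat"])
                poly = _contour_polygon(e["contour_eff_lon"], e["contour_eff_lat"], lon0, lat0)
                vx, vy = poly.exterior.xy
                reach = float(np.max(np.hypot(np.asarray(vx), np.asarray(vy))))
                geoms.append((e, poly, reach))
            geom_cache[day] = (todays["lon"].to_numpy(float), todays["lat"].to_numpy(float),
                               todays["eddy_id"].to_numpy(),
                               todays["effective_radius_km"].to_numpy(float), geoms)
        return geom_cache[day]

    def covers(geom, lon, lat):
        e, poly, reach = geom
        x, y = tangent_plane_xy(lon, lat, float(e["lon"]), float(e["lat"]))
        return poly.covers(Point(float(x), float(y)))

    rows = []
    for (_, prof), day in zip(profiles.iterrows(), dates):
        lon, lat = float(prof["lon"]), float(prof["lat"])
        rec = {"profile_id": prof["profile_id"], "eddy_id": pd.NA, "relation": "unused",
               "zone": pd.NA, "r_norm": np.nan, "period": prof.get("period", pd.NA)}
        todays = atlas_by_date.get(day)
        if todays is not None:
            clon, clat, ids, radii, geoms = day_geoms(day, todays)
            d = haversine_km(lon, lat, clon, clat)
            container = None
            # distance prefilter: a point farther than the outermost vertex
            # cannot be inside the contour
            for pos in np.argsort(d):
                if d[pos] > geoms[pos][2] * 1.01:
                    break
                if covers(geoms[pos], lon, lat):
                    container = geoms[pos][0]
                    break
            if container is not None:
                zone, r_norm = assign_zone(lon, lat, container)
                rec.update(eddy_id=container["eddy_id"], relation="inside",
                           zone=zone, r_norm=r_norm)
            else:
                cap = 2.0 * float(radii.max())
                order = np.lexsort((ids, d))
                best = order[0]
                if d[best] <= cap and d[best] <= ribbon_factor * radii[best]:
                    contaminated = False
                    if guard:
                        for pos in np.argsort(d):
                            if pos == best:
                                continue
                            if d[pos] > geoms[pos][2] * 1.01:
                                break
                            if covers(geoms[pos], lon, lat):
                                contaminated = True
                                break
                    if not contaminated:
                        rec.update(eddy_id=ids[best], relation="control",
                                   r_norm=float(d[best] / radii[best]))
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class SampledEddy:
    """All profiles attributed to one eddy, partitioned for the analysis."""

    eddy_id: object
    polarity: str
    inside: pd.DataFrame          # profile rows joined with zone / r_norm
    control: pd.DataFrame
    zones_sampled: tuple
    counts: dict = field(default_factory=dict)


def build_sampled_eddies(colloc: pd.DataFrame, profiles: pd.DataFrame,
                         atlas: pd.DataFrame):
    """Group collocated profiles per eddy and apply the retention rule.

    Retained eddies have inside profiles in >= 2 distinct zones AND at least
    one control profile. Returns (list of SampledEddy, drop-log DataFrame).
    """
    merged = colloc.merge(profiles, on="profile_id", how="left", suffixes=("", "_prof"))
    retained, dropped = [], []
    polarity_by_id = (atlas.drop_duplicates("eddy_id").set_index("eddy_id")["polarity"]
                      if not atlas.empty else pd.Series(dtype=object))
    for eid, grp in merged[merged["eddy_id"].notna()].groupby("eddy_id"):
        inside = grp[grp["relation"] == "inside"]
        control = grp[grp["relation"] == "control"]
        zones = tuple(sorted(inside["zone"].dropna().unique()))
        if len(zones) < 2:
            dropped.append({"eddy_id": eid, "reason": "<2 inside zones"})
            continue
        if control.empty:
            dropped.append({"eddy_id": eid, "reason": "no control profiles"})
            continue
        counts = {
            "n_inside": len(inside), "n_control": len(control),
            "n_inside_day": int((inside["period"] == "day").sum()),
            "n_inside_night": int((inside["period"] == "night").sum()),
            "n_control_day": int((control["period"] == "day").sum()),
            "n_control_night": int((control["period"] == "night").sum()),
        }
        retained.append(SampledEddy(
            eddy_id=eid, polarity=str(polarity_by_id.get(eid, "NA")),
            inside=inside.reset_index(drop=True), control=control.reset_index(drop=True),
            zones_sampled=zones, counts=counts))
    return retained, pd.DataFrame(dropped, columns=["eddy_id", "reason"])
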