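"""Point-in-contour, zone geometry, control ribbon, and the retention rule."""

import numpy as np
import pandas as pd
import pytest

from eddyforage import (assign_zone, build_sampled_eddies, control_membership,
                        nearest_eddy, point_in_contour)
from eddyforage.geo import haversine_km, tangent_plane_lonlat
from helpers import make_eddy, winding_number_inside, wobbly_polygon


@pytest.fixture(scope="module")
def eddy():
    return make_eddy(r_eff_km=50.0, r_spd_km=30.0)


def _point_at_radius(eddy, r_km, bearing_rad=0.3):
    lon, lat = tangent_plane_lonlat(r_km * np.cos(bearing_rad), r_km * np.sin(bearing_rad),
                                    eddy["lon"], eddy["lat"])
    return float(lon), float(lat)


class TestPointInContour:
    def test_center_inside(self, eddy):
        assert point_in_contour(eddy["lon"], eddy["lat"],
                                eddy["contour_eff_lon"], eddy["contour_eff_lat"])

    def test_three_radii_out_is_outside(self, eddy):
        lon, lat = _point_at_radius(eddy, 150.0)
        assert not point_in_contour(lon, lat, eddy["contour_eff_lon"],
                                    eddy["contour_eff_lat"])

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            point_in_contour(0, 0, [1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_agrees_with_winding_number_oracle(self, rng):
        mismatches = 0
        checked = 0
        for _ in range(200):
            # half the polygons straddle the dateline
            clon = rng.uniform(170, 190) if rng.random() < 0.5 else rng.uniform(-150, 150)
            clon = (clon + 180) % 360 - 180
            clat = rng.uniform(-55, 55)
            plon, plat = wobbly_polygon(rng, clon, clat, radius_deg=rng.uniform(0.5, 2.0))
            for _ in range(25):
                dlon = rng.uniform(-3, 3)
                dlat = rng.uniform(-3, 3)
                lon = (clon + dlon + 180) % 360 - 180
                lat = clat + dlat
                got = point_in_contour(lon, lat, plon, plat)
                want = winding_number_inside(lon, lat, plon, plat)
                checked += 1
                mismatches += got != want
        assert checked == 5000
        assert mismatches == 0


class TestAssignZone:
    def test_effective_border_at_45_of_50_km(self, eddy):
        # d_eff/D_eff = 5/50 = 0.1 <= 0.3, outside the 30 km speed contour
        lon, lat = _point_at_radius(eddy, 45.0)
        zone, r_norm = assign_zone(lon, lat, eddy)
        assert zone == "effective_border"
        assert r_norm == pytest.approx(0.9, abs=0.01)

    def test_center_is_core(self, eddy):
        zone, r_norm = assign_zone(eddy["lon"], eddy["lat"], eddy)
        assert zone == "core"
        assert r_norm == pytest.approx(0.0, abs=1e-9)

    def test_20_km_is_intern(self, eddy):
        # inside speed contour: d_spd/D_spd = 10/30 = 0.33 > 0.3 and
        # r/D_spd = 0.67 > 0.3 -> intern
        lon, lat = _point_at_radius(eddy, 20.0)
        assert assign_zone(lon, lat, eddy)[0] == "intern"

    def test_outside_effective_contour_errors(self, eddy):
        lon, lat = _point_at_radius(eddy, 70.0)
        with pytest.raises(ValueError, match="outside"):
            assign_zone(lon, lat, eddy)

    def test_rotation_invariance_for_circles(self, eddy):
        for r, expected in [(5.0, "core"), (20.0, "intern"), (25.0, "speed_border"),
                            (33.0, "intern"), (46.0, "effective_border")]:
            for bearing in np.linspace(0, 2 * np.pi, 13):
                lon, lat = _point_at_radius(eddy, r, bearing)
                assert assign_zone(lon, lat, eddy)[0] == expected

    def test_partition_every_inside_point_gets_exactly_one_zone(self, eddy, rng):
        # radial bands on the circle: [0, .3Rs] core, (.3Rs, .7Rs) intern,
        # [.7Rs, Rs] speed border, (Rs, .7Re) intern, [.7Re, Re] effective border
        r_spd, r_eff = 30.0, 50.0
        edges = np.array([0.3 * r_spd, 0.7 * r_spd, r_spd, 0.7 * r_eff, r_eff])
        n = counted = 0
        while n < 2000:
            r = rng.uniform(0, 0.998 * r_eff)
            if np.min(np.abs(edges - r)) < 0.25:   # skip band edges (polygon != circle)
                continue
            n += 1
            lon, lat = _point_at_radius(eddy, r, rng.uniform(0, 2 * np.pi))
            zone, _ = assign_zone(lon, lat, eddy)
            expected = ("core" if r < edges[0] else
                        "intern" if r < edges[1] else
                        "speed_border" if r < edges[2] else
                        "intern" if r < edges[3] else "effective_border")
            assert zone == expected
            counted += 1
        assert counted == 2000


class TestNearestEddy:
    def _two_eddies(self):
        e1 = make_eddy(eddy_id=1, lon=-140.0)
        e2 = make_eddy(eddy_id=2, lon=-138.0)
        return pd.DataFrame([e1, e2])

    def test_picks_nearer_center(self):
        eddies = self._two_eddies()
        assert nearest_eddy(-139.9, -30.0, eddies) == 1
        assert nearest_eddy(-138.1, -30.0, eddies) == 2

    def test_none_when_no_eddies(self):
        assert nearest_eddy(0.0, 0.0, pd.DataFrame(columns=["eddy_id", "lon", "lat",
                                                            "effective_radius_km"])) is None

    def test_none_beyond_search_cap(self):
        eddies = self._two_eddies()
        assert nearest_eddy(-120.0, -30.0, eddies) is None  # ~1700 km away, cap 100 km

    def test_tie_breaks_to_smaller_id(self):
        e_hi = make_eddy(eddy_id=7, lon=-141.0)
        e_lo = make_eddy(eddy_id=3, lon=-139.0)
        eddies = pd.DataFrame([e_hi, e_lo])
        assert nearest_eddy(-140.0, -30.0, eddies) == 3


class TestControlMembership:
    def test_inside_ribbon(self, eddy):
        lon, lat = _point_at_radius(eddy, 75.0)  # 1.5 R_eff
        assert control_membership(lon, lat, eddy, pd.DataFrame([eddy]))

    def test_beyond_two_radii_not_control(self, eddy):
        lon, lat = _point_at_radius(eddy, 125.0)  # 2.5 R_eff
        assert not control_membership(lon, lat, eddy, pd.DataFrame([eddy]))

    def test_neighbor_contamination_guard(self, eddy):
        # neighbor centered 75 km east: the candidate point sits inside it
        nlon, nlat = _point_at_radius(eddy, 75.0, 0.0)
        neighbor = make_eddy(eddy_id=99, lon=nlon, lat=nlat)
        others = pd.DataFrame([eddy, neighbor])
        plon, plat = _point_at_radius(eddy, 75.0, 0.0)
        assert not control_membership(plon, plat, eddy, others)
        assert control_membership(plon, plat, eddy, others, guard=False)


class TestRetentionRule:
    def _colloc(self, zones, with_control):
        rows = []
        for i, z in enumerate(zones):
            rows.append({"profile_id": i, "eddy_id": 1, "relation": "inside",
                         "zone": z, "r_norm": 0.2, "period": "day"})
        if with_control:
            rows.append({"profile_id": 90, "eddy_id": 1, "relation": "control",
                         "zone": pd.NA, "r_norm": 1.5, "period": "day"})
        return pd.DataFrame(rows)

    def _profiles(self, ids):
        from eddyforage import NASC_COLUMNS
        df = pd.DataFrame({"profile_id": ids,
                           "time": pd.Timestamp("2015-01-15", tz="UTC"),
                           "lon": -140.0, "lat": -30.0, "period": "day"})
        for c in NASC_COLUMNS:
            df[c] = 100.0
        return df

    def test_two_zones_plus_control_retained(self):
        colloc = self._colloc(["core", "intern"], with_control=True)
        atlas = pd.DataFrame([make_eddy(eddy_id=1)])
        sampled, dropped = build_sampled_eddies(colloc, self._profiles([0, 1, 90]), atlas)
        assert len(sampled) == 1 and dropped.empty
        assert sampled[0].zones_sampled == ("core", "intern")

    def test_one_zone_plus_control_dropped(self):
        colloc = self._colloc(["core"], with_control=True)
        atlas = pd.DataFrame([make_eddy(eddy_id=1)])
        sampled, dropped = build_sampled_eddies(colloc, self._profiles([0, 90]), atlas)
        assert not sampled
        assert dropped["reason"].iloc[0] == "<2 inside zones"

    def test_three_zones_without_control_dropped(self):
        colloc = self._colloc(["core", "intern", "speed_border"], with_control=False)
        atlas = pd.DataFrame([make_eddy(eddy_id=1)])
        sampled, dropped = build_sampled_eddies(colloc, self._profiles([0, 1, 2]), atlas)
        assert not sampled
        assert dropped["reason"].iloc[0] == "no control profiles"


class TestEndToEndGeometry:
    def test_no_profile_both_inside_and_control(self, noisy_run):
        colloc = noisy_run["collocation"]
        per_profile = colloc.groupby("profile_id")["relation"].nunique()
        assert (per_profile == 1).all()

    def test_transect_split_at_effective_radius(self, noisy_run):
        # along a center crossing, the inside/outside split must sit at
        # R_eff within one profile spacing (plus the polygon-circle gap)
        atlas = noisy_run["atlas"]
        colloc = noisy_run["collocation"].merge(noisy_run["profiles"], on="profile_id")
        spacing_km = 1.0 / noisy_run["config"].synthetic.profiles_per_track_km
        checked = 0
        for eid, grp in colloc[colloc["relation"] == "inside"].groupby("eddy_id"):
            recs = atlas[atlas["eddy_id"] == eid]
            r_eff = float(recs["effective_radius_km"].iloc[0])
            days = pd.DatetimeIndex(grp["time"]).tz_convert("UTC").normalize().tz_localize(None)
            dists = []
            for (_, p), day in zip(grp.iterrows(), days):
                rec = recs[recs["date"] == day].iloc[0]
                dists.append(float(haversine_km(p["lon"], p["lat"], rec["lon"], rec["lat"])))
            assert max(dists) <= r_eff + 1.5 * spacing_km
            checked += 1
        assert checked > 0
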