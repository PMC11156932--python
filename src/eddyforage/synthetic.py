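"""Synthetic eddy ocean: atlas, ship track, acoustic profiles, surface fields.

Generates the three inputs the pipeline consumes — an eddy-trajectory
atlas, georeferenced 38 kHz NASC profiles along a ship track, and
along-track SST / chlorophyll samples — with known ground truth, so every
downstream stage (collocation, anomalies, classification) is testable
without external altimetry or sonar archives.

The acoustic model is a two-component vertical backscatter column: an
epipelagic component plus a Gaussian deep scattering layer (DSL) centered
near 500 m by day. At night a fixed fraction of the DSL mass migrates into
the epipelagic shape (diel vertical migration), conserving the column
integral exactly. A designated fraction of eddies multiplies all NASC bins
inside their effective contour by a constant factor; SST and chlorophyll
carry polarity-signed signatures inside every eddy (anticyclones warm /
chlorophyll-poor, cyclones cool / chlorophyll-rich). Observation noise is
multiplicative lognormal per profile, parameterized so the multiplicative
median is 1 (the mean is then sqrt(1+cv^2), handled explicitly where a
mean matters).

All randomness derives from the config seed through named substreams, and
identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import collocation
from .acoustics import BIN_CENTERS_M, NASC_COLUMNS, classify_period, solar_elevation
from .atlas import ATLAS_CONTOUR_COLUMNS, ATLAS_SCALAR_COLUMNS
from .geo import (circle_polygon, great_circle_interpolate, haversine_km,
                  normalize_lon, tangent_plane_lonlat)

GRAVITY_MS2 = 9.81
OMEGA_RAD_S = 7.2921e-5
MAX_ROTATIONAL_SPEED_MS = 2.0
MIN_CORIOLIS_LAT_DEG = 5.0


class DomainTooSmallError(ValueError):
    """Raised when non-overlapping eddy placement fails after bounded retries."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic ocean.

    Ranges mirror the envelope of the sampled real-eddy population:
    amplitude within [0.004, 0.698] m, effective areas within
    [2464, 107984] km^2, lifespans within [14, 1000] d.
    """

    seed: int = 0
    n_eddies: int = 12
    domain_bounds: tuple = (-160.0, -120.0, -45.0, -15.0)  # lon_min, lon_max, lat_min, lat_max
    amplitude_range: tuple = (0.02, 0.4)        # m
    radius_range: tuple = (40.0, 100.0)         # km, effective radius
    lifespan_range: tuple = (60, 365)           # days
    fraction_effect_eddies: float = 0.3
    effect_size_nasc: float = 1.5               # multiplicative, inside effect eddies
    effect_size_sst: float = 0.3                # deg C additive, signed by polarity
    effect_size_chl: float = 1.18               # multiplicative, signed by polarity
    noise_cv: float = 0.3                       # lognormal CV per profile
    profiles_per_track_km: float = 1.0
    ship_speed_kmh: float = 18.5                # ~10 knots
    track_plan: tuple | None = None             # ((lon, lat), ...) waypoints
    start_date: str = "2015-01-15"
    atlas_days: int = 45
    drift_speed_km_day: float = 3.0
    speed_radius_fraction: float = 0.7
    n_contour_vertices: int = 64
    dvm_migrate_fraction: float = 0.5
    epipelagic_total_nasc: float = 500.0
    dsl_total_nasc: float = 1500.0
    epi_center_m: float = 60.0
    epi_width_m: float = 40.0
    dsl_center_m: float = 500.0
    dsl_width_m: float = 80.0
    seabed_depth_m: float = 4000.0
    sst_background_c: float = 18.0
    sst_noise_sd_c: float = 0.2
    chl_background: float = 0.15
    chl_noise_cv: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.fraction_effect_eddies <= 1.0:
            raise ValueError("fraction_effect_eddies must be in [0, 1]")
        if self.effect_size_nasc <= 0 or self.effect_size_chl <= 0:
            raise ValueError("multiplicative effect sizes must be > 0")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be positive and ordered")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def lognormal_factors(rng, cv: float, size) -> np.ndarray:
    """Multiplicative noise with median 1 and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(size))


def rotational_speed_ms(amplitude_m: float, speed_radius_km: float, lat_deg: float) -> float:
    """Geostrophic scaling U = g*A/(f*R_spd), monotone in amplitude.

    The Coriolis latitude is floored at 5 degrees and the result capped at
    2 m/s so low-latitude eddies do not blow up.
    """
    lat_eff = max(abs(lat_deg), MIN_CORIOLIS_LAT_DEG)
    f = 2.0 * OMEGA_RAD_S * np.sin(np.radians(lat_eff))
    u = GRAVITY_MS2 * amplitude_m / (f * speed_radius_km * 1000.0)
    return float(min(u, MAX_ROTATIONAL_SPEED_MS))


def generate_eddy_atlas(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily eddy records over the simulation window, plus ground truth.

    Eddies are placed so that their control ribbons (2x effective radius)
    do not overlap, drift linearly at `drift_speed_km_day` along a random
    bearing, and carry 64-vertex circular effective and speed contours.

    Returns (atlas, ground_truth); ground truth has one row per eddy with
    has_nasc_effect, effect_direction and true_effect_size.
    """
    rng = _rng(config, 1)
    lon_min, lon_max, lat_min, lat_max = config.domain_bounds
    radii = rng.uniform(*config.radius_range, size=config.n_eddies)
    centers = []
    km_per_deg_lat = 111.19
    for i, r in enumerate(radii):
        placed = False
        for _ in range(500):
            margin_lat = r / km_per_deg_lat
            lat = rng.uniform(lat_min + margin_lat, lat_max - margin_lat)
            margin_lon = r / (km_per_deg_lat * np.cos(np.radians(lat)))
            lon = rng.uniform(lon_min + margin_lon, lon_max - margin_lon)
            ok = all(haversine_km(lon, lat, lo, la) >= 2.0 * (r + radii[j]) + 10.0
                     for j, (lo, la) in enumerate(centers))
            if ok:
                centers.append((lon, lat))
                placed = True
                break
        if not placed:
            raise DomainTooSmallError(
                f"could not place eddy {i} of radius {r:.0f} km after 500 tries")

    amplitudes = rng.uniform(*config.amplitude_range, size=config.n_eddies)
    polarities = np.where(rng.random(config.n_eddies) < 0.5, "AE", "CE")
    lifespans = rng.integers(config.lifespan_range[0], config.lifespan_range[1] + 1,
                             size=config.n_eddies)
    bearings = rng.uniform(0, 2 * np.pi, size=config.n_eddies)
    start = pd.Timestamp(config.start_date)
    ages0 = np.array([rng.integers(0, max(1, life - config.atlas_days))
                      for life in lifespans])

    n_effect = int(round(config.fraction_effect_eddies * config.n_eddies))
    effect_ids = set(rng.permutation(config.n_eddies)[:n_effect].tolist())
    direction = 1 if config.effect_size_nasc >= 1.0 else -1

    records = []
    for i in range(config.n_eddies):
        lon0, lat0 = centers[i]
        r_eff, r_spd = float(radii[i]), float(radii[i] * config.speed_radius_fraction)
        for d in range(config.atlas_days):
            age = int(ages0[i]) + d
            if age > lifespans[i]:
                break
            dx = config.drift_speed_km_day * d * np.cos(bearings[i])
            dy = config.drift_speed_km_day * d * np.sin(bearings[i])
            lon_c, lat_c = tangent_plane_lonlat(dx, dy, lon0, lat0)
            lon_c, lat_c = float(lon_c), float(lat_c)
            eff_lon, eff_lat = circle_polygon(lon_c, lat_c, r_eff, config.n_contour_vertices)
            spd_lon, spd_lat = circle_polygon(lon_c, lat_c, r_spd, config.n_contour_vertices)
            records.append({
                "eddy_id": i, "date": start + pd.Timedelta(days=d),
                "polarity": polarities[i], "lon": normalize_lon(lon_c), "lat": lat_c,
                "amplitude_m": float(amplitudes[i]),
                "effective_radius_km": r_eff,
                "effective_area_km2": float(np.pi * r_eff**2),
                "speed_radius_km": r_spd,
                "rotational_speed_ms": rotational_speed_ms(amplitudes[i], r_spd, lat_c),
                "first_detection_date": start - pd.Timedelta(days=int(ages0[i])),
                "lifespan_days": int(lifespans[i]),
                "contour_eff_lon": eff_lon, "contour_eff_lat": eff_lat,
                "contour_spd_lon": spd_lon, "contour_spd_lat": spd_lat,
            })
    atlas = pd.DataFrame(records, columns=ATLAS_SCALAR_COLUMNS + ATLAS_CONTOUR_COLUMNS)
    truth = pd.DataFrame({
        "eddy_id": np.arange(config.n_eddies),
        "polarity": polarities,
        "has_nasc_effect": [i in effect_ids for i in range(config.n_eddies)],
        "effect_direction": [direction if i in effect_ids else 0
                             for i in range(config.n_eddies)],
        "true_effect_size": [config.effect_size_nasc if i in effect_ids else 1.0
                             for i in range(config.n_eddies)],
    })
    return atlas, truth


def survey_track_plan(atlas: pd.DataFrame, leg_factor: float = 2.2,
                      ship_speed_kmh: float | None = None) -> tuple:
    """Waypoints for a survey crossing every eddy through its center.

    Eddies are visited in order of first-day longitude; each gets an entry
    and exit waypoint `leg_factor` effective radii west/east of its center,
    so a crossing samples the control ribbon on both flanks and a full
    inside diameter. When `ship_speed_kmh` is given the planner predicts
    the arrival day from the cumulative track distance and aims at the
    eddy's drifted center on that day; otherwise it uses day-0 centers.
    """
    day0 = atlas[atlas["date"] == atlas["date"].min()].sort_values("lon")
    by_id = dict(tuple(atlas.groupby("eddy_id")))
    plan: list = []
    cum_km = 0.0
    prev = None
    for _, e0 in day0.iterrows():
        traj = by_id[e0["eddy_id"]].sort_values("date").reset_index(drop=True)
        day = 0
        entry = exit_ = None
        dx = 0.0
        for _ in range(3):  # fixed-point: arrival day <-> drifted center
            e = traj.iloc[min(day, len(traj) - 1)]
            dx = leg_factor * float(e["effective_radius_km"])
            elon, elat = tangent_plane_lonlat(-dx, 0.0, e["lon"], e["lat"])
            entry = (float(elon), float(elat))
            xlon, xlat = tangent_plane_lonlat(dx, 0.0, e["lon"], e["lat"])
            exit_ = (float(xlon), float(xlat))
            d_entry = cum_km + (float(haversine_km(*prev, *entry)) if prev else 0.0)
            if not ship_speed_kmh:
                break
            day = int(d_entry / ship_speed_kmh / 24.0)
        plan.extend([entry, exit_])
        cum_km = d_entry + 2.0 * dx
        prev = exit_
    return tuple(plan)


def generate_track(config: SyntheticConfig, plan=None) -> pd.DataFrame:
    """Timestamped ship positions along great-circle legs between waypoints.

    Positions are spaced 1/profiles_per_track_km apart; timestamps advance
    at `ship_speed_kmh` along the cumulative track distance and are strictly
    increasing.
    """
    plan = plan if plan is not None else config.track_plan
    if plan is None or len(plan) < 2:
        raise ValueError("track plan needs at least 2 waypoints")
    if config.ship_speed_kmh <= 0:
        raise ValueError("ship_speed_kmh must be > 0")
    if config.profiles_per_track_km <= 0:
        raise ValueError("profiles_per_track_km must be > 0")
    wlon = np.array([w[0] for w in plan], dtype=float)
    wlat = np.array([w[1] for w in plan], dtype=float)
    leg_km = haversine_km(wlon[:-1], wlat[:-1], wlon[1:], wlat[1:])
    cum = np.concatenate([[0.0], np.cumsum(leg_km)])
    spacing = 1.0 / config.profiles_per_track_km
    n_steps = max(1, int(round(cum[-1] / spacing)))
    s = np.linspace(0.0, cum[-1], n_steps + 1)  # both endpoints sampled
    leg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(leg_km) - 1)
    lons = np.empty_like(s)
    lats = np.empty_like(s)
    for li in np.unique(leg_idx):
        sel = leg_idx == li
        frac = (s[sel] - cum[li]) / leg_km[li] if leg_km[li] > 0 else np.zeros(sel.sum())
        lons[sel], lats[sel] = great_circle_interpolate(
            wlon[li], wlat[li], wlon[li + 1], wlat[li + 1], frac)
    t0 = pd.Timestamp(config.start_date, tz="UTC")
    times = t0 + pd.to_timedelta(s / config.ship_speed_kmh, unit="h")
    return pd.DataFrame({"time": times, "lon": lons, "lat": lats})


def day_night_profiles(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless baseline NASC columns (day, night) on the 73-bin grid.

    Shapes are normalized to unit sum before scaling, so the day and night
    column integrals are exactly equal: at night `dvm_migrate_fraction` of
    the DSL mass moves into the epipelagic shape.
    """
    epi = np.exp(-0.5 * ((BIN_CENTERS_M - config.epi_center_m) / config.epi_width_m) ** 2)
    dsl = np.exp(-0.5 * ((BIN_CENTERS_M - config.dsl_center_m) / config.dsl_width_m) ** 2)
    epi /= epi.sum()
    dsl /= dsl.sum()
    e0, d0, m = config.epipelagic_total_nasc, config.dsl_total_nasc, config.dvm_migrate_fraction
    day = e0 * epi + d0 * dsl
    night = (e0 + m * d0) * epi + (1.0 - m) * d0 * dsl
    return day, night


def _inside_eddy(lon, lat, todays: pd.DataFrame):
    """Id of the eddy whose effective contour contains the point, else None."""
    if todays is None or todays.empty:
        return None
    d = haversine_km(lon, lat, todays["lon"].to_numpy(), todays["lat"].to_numpy())
    for pos in np.argsort(d):
        e = todays.iloc[pos]
        if d[pos] > 1.2 * e["effective_radius_km"]:
            break
        if collocation.point_in_contour(lon, lat, e["contour_eff_lon"], e["contour_eff_lat"]):
            return int(e["eddy_id"])
    return None


def generate_profiles(track: pd.DataFrame, atlas: pd.DataFrame, truth: pd.DataFrame,
                      config: SyntheticConfig):
    """Acoustic profiles and surface samples along the track.

    Returns (profiles, surface, profile_truth):

    * profiles — wide NASC table (one row per profile) with time, position,
      seabed depth, solar elevation and day/night/twilight period;
    * surface — along-track SST (deg C) and chlorophyll samples;
    * profile_truth — per-profile ground truth: containing eddy id, applied
      effect factor, noise factor and the noiseless column total.

    Inside an effect eddy every bin is multiplied by the configured factor;
    the twilight column shape follows the nearer period (these profiles are
    removed downstream anyway).
    """
    rng = _rng(config, 2)
    times = pd.DatetimeIndex(track["time"])
    lon = track["lon"].to_numpy(dtype=float)
    lat = track["lat"].to_numpy(dtype=float)
    elev = solar_elevation(lon, lat, times)
    period = classify_period(elev)
    day_col, night_col = day_night_profiles(config)

    atlas_by_date = (dict(tuple(atlas.groupby("date"))) if not atlas.empty else {})
    days = times.tz_convert("UTC").normalize().tz_localize(None)

    n = len(track)
    truth_by_id = truth.set_index("eddy_id")
    noise = lognormal_factors(rng, config.noise_cv, n)
    sst_noise = rng.normal(0.0, config.sst_noise_sd_c, size=n)
    chl_noise = lognormal_factors(rng, config.chl_noise_cv, n)

    nasc = np.empty((n, len(BIN_CENTERS_M)))
    inside_id = np.full(n, -1)
    effect_factor = np.ones(n)
    sst = np.full(n, config.sst_background_c)
    chl = np.full(n, config.chl_background)
    for i in range(n):
        base = day_col if elev[i] > -9.0 else night_col
        eid = _inside_eddy(lon[i], lat[i], atlas_by_date.get(days[i]))
        if eid is not None:
            inside_id[i] = eid
            pol = truth_by_id.loc[eid, "polarity"]
            sst[i] += config.effect_size_sst if pol == "AE" else -config.effect_size_sst
            chl[i] *= config.effect_size_chl if pol == "CE" else 1.0 / config.effect_size_chl
            if truth_by_id.loc[eid, "has_nasc_effect"]:
                effect_factor[i] = config.effect_size_nasc
        nasc[i] = base * effect_factor[i]
    true_totals = nasc.sum(axis=1)
    nasc = nasc * noise[:, None]
    sst = sst + sst_noise
    chl = chl * chl_noise

    profiles = pd.DataFrame({
        "profile_id": np.arange(n), "time": times, "lon": lon, "lat": lat,
        "seabed_depth_m": config.seabed_depth_m,
        "solar_elevation_deg": elev, "period": period,
    })
    profiles = pd.concat(
        [profiles, pd.DataFrame(nasc, columns=NASC_COLUMNS)], axis=1)
    surface = pd.DataFrame({
        "profile_id": np.arange(n), "time": times, "lon": lon, "lat": lat,
        "sst_c": sst, "chl": chl,
    })
    profile_truth = pd.DataFrame({
        "profile_id": np.arange(n),
        "inside_eddy_id": inside_id,
        "effect_factor": effect_factor,
        "noise_factor": noise,
        "true_column_total": true_totals,
    })
    return profiles, surface, profile_truth


def generate_bundle(config: SyntheticConfig):
    """Atlas + auto-planned survey track + profiles + surface samples."""
    atlas, truth = generate_eddy_atlas(config)
    plan = (config.track_plan if config.track_plan is not None
            else survey_track_plan(atlas, ship_speed_kmh=config.ship_speed_kmh))
    track = generate_track(config, plan)
    profiles, surface, profile_truth = generate_profiles(track, atlas, truth, config)
    return {"atlas": atlas, "truth": truth, "track": track,
            "profiles": profiles, "surface": surface, "profile_truth": profile_truth}


def simulate_classification_experiment(n_eddies: int, fraction_effect: float,
                                       effect_size: float, noise_cv: float,
                                       n_inside: int = 30, n_outside: int = 30,
                                       layer: str = "epipelagic", seed: int = 0,
                                       alpha: float = 0.05,
                                       stratify: bool = True) -> pd.DataFrame:
    """Monte-Carlo eddy-classification experiment at the sample level.

    Draws, for each simulated eddy, `n_inside` inside and `n_outside`
    control per-profile layer values from the generator's column model
    (per-profile lognormal noise multiplies the whole column, so a layer
    mean is the noiseless layer mean times the profile's noise factor),
    splits them half day / half night, and classifies the eddy with the
    stratified rank-sum test. Used for type-I and power/recovery studies
    where full ship-track geometry adds nothing.

    Returns one row per eddy: has_effect, outcome, p_value, statistic.
    """
    from .classify import classify_samples

    config = SyntheticConfig()
    day_col, night_col = day_night_profiles(config)
    from .anomaly import layer_mask
    mask = layer_mask(layer)
    base = {"day": float(day_col[mask].mean()), "night": float(night_col[mask].mean())}
    rng = np.random.default_rng([int(seed) % (2**31), 3])
    n_effect = int(round(fraction_effect * n_eddies))
    rows = []
    for i in range(n_eddies):
        has_effect = i < n_effect
        factor = effect_size if has_effect else 1.0
        inside, outside = {}, {}
        for side, store, n_side, f in (("in", inside, n_inside, factor),
                                       ("out", outside, n_outside, 1.0)):
            n_day = n_side // 2
            for per, k in (("day", n_day), ("night", n_side - n_day)):
                store[per] = base[per] * f * lognormal_factors(rng, noise_cv, k)
        outcome, p, statistic = classify_samples(inside, outside, alpha=alpha,
                                                 stratify=stratify)
        rows.append({"eddy_id": i, "has_effect": has_effect, "outcome": outcome,
                     "p_value": p, "statistic": statistic})
    return pd.DataFrame(rows)
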