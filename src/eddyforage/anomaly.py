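"""Per-eddy inside/outside mean profiles and relative anomalies.

For each sampled eddy the mean NASC vertical profile is computed inside the
effective contour and in the control ribbon, separately for day and night
(so diel vertical migration never mixes into the comparison), and the
relative anomaly is

    anomaly = (mean inside - mean outside) / mean outside

per 10-m bin. When both day and night matched pairs exist the final anomaly
is the unweighted mean of the two period anomalies. Layer anomalies use the
epipelagic (20-200 m usable; nominal 0-200 m) and mesopelagic (200-750 m)
strata. SST and chlorophyll anomalies use the same relative form on the
along-track surface samples (an additive option in degrees C is exposed for
SST). Across-eddy aggregates report mean, sample sd, n and the 95% normal
confidence half-width 1.96*sd/sqrt(n).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acoustics import BIN_CENTERS_M, NASC_COLUMNS

#: Layer bounds in meters; bins whose centers fall in [lo, hi) contribute.
LAYERS = {"epipelagic": (0.0, 200.0), "mesopelagic": (200.0, 750.0)}
PERIODS = ("day", "night")


def layer_mask(layer) -> np.ndarray:
    """Boolean mask over the 73 bin centers for a named or custom layer."""
    if isinstance(layer, str):
        try:
            lo, hi = LAYERS[layer]
        except KeyError:
            raise ValueError(f"unknown layer {layer!r}; use {sorted(LAYERS)} or (lo, hi)")
    else:
        lo, hi = layer
    mask = (BIN_CENTERS_M >= lo) & (BIN_CENTERS_M < hi)
    if not mask.any():
        raise ValueError(f"layer ({lo}, {hi}) contains no depth bins")
    return mask


def nasc_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """(n_profiles, 73) float array of NASC values."""
    return profiles[NASC_COLUMNS].to_numpy(dtype=float)


def mean_profile(profiles: pd.DataFrame, period: str | None = None):
    """Per-bin arithmetic mean over profiles (optionally one period).

    Returns (mean, n) arrays of length 73; bins with no data are NaN with
    n = 0. Raises on an empty selection.
    """
    sel = profiles if period is None else profiles[profiles["period"] == period]
    if sel.empty:
        raise ValueError(f"no profiles for period {period!r}")
    m = nasc_matrix(sel)
    n = np.sum(np.isfinite(m), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nanmean(np.where(np.isfinite(m), m, np.nan), axis=0), np.nan)
    return mean, n


def anomaly_profile(inside_mean, outside_mean):
    """Relative anomaly (in - out)/out per bin.

    Bins where either side is missing or the outside mean is <= 0 are NaN;
    the number of such zero-denominator bins is returned as a flag count.
    """
    inside_mean = np.asarray(inside_mean, dtype=float)
    outside_mean = np.asarray(outside_mean, dtype=float)
    if inside_mean.shape != outside_mean.shape:
        raise ValueError("inside and outside profiles are on different bin grids")
    bad_denominator = np.isfinite(outside_mean) & (outside_mean <= 0)
    valid = np.isfinite(inside_mean) & np.isfinite(outside_mean) & ~bad_denominator
    if not valid.any():
        raise ValueError("no bin has both inside and outside data")
    out = np.full_like(inside_mean, np.nan)
    out[valid] = inside_mean[valid] / outside_mean[valid] - 1.0
    return out, int(bad_denominator.sum())


def layer_values(profiles: pd.DataFrame, layer) -> np.ndarray:
    """Per-profile unweighted mean NASC over a depth layer.

    One value per profile; these feed the per-eddy rank tests. `layer` is
    'epipelagic', 'mesopelagic' or a (lo, hi) tuple in meters (centers in
    [lo, hi) contribute, e.g. (400, 600) for the mid-mesopelagic check).
    """
    mask = layer_mask(layer)
    m = nasc_matrix(profiles)[:, mask]
    with np.errstate(invalid="ignore"):
        return np.nanmean(m, axis=1)


def surface_anomaly(inside_samples, outside_samples, mode: str = "relative") -> float:
    """Eddy surface signature from along-track samples.

    relative: (mean_in - mean_out)/mean_out (dimensionless, used for Chl and
    for SST when expressed as a relative signal); additive: mean_in -
    mean_out (degrees C for SST).
    """
    x = np.asarray(inside_samples, dtype=float)
    y = np.asarray(outside_samples, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both inside and outside samples are required")
    if mode == "additive":
        return float(np.mean(x) - np.mean(y))
    if mode != "relative":
        raise ValueError("mode must be 'relative' or 'additive'")
    out_mean = float(np.mean(y))
    if out_mean <= 0:
        raise ValueError("outside mean <= 0: relative anomaly undefined")
    return float(np.mean(x) / out_mean - 1.0)


def eddy_anomaly(sampled) -> dict:
    """Full anomaly record for one sampled eddy.

    Period coherence is structural: day inside means are only ever divided
    by day outside means (and night by night); periods present on only one
    side are skipped. The final per-bin and per-layer anomalies average the
    available period anomalies with equal weight.

    Returns a dict with per-bin arrays ('inside_mean', 'outside_mean',
    'anomaly', 'n_in', 'n_out'), per-layer anomalies, and the periods used.
    """
    period_anoms, period_layers = {}, {}
    inside_means, outside_means = {}, {}
    n_in_total = np.zeros(len(BIN_CENTERS_M), dtype=int)
    n_out_total = np.zeros(len(BIN_CENTERS_M), dtype=int)
    for period in PERIODS:
        ins = sampled.inside[sampled.inside["period"] == period]
        out = sampled.control[sampled.control["period"] == period]
        if ins.empty or out.empty:
            continue
        in_mean, n_in = mean_profile(ins)
        out_mean, n_out = mean_profile(out)
        anom, _ = anomaly_profile(in_mean, out_mean)
        period_anoms[period] = anom
        inside_means[period], outside_means[period] = in_mean, out_mean
        n_in_total += n_in
        n_out_total += n_out
        layers = {}
        for name in LAYERS:
            mask = layer_mask(name)
            li = np.nanmean(in_mean[mask])
            lo = np.nanmean(out_mean[mask])
            layers[name] = li / lo - 1.0 if np.isfinite(lo) and lo > 0 else np.nan
        period_layers[period] = layers
    if not period_anoms:
        raise ValueError(f"eddy {sampled.eddy_id}: no period with matched inside and control data")
    with np.errstate(invalid="ignore"):
        anomaly = np.nanmean(np.vstack(list(period_anoms.values())), axis=0)
        inside_mean = np.nanmean(np.vstack(list(inside_means.values())), axis=0)
        outside_mean = np.nanmean(np.vstack(list(outside_means.values())), axis=0)
    layer_anoms = {
        name: float(np.nanmean([period_layers[p][name] for p in period_layers]))
        for name in LAYERS
    }
    return {
        "eddy_id": sampled.eddy_id, "polarity": sampled.polarity,
        "inside_mean": inside_mean, "outside_mean": outside_mean,
        "anomaly": anomaly, "n_in": n_in_total, "n_out": n_out_total,
        "layer_anomalies": layer_anoms, "periods_used": tuple(period_anoms),
    }


def aggregate(anomaly_arrays, n_min: int = 1) -> pd.DataFrame:
    """Across-eddy per-bin aggregate: mean, sd (n-1), n, 95% CI half-width.

    `anomaly_arrays` is a sequence of per-bin anomaly vectors (one per
    eddy). With a single contributing eddy the CI is NaN (flagged by n).
    """
    arrs = np.vstack(list(anomaly_arrays))
    if arrs.shape[0] < 1:
        raise ValueError("need at least one eddy")
    n = np.sum(np.isfinite(arrs), axis=0)
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # n=1 bins: sd undefined, flagged NaN
        mean = np.where(n >= n_min, np.nanmean(arrs, axis=0), np.nan)
        sd = np.where(n >= 2, np.nanstd(arrs, axis=0, ddof=1), np.nan)
    ci = 1.96 * sd / np.sqrt(np.maximum(n, 1))
    return pd.DataFrame({
        "bin_center_m": BIN_CENTERS_M, "mean_anomaly": mean,
        "sd": sd, "n": n, "ci95_half_width": ci,
    })
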