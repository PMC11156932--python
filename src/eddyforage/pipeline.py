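"""End-to-end orchestration: atlas -> prep -> collocation -> anomaly -> classify.

`run_pipeline` executes the whole chain from either a synthetic config or
CSV inputs, applies every filter with its conventional default (alpha 0.05,
minimum lifespan 14 d, minimum seabed 1000 m, twilight band [-18, 0] deg,
30% zone bands, control ribbon at 2x the effective radius), and writes the
output tables plus a JSON run manifest with the filter-stage counts. The
same config and seed reproduce the outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustics, anomaly, atlas as atlas_mod, classify, collocation
from .synthetic import SyntheticConfig, generate_bundle

CLASSIFY_VARIABLES = ("nasc_epipelagic", "nasc_mesopelagic", "sst", "chl")


@dataclasses.dataclass
class PipelineConfig:
    synthetic: SyntheticConfig | None = None
    atlas_path: str | None = None
    profiles_path: str | None = None
    surface_path: str | None = None
    alpha: float = 0.05
    min_lifespan_days: int = 14
    min_seabed_m: float = 1000.0
    ribbon_factor: float = 2.0
    control_guard: bool = True
    trapping_definition: str = "U_over_c"
    stratify_periods: bool = True
    drop_unknown_seabed: bool = False
    grid_cell_degrees: float = 3.0
    out_dir: str | None = None


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        bundle = generate_bundle(config.synthetic)
        return bundle["atlas"], bundle["profiles"], bundle["surface"], bundle
    if not (config.atlas_path and config.profiles_path):
        raise ValueError("either a synthetic config or atlas/profiles paths are required")
    atl = atlas_mod.read_atlas(config.atlas_path)
    profiles = acoustics.read_profiles(config.profiles_path)
    surface = pd.read_csv(config.surface_path) if config.surface_path else None
    return atl, profiles, surface, None


def eddy_characteristics_table(sampled_eddies, atl: pd.DataFrame,
                               anomalies: list, trapping: pd.Series,
                               surface_anoms: dict) -> pd.DataFrame:
    """Six characteristics per retained eddy: amplitude, trapping, area,
    SST anomaly, Chl anomaly, age — evaluated on the days the eddy was
    sampled inside (means over those daily records)."""
    rows = []
    for se in sampled_eddies:
        days = pd.DatetimeIndex(se.inside["time"]).tz_convert("UTC").normalize().tz_localize(None)
        recs = atl[(atl["eddy_id"] == se.eddy_id) & (atl["date"].isin(set(days)))]
        if recs.empty:
            recs = atl[atl["eddy_id"] == se.eddy_id]
        ages = [(d - f).days for d, f in zip(recs["date"], recs["first_detection_date"])]
        sa = surface_anoms.get(se.eddy_id, {})
        rows.append({
            "eddy_id": se.eddy_id,
            "amplitude_m": float(recs["amplitude_m"].mean()),
            "trapping": float(trapping.loc[recs.index].replace(np.inf, np.nan).mean()),
            "effective_area_km2": float(recs["effective_area_km2"].mean()),
            "sst_anomaly": sa.get("sst_rel", np.nan),
            "chl_anomaly": sa.get("chl_rel", np.nan),
            "age_days": float(np.mean(ages)),
        })
    return pd.DataFrame(rows)


def summarize_grid(eddy_table: pd.DataFrame, cell_degrees: float = 3.0):
    """Gridded percentage of significant eddies.

    `eddy_table` needs lon, lat (the eddy's representative position: mean of
    its inside-profile positions) and a boolean `significant` column
    (increase or decrease, combined). Cells are anchored at (-180, -90);
    empty cells are omitted. Returns (grid, latitudinal marginal).
    """
    t = eddy_table.copy()
    t["cell_lon"] = np.floor((t["lon"] + 180.0) / cell_degrees) * cell_degrees - 180.0
    t["cell_lat"] = np.floor((t["lat"] + 90.0) / cell_degrees) * cell_degrees - 90.0
    grid = (t.groupby(["cell_lon", "cell_lat"])
            .agg(n_eddies=("significant", "size"), n_significant=("significant", "sum"))
            .reset_index())
    grid["pct_significant"] = 100.0 * grid["n_significant"] / grid["n_eddies"]
    lat = (t.groupby("cell_lat")
           .agg(n_eddies=("significant", "size"), n_significant=("significant", "sum"))
           .reset_index())
    lat["pct_significant"] = 100.0 * lat["n_significant"] / lat["n_eddies"]
    return grid, lat


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns every intermediate and final table.

    Stages: read/filter atlas (lifespan >= 14 d) -> prepare profiles
    (twilight and shelf exclusions) -> collocate (inside zones, control
    ribbon, retention rule) -> per-eddy anomalies -> per-eddy rank-sum
    classification -> proportions, characteristic comparisons, 3-degree
    grid summary. Writes CSVs and a manifest when `config.out_dir` is set.
    """
    counts = {}
    atl, profiles, surface, bundle = _load_inputs(config)
    counts["atlas_records"] = len(atl)
    counts["atlas_eddies"] = int(atl["eddy_id"].nunique()) if len(atl) else 0

    atl = atlas_mod.filter_lifespan(atl, config.min_lifespan_days)
    counts["atlas_eddies_lifespan_ok"] = int(atl["eddy_id"].nunique()) if len(atl) else 0
    trapping = atlas_mod.compute_trapping(atl, definition=config.trapping_definition)

    if "period" not in profiles.columns:
        profiles = acoustics.annotate_period(profiles)
    counts["profiles_raw"] = len(profiles)
    profiles = acoustics.filter_profiles(profiles, config.min_seabed_m,
                                         drop_unknown_seabed=config.drop_unknown_seabed)
    counts["profiles_retained"] = len(profiles)

    if surface is not None:
        profiles = profiles.merge(surface[["profile_id", "sst_c", "chl"]],
                                  on="profile_id", how="left")

    colloc = collocation.collocate_profiles(profiles, atl, guard=config.control_guard,
                                            ribbon_factor=config.ribbon_factor)
    counts["profiles_inside"] = int((colloc["relation"] == "inside").sum())
    counts["profiles_control"] = int((colloc["relation"] == "control").sum())

    sampled, drop_log = collocation.build_sampled_eddies(colloc, profiles, atl)
    counts["eddies_sampled"] = len(sampled) + len(drop_log)
    counts["eddies_retained"] = len(sampled)

    anomalies = []
    surface_anoms = {}
    matched = []
    for se in sampled:
        try:
            a = anomaly.eddy_anomaly(se)
        except ValueError:
            # inside and control profiles exist but never in the same
            # day/night period: the coherent comparison is undefined
            drop_log = pd.concat([drop_log, pd.DataFrame(
                [{"eddy_id": se.eddy_id, "reason": "no matched day/night period"}])],
                ignore_index=True)
            continue
        matched.append(se)
        anomalies.append(a)
    sampled = matched
    counts["eddies_retained"] = len(sampled)
    for se in sampled:
        sa = {}
        if "sst_c" in se.inside.columns and se.inside["sst_c"].notna().any():
            sa["sst_rel"] = anomaly.surface_anomaly(se.inside["sst_c"], se.control["sst_c"])
            sa["sst_additive_c"] = anomaly.surface_anomaly(
                se.inside["sst_c"], se.control["sst_c"], mode="additive")
            sa["chl_rel"] = anomaly.surface_anomaly(se.inside["chl"], se.control["chl"])
        surface_anoms[se.eddy_id] = sa

    results = []
    for se in sampled:
        for var in CLASSIFY_VARIABLES:
            res = classify.classify_eddy(se, var, alpha=config.alpha,
                                         stratify=config.stratify_periods)
            if res is not None:
                results.append(res)
    results_df = classify.results_table(results)
    polarity_by_id = {se.eddy_id: se.polarity for se in sampled}
    if not results_df.empty:
        results_df["polarity"] = results_df["eddy_id"].map(polarity_by_id)

    anom_rows = []
    for a in anomalies:
        for var, layer in (("nasc_epipelagic", "epipelagic"), ("nasc_mesopelagic", "mesopelagic")):
            anom_rows.append({"eddy_id": a["eddy_id"], "variable": var,
                              "anomaly": a["layer_anomalies"][layer]})
        sa = surface_anoms.get(a["eddy_id"], {})
        if "sst_rel" in sa:
            anom_rows.append({"eddy_id": a["eddy_id"], "variable": "sst",
                              "anomaly": sa["sst_rel"]})
            anom_rows.append({"eddy_id": a["eddy_id"], "variable": "chl",
                              "anomaly": sa["chl_rel"]})
    layer_anom_df = pd.DataFrame(anom_rows, columns=["eddy_id", "variable", "anomaly"])

    proportions = (classify.summarize_proportions(results_df, layer_anom_df)
                   if not results_df.empty else pd.DataFrame())

    characteristics = eddy_characteristics_table(sampled, atl, anomalies, trapping,
                                                 surface_anoms)
    epi = results_df[results_df["variable"] == "nasc_epipelagic"] if not results_df.empty \
        else pd.DataFrame(columns=["eddy_id", "outcome"])
    comparison = (classify.compare_characteristics(epi, characteristics, alpha=config.alpha)
                  if not epi.empty else pd.DataFrame())

    eddy_positions = []
    sig_by_id = {}
    if not epi.empty:
        sig_by_id = {r["eddy_id"]: r["outcome"] != "null" for _, r in epi.iterrows()}
    for se in sampled:
        eddy_positions.append({
            "eddy_id": se.eddy_id, "polarity": se.polarity,
            "lon": float(se.inside["lon"].mean()), "lat": float(se.inside["lat"].mean()),
            "significant": bool(sig_by_id.get(se.eddy_id, False)),
        })
    eddy_pos_df = pd.DataFrame(eddy_positions,
                               columns=["eddy_id", "polarity", "lon", "lat", "significant"])
    if not eddy_pos_df.empty:
        grid, lat_marginal = summarize_grid(eddy_pos_df, config.grid_cell_degrees)
    else:
        grid, lat_marginal = pd.DataFrame(), pd.DataFrame()

    per_bin_rows = []
    for a in anomalies:
        for j, bc in enumerate(anomaly.BIN_CENTERS_M):
            per_bin_rows.append({
                "eddy_id": a["eddy_id"], "polarity": a["polarity"], "bin_center_m": bc,
                "inside_mean": a["inside_mean"][j], "outside_mean": a["outside_mean"][j],
                "anomaly": a["anomaly"][j], "n_in": a["n_in"][j], "n_out": a["n_out"][j],
                "period_coverage": "+".join(a["periods_used"]),
            })
    anomaly_table = pd.DataFrame(per_bin_rows)

    aggregates = {}
    for pol in ("AE", "CE"):
        arrs = [a["anomaly"] for a in anomalies if a["polarity"] == pol]
        if arrs:
            aggregates[pol] = anomaly.aggregate(arrs)

    out = {
        "config": config, "counts": counts, "atlas": atl, "trapping": trapping,
        "profiles": profiles, "collocation": colloc, "sampled_eddies": sampled,
        "drop_log": drop_log, "anomalies": anomalies, "anomaly_table": anomaly_table,
        "layer_anomalies": layer_anom_df, "aggregates": aggregates,
        "classifications": results_df, "proportions": proportions,
        "characteristics": characteristics, "comparison": comparison,
        "eddy_positions": eddy_pos_df, "grid": grid, "lat_marginal": lat_marginal,
        "bundle": bundle,
    }
    if config.out_dir is not None:
        write_outputs(out, config.out_dir)
    return out


def _config_to_jsonable(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def write_outputs(out: dict, out_dir) -> None:
    """Write the pipeline tables as CSV plus a JSON run manifest."""
    p = Path(out_dir)
    p.mkdir(parents=True, exist_ok=True)
    tables = ["collocation", "anomaly_table", "layer_anomalies", "classifications",
              "proportions", "characteristics", "comparison", "eddy_positions",
              "grid", "lat_marginal", "drop_log"]
    for name in tables:
        df = out[name]
        if isinstance(df, pd.DataFrame):
            df.to_csv(p / f"{name}.csv", index=False)
    for pol, agg in out["aggregates"].items():
        agg.to_csv(p / f"aggregate_{pol}.csv", index=False)
    manifest = {
        "config": _config_to_jsonable(out["config"]),
        "counts": out["counts"],
        "retained_eddy_ids": [str(se.eddy_id) for se in out["sampled_eddies"]],
    }
    (p / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
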