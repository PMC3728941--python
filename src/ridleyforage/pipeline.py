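"""End-to-end orchestration of the foraging-area analysis.

Stages communicate through plain-text files in a workspace directory, so
every stage can be run on its own (via the CLI) or chained by
:func:`run_pipeline`:

    simulate -> fit-ssm -> segment -> homerange -> fidelity -> grid-glm -> report

Outputs: ``tracks.csv``, environment rasters (ESRI ASCII) and coast
polygons (GeoJSON), ``statepaths.csv``, ``sites.csv`` with KDE/fidelity
columns, ``grid.csv``, ``glm.csv`` and ``summary.json`` - every summary
number is recomputable from the per-stage tables.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import fidelity as fid
from . import habitat_glm as hg
from . import home_range as hr
from . import segmentation as seg
from . import ssm as ssm_mod
from . import summaries, synthetic, track_io
from .geo import distance_to_polygon_km, project_points
from .raster import Raster

log = logging.getLogger("ridleyforage")


@dataclass
class PipelineConfig:
    workspace: str = "ridleyforage_run"
    seed: int = 0
    # simulation
    n_turtles: int = 5
    duration_days: float | None = None   # None: drawn uniformly in [98, 342]
    # SSM
    ssm_preset: str = "desk"             # "desk" or "full"
    # thresholds
    mode_cutoff: float = 1.5
    min_kde_days: float = 20.0
    min_period_days: float = 2.0
    fidelity_threshold: float = 95.0
    max_speed_kmh: float = 10.0
    depth_limit_m: float = 100.0
    cell_km: float = 25.0
    subsample_fraction: float = 0.2
    fidelity_replicates: int = 100
    min_site_points: int = 10            # daily locations needed for KDE/fidelity

    def ssm_config(self, seed: int) -> ssm_mod.SSMConfig:
        if self.ssm_preset == "tiny":  # smoke-test scale
            return ssm_mod.SSMConfig(n_iterations=400, burn_in=300, thin=1,
                                     seed=seed, mode_cutoff=self.mode_cutoff)
        if self.ssm_preset == "desk":
            return ssm_mod.SSMConfig.desk_scale(seed=seed, mode_cutoff=self.mode_cutoff)
        return ssm_mod.SSMConfig(seed=seed, mode_cutoff=self.mode_cutoff)


def _ws(config) -> Path:
    p = Path(config.workspace)
    p.mkdir(parents=True, exist_ok=True)
    return p


def load_environment(ws: Path) -> synthetic.EnvironmentFields:
    bathy = Raster.from_ascii(ws / "bathymetry.asc")
    return synthetic.EnvironmentFields(
        bathymetry=bathy,
        sst=Raster.from_ascii(ws / "sst.asc"),
        npp=Raster.from_ascii(ws / "npp.asc"),
        coastline=shapely.from_geojson((ws / "coastline.geojson").read_text()),
        mainland=shapely.from_geojson((ws / "mainland.geojson").read_text()),
        bounds=bathy.bounds)


def stage_simulate(config: PipelineConfig) -> None:
    """Generate the environment and the synthetic study tracks."""
    ws = _ws(config)
    env = synthetic.generate_environment(seed=config.seed)
    env.bathymetry.to_ascii(ws / "bathymetry.asc")
    env.sst.to_ascii(ws / "sst.asc")
    env.npp.to_ascii(ws / "npp.asc")
    (ws / "coastline.geojson").write_text(shapely.to_geojson(env.coastline))
    (ws / "mainland.geojson").write_text(shapely.to_geojson(env.mainland))
    sim = synthetic.SimConfig(n_turtles=config.n_turtles,
                              duration_days=config.duration_days, seed=config.seed)
    truths, tracks = synthetic.simulate_study(sim, env=env)
    track_io.write_tracks(tracks, ws / "tracks.csv")
    truth_rows = []
    for tt in truths:
        truth_rows.append(pd.DataFrame({
            "turtle_id": tt.turtle_id, "time": tt.times, "lon": tt.lon,
            "lat": tt.lat, "state": tt.states}))
    pd.concat(truth_rows).to_csv(ws / "true_states.csv", index=False)
    log.info("simulate: %d turtles into %s", config.n_turtles, ws)


def stage_ssm(config: PipelineConfig) -> None:
    """Filter each track and fit the switching DCRW."""
    ws = _ws(config)
    env = load_environment(ws)
    tracks = track_io.read_argos_table(ws / "tracks.csv")
    paths, posts, travel = [], [], []
    for i, tr in enumerate(tracks):
        tr.release_lon, tr.release_lat = synthetic.DEFAULT_RELEASE
        ftr = track_io.filter_fixes(tr, env=env, max_speed_kmh=config.max_speed_kmh)
        post, path, diag = ssm_mod.fit_switching_dcrw(
            ftr, config.ssm_config(seed=(config.seed * 1009 + 7 * i) & 0x7FFFFFFF))
        log.info("ssm: %s converged=%s", tr.turtle_id, diag["converged"])
        df = path.to_frame()
        df.insert(0, "turtle_id", tr.turtle_id)
        paths.append(df)
        p = post.reset_index(names="parameter")
        p.insert(0, "turtle_id", tr.turtle_id)
        posts.append(p)
        straight, total = track_io.travel_distances(ftr)
        travel.append({"turtle_id": tr.turtle_id, "straight_line_km": straight,
                       "total_path_km": total, "tracking_days": ftr.duration_days,
                       "n_fixes": len(ftr)})
    pd.concat(paths).to_csv(ws / "statepaths.csv", index=False)
    pd.concat(posts).to_csv(ws / "posteriors.csv", index=False)
    pd.DataFrame(travel).to_csv(ws / "travel.csv", index=False)


def _load_statepaths(ws: Path, config) -> dict[str, ssm_mod.StatePath]:
    df = pd.read_csv(ws / "statepaths.csv", parse_dates=["time"])
    out = {}
    for tid, g in df.groupby("turtle_id", sort=True):
        g = g.sort_values("time")
        out[str(tid)] = ssm_mod.StatePath(
            turtle_id=str(tid), times=pd.DatetimeIndex(g["time"]),
            lon=g["lon"].to_numpy(), lat=g["lat"].to_numpy(),
            lon_lo=g["lon_lo"].to_numpy(), lon_hi=g["lon_hi"].to_numpy(),
            lat_lo=g["lat_lo"].to_numpy(), lat_hi=g["lat_hi"].to_numpy(),
            x_km=np.zeros(len(g)), y_km=np.zeros(len(g)),
            b_mean=g["b_mean"].to_numpy(), mode=g["mode"].to_numpy(),
            step_hours=8.0)
    return out


def stage_segment(config: PipelineConfig) -> None:
    """Segment behavior, label foraging sites, build the foraging-day table."""
    ws = _ws(config)
    env = load_environment(ws)
    tracks = {t.turtle_id: t for t in track_io.read_argos_table(ws / "tracks.csv")}
    site_rows, daily_rows, fday = [], [], []
    for tid, path in _load_statepaths(ws, config).items():
        segments = seg.segment_behavior(path)
        sites = seg.label_foraging_sites(segments, min_kde_days=config.min_kde_days)
        seg.attach_site_data(sites, tracks[tid], env=env,
                             depth_limit_m=config.depth_limit_m)
        for s in sites:
            site_rows.append({
                "turtle_id": tid, "label": s.label, "start": s.segment.start,
                "end": s.segment.end, "arrival": s.arrival,
                "duration_days": s.duration_days,
                "n_daily_locations": len(s.daily_locations)})
            d = s.daily_locations.copy()
            d.insert(0, "turtle_id", tid)
            d.insert(1, "label", s.label)
            daily_rows.append(d)
        fday.append(seg.foraging_day_table(path, segments, tracks[tid], env=env))
    pd.DataFrame(site_rows).to_csv(ws / "sites.csv", index=False)
    pd.concat(daily_rows, ignore_index=True).to_csv(ws / "site_daily_locations.csv", index=False) \
        if daily_rows else pd.DataFrame().to_csv(ws / "site_daily_locations.csv")
    pd.concat(fday, ignore_index=True).to_csv(ws / "foraging_days.csv", index=False)


def stage_homerange(config: PipelineConfig) -> None:
    """50% KDE core areas, centroids and centroid-based distances per site."""
    ws = _ws(config)
    env = load_environment(ws)
    sites = pd.read_csv(ws / "sites.csv")
    daily = pd.read_csv(ws / "site_daily_locations.csv")
    cols = {c: [] for c in ["area_km2", "centroid_lon", "centroid_lat",
                            "bathymetry_m", "dist_nearest_land_km", "dist_mainland_km"]}
    geoms = []
    for _, row in sites.iterrows():
        pts = daily[(daily["turtle_id"] == row["turtle_id"]) & (daily["label"] == row["label"])]
        if len(pts) < config.min_site_points:
            for c in cols:
                cols[c].append(np.nan)
            continue
        xy = project_points(pts[["lon", "lat"]].to_numpy(), env.projection)
        try:
            h = hr.lscv_bandwidth(xy)
            core = hr.kde_core_area(xy, h, env=env)
        except ValueError as exc:
            log.warning("homerange: %s/%s skipped (%s)", row["turtle_id"], row["label"], exc)
            for c in cols:
                cols[c].append(np.nan)
            continue
        lon, lat = core.centroid_lonlat
        cols["area_km2"].append(core.in_water_area_km2)
        cols["centroid_lon"].append(lon)
        cols["centroid_lat"].append(lat)
        cols["bathymetry_m"].append(core.bathymetry_at_centroid_m)
        cols["dist_nearest_land_km"].append(distance_to_polygon_km((lon, lat), env.coastline, env.projection))
        cols["dist_mainland_km"].append(distance_to_polygon_km((lon, lat), env.mainland, env.projection))
        geoms.append({"turtle_id": row["turtle_id"], "label": row["label"],
                      "geometry": json.loads(shapely.to_geojson(core.in_water_polygons_km))})
    for c, v in cols.items():
        sites[c] = v
    sites.to_csv(ws / "sites.csv", index=False)
    (ws / "core_areas.geojson").write_text(json.dumps(
        {"type": "FeatureCollection",
         "features": [{"type": "Feature", "properties": {k: g[k] for k in ("turtle_id", "label")},
                       "geometry": g["geometry"]} for g in geoms]}))


def stage_fidelity(config: PipelineConfig) -> None:
    """Constrained-random-walk fidelity test per delineated site."""
    ws = _ws(config)
    env = load_environment(ws)
    sites = pd.read_csv(ws / "sites.csv")
    daily = pd.read_csv(ws / "site_daily_locations.csv")
    prop, verdict = [], []
    for _, row in sites.iterrows():
        pts = daily[(daily["turtle_id"] == row["turtle_id"]) & (daily["label"] == row["label"])]
        if len(pts) < config.min_site_points:
            prop.append(np.nan)
            verdict.append(None)
            continue
        xy = project_points(pts[["lon", "lat"]].to_numpy(), env.projection)
        try:
            res = fid.site_fidelity_test(
                xy, env, n_replicates=config.fidelity_replicates,
                seed=(config.seed * 2003
                      + zlib.crc32(f"{row['turtle_id']}|{row['label']}".encode())) & 0x7FFFFFFF,
                threshold=config.fidelity_threshold,
                turtle_id=str(row["turtle_id"]), site_label=row["label"])
            prop.append(res.proportion_higher)
            verdict.append(bool(res.fidelity))
        except ValueError as exc:
            log.warning("fidelity: %s/%s skipped (%s)", row["turtle_id"], row["label"], exc)
            prop.append(np.nan)
            verdict.append(None)
    sites["proportion_higher"] = prop
    sites["fidelity"] = verdict
    sites.to_csv(ws / "sites.csv", index=False)
    # Table-1-style layout: turtle x site-class proportions
    if len(sites):
        pivot = sites.pivot_table(index="turtle_id", columns="label",
                                  values="proportion_higher", aggfunc="first")
        pivot.to_csv(ws / "fidelity_table.csv")


def stage_grid(config: PipelineConfig) -> None:
    """25-km grid counts and the habitat GLM."""
    ws = _ws(config)
    env = load_environment(ws)
    fday = pd.read_csv(ws / "foraging_days.csv")
    cells, spec = hg.build_grid(env, cell_km=config.cell_km,
                                depth_limit_m=config.depth_limit_m,
                                release_points=[synthetic.DEFAULT_RELEASE])
    cells = hg.count_foraging_days(fday, cells, spec, env.projection,
                                   min_period_days=config.min_period_days)
    cells.to_csv(ws / "grid.csv")
    sub = hg.subsample_cells(cells, config.subsample_fraction, seed=config.seed)
    sub.to_csv(ws / "grid_subsample.csv")
    if sub["foraging_days"].sum() > 0 and len(sub) >= 20:
        fit = hg.fit_log_glm(sub)
        fit.table.reset_index(names="parameter").to_csv(ws / "glm.csv", index=False)
    else:
        log.warning("grid-glm: too few foraging days in the subsample; GLM skipped")


def stage_report(config: PipelineConfig) -> dict:
    """Assemble the run summary from the emitted per-stage tables."""
    ws = _ws(config)
    sites = pd.read_csv(ws / "sites.csv")
    travel = pd.read_csv(ws / "travel.csv")
    grid = pd.read_csv(ws / "grid.csv")
    foraging_days = float(sites["duration_days"].sum()) if len(sites) else 0.0
    total_days = float(travel["tracking_days"].sum())
    out = summaries.run_summary(sites, travel, total_days, foraging_days)
    out["grid_total_foraging_days"] = float(grid["foraging_days"].sum())
    out["n_grid_cells"] = int(len(grid))
    out["n_subsampled_cells"] = summaries.subsample_size(len(grid), config.subsample_fraction)
    if len(sites):
        faf = sites.dropna(subset=["proportion_higher"])
        out["n_sites_tested"] = int(len(faf))
        out["n_sites_fidelity"] = int((faf["fidelity"] == True).sum())  # noqa: E712
    (ws / "summary.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    return out


STAGES = {
    "simulate": stage_simulate,
    "fit-ssm": stage_ssm,
    "segment": stage_segment,
    "homerange": stage_homerange,
    "fidelity": stage_fidelity,
    "grid-glm": stage_grid,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the summary dict."""
    result = None
    for name, fn in STAGES.items():
        log.info("stage %s", name)
        result = fn(config)
    return result
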