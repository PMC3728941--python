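"""Summary-statistic layer: derived quantities from per-stage tables.

Every percentage or ratio the pipeline reports is recomputed here from the
underlying totals, never stored. The module also carries the published
aggregate totals from the 1998-2011 Gulf of Mexico Kemp's ridley
satellite-tracking study (31 post-nesting females tagged at Padre Island
National Seashore and Rancho Nuevo), against which the summary arithmetic
can be exercised and cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StudyTotals:
    """Aggregate totals of a tracking study's foraging-site analysis."""

    total_tracking_days: int
    foraging_days: int               # days at F+F1+F2+F3 sites combined
    mean_area_f_km2: float           # mean 50% KDE area of final (F) sites
    mean_area_f1_km2: float
    mean_area_f2_km2: float
    area_f3_km2: float
    daily_locations_f: int           # mean daily locations at F sites
    daily_locations_total: int       # at all foraging sites combined
    turtles_with_faf: int            # turtles showing foraging-area fidelity
    turtles_faf_usgom: int           # of those, in US Gulf waters
    n_grid_cells: int
    subsample_fraction: float


#: Published totals for the 31-turtle 1998-2011 Kemp's ridley study.
KEMPS_RIDLEY_1998_2011 = StudyTotals(
    total_tracking_days=6009,
    foraging_days=2641,
    mean_area_f_km2=660.8,
    mean_area_f1_km2=1314.7,
    mean_area_f2_km2=1739.0,
    area_f3_km2=1413.5,
    daily_locations_f=1215,
    daily_locations_total=1896,
    turtles_with_faf=24,
    turtles_faf_usgom=22,
    n_grid_cells=778,
    subsample_fraction=0.2,
)


def pct_days_foraging(foraging_days: float, total_days: float) -> float:
    """Percent of tracking days spent in foraging mode."""
    if total_days <= 0:
        raise ValueError("total_days must be positive")
    return 100.0 * foraging_days / total_days


def area_ratio(area_km2: float, reference_km2: float) -> float:
    """Ratio of a site-class mean area to the final-site mean area."""
    if reference_km2 <= 0:
        raise ValueError("reference area must be positive")
    return area_km2 / reference_km2


def pct_of_total(part: float, total: float) -> float:
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * part / total


def subsample_size(n_cells: int, fraction: float) -> int:
    """Number of grid cells in a ``fraction`` subsample (floor)."""
    return int(np.floor(fraction * n_cells))


def study_identities(totals: StudyTotals = KEMPS_RIDLEY_1998_2011) -> dict[str, float]:
    """All derived summary quantities for a set of study totals."""
    return {
        "pct_tracking_days_foraging": pct_days_foraging(
            totals.foraging_days, totals.total_tracking_days),
        "f1_f_area_ratio": area_ratio(totals.mean_area_f1_km2, totals.mean_area_f_km2),
        "f2_f_area_ratio": area_ratio(totals.mean_area_f2_km2, totals.mean_area_f_km2),
        "f3_f_area_ratio": area_ratio(totals.area_f3_km2, totals.mean_area_f_km2),
        "pct_daily_locations_at_f": pct_of_total(
            totals.daily_locations_f, totals.daily_locations_total),
        "pct_faf_usgom": pct_of_total(totals.turtles_faf_usgom, totals.turtles_with_faf),
        "n_subsampled_cells": subsample_size(totals.n_grid_cells, totals.subsample_fraction),
    }


def site_summary_table(all_sites: list) -> pd.DataFrame:
    """Per-site summary rows (turtle, label, arrival, days, locations, area)."""
    rows = []
    for site in all_sites:
        rows.append({
            "turtle_id": site.turtle_id,
            "label": site.label,
            "arrival": site.arrival,
            "duration_days": site.duration_days,
            "n_daily_locations": (len(site.daily_locations)
                                  if site.daily_locations is not None else 0),
            "area_km2": site.extras.get("core_area_km2", np.nan),
            "centroid_lon": site.extras.get("centroid_lon", np.nan),
            "centroid_lat": site.extras.get("centroid_lat", np.nan),
            "bathymetry_m": site.extras.get("bathymetry_m", np.nan),
            "dist_nearest_land_km": site.extras.get("dist_nearest_land_km", np.nan),
            "dist_mainland_km": site.extras.get("dist_mainland_km", np.nan),
            "proportion_higher": site.extras.get("proportion_higher", np.nan),
            "fidelity": site.extras.get("fidelity", None),
        })
    return pd.DataFrame(rows)


def run_summary(site_table: pd.DataFrame, travel: pd.DataFrame,
                total_tracking_days: float, foraging_days: float) -> dict[str, float]:
    """Top-level summary of one pipeline run, recomputed from its tables."""
    out = {
        "n_turtles": int(travel["turtle_id"].nunique()),
        "mean_straight_line_km": float(travel["straight_line_km"].mean()),
        "sd_straight_line_km": float(travel["straight_line_km"].std(ddof=1)),
        "mean_total_path_km": float(travel["total_path_km"].mean()),
        "total_tracking_days": float(total_tracking_days),
        "total_foraging_days": float(foraging_days),
        "pct_tracking_days_foraging": pct_days_foraging(foraging_days, total_tracking_days),
    }
    f = site_table[site_table["label"] == "F"]
    if len(f):
        out["mean_area_f_km2"] = float(f["area_km2"].mean())
        out["mean_dist_mainland_km"] = float(f["dist_mainland_km"].mean())
        out["mean_dist_nearest_land_km"] = float(f["dist_nearest_land_km"].mean())
    for lab in ("F1", "F2", "F3"):
        sub = site_table[site_table["label"] == lab]
        if len(sub) and len(f) and f["area_km2"].mean() > 0:
            out[f"{lab.lower()}_f_area_ratio"] = area_ratio(
                float(sub["area_km2"].mean()), float(f["area_km2"].mean()))
    return out
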