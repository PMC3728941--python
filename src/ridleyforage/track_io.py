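"""Reading, validation and filtering of Argos-style satellite fixes.

A :class:`Track` wraps one turtle's time-ordered fixes as a DataFrame with
columns ``time`` (UTC), ``lon``, ``lat``, ``lc`` and optionally
``true_state`` (for synthetic fixtures). Location classes follow the Argos
convention 3, 2, 1, 0, A, B (decreasing quality) plus the invalid class Z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import great_circle_km

VALID_LC = ["3", "2", "1", "0", "A", "B", "Z"]
#: Argos quality ordering used to break duplicate-timestamp ties (best first).
LC_QUALITY_ORDER = ["3", "2", "1", "0", "A", "B", "Z"]

TRACK_COLUMNS = ["turtle_id", "utc_timestamp", "lon", "lat", "lc"]


@dataclass
class Track:
    """One turtle's ordered satellite fixes plus release metadata."""

    turtle_id: str
    fixes: pd.DataFrame
    release_lon: float | None = None
    release_lat: float | None = None
    release_date: pd.Timestamp | None = None
    site: str | None = field(default=None)  # tagging-site label, e.g. PAIS / RN

    def __post_init__(self):
        self.fixes = self.fixes.reset_index(drop=True)
        if len(self.fixes) and not self.fixes["time"].is_monotonic_increasing:
            raise ValueError(f"track {self.turtle_id}: fix times must be increasing")

    def __len__(self):
        return len(self.fixes)

    @property
    def duration_days(self) -> float:
        t = self.fixes["time"]
        return (t.iloc[-1] - t.iloc[0]).total_seconds() / 86400.0


def _validate_fixes(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    bad_lc = ~df["lc"].isin(VALID_LC)
    bad_coord = (df["lat"].abs() > 90) | (df["lon"].abs() > 180) | df[["lon", "lat"]].isna().any(axis=1)
    bad = bad_lc | bad_coord
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{source}: unparseable/invalid rows at lines {lines[:10]}")
    return df


def read_argos_table(path, column_map: dict | None = None) -> list[Track]:
    """Read a delimited fix table into one :class:`Track` per turtle.

    The default dialect is the package's own export format (columns
    ``turtle_id, utc_timestamp, lon, lat, lc`` and optional ``true_state``);
    ``column_map`` renames foreign column names onto these. Duplicate
    timestamps within a turtle keep the better location class.
    """
    df = pd.read_csv(path, dtype={"lc": str})
    if column_map:
        df = df.rename(columns=column_map)
    if df.empty:
        warnings.warn(f"{path}: empty fix table")
        return []
    df["time"] = pd.to_datetime(df["utc_timestamp"], utc=True)
    df["lc"] = df["lc"].str.strip().str.upper()
    _validate_fixes(df, str(path))
    tracks = []
    for tid, grp in df.groupby("turtle_id", sort=True):
        grp = grp.copy()
        grp["_q"] = grp["lc"].map({c: i for i, c in enumerate(LC_QUALITY_ORDER)})
        grp = (grp.sort_values(["time", "_q"])
                  .drop_duplicates(subset="time", keep="first")
                  .drop(columns=["_q", "utc_timestamp", "turtle_id"]))
        keep = ["time", "lon", "lat", "lc"] + (["true_state"] if "true_state" in grp else [])
        tracks.append(Track(turtle_id=str(tid), fixes=grp[keep]))
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks to the package's delimited dialect (CSV)."""
    frames = []
    for tr in tracks:
        out = tr.fixes.copy()
        out.insert(0, "turtle_id", tr.turtle_id)
        out["utc_timestamp"] = out.pop("time").dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        cols = TRACK_COLUMNS + (["true_state"] if "true_state" in out else [])
        frames.append(out[cols])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def filter_fixes(track: Track, env=None, mode_context: str | np.ndarray | None = None,
                 max_speed_kmh: float = 10.0, depth_limit_m: float = 100.0) -> Track:
    """Remove implausible fixes.

    Always drops LC Z. With an environment, drops on-land fixes
    (bathymetry > 0) and — in foraging context — fixes in water deeper than
    ``depth_limit_m`` (depths beyond the shelf are not plausible for a
    foraging hard-shelled turtle). ``mode_context`` is either ``"foraging"``
    (rule applies to all fixes), ``"migration"``/None (rule off), or a
    boolean array flagging the foraging fixes. Finally, fixes requiring
    speed above ``max_speed_kmh`` from the previously retained fix are
    dropped (the later fix of the fast pair goes).

    The operation is idempotent: filtering an already-filtered track is a
    no-op.
    """
    df = track.fixes
    keep = df["lc"] != "Z"
    if env is not None:
        bathy = env.bathymetry.sample(df["lon"].to_numpy(), df["lat"].to_numpy())
        outside = ~np.isfinite(bathy)
        if outside.any():
            warnings.warn(f"track {track.turtle_id}: {int(outside.sum())} fixes outside raster coverage excluded")
        keep &= ~outside
        keep &= ~(bathy > 0)  # on land
        if mode_context is not None and not isinstance(mode_context, str):
            forag = np.asarray(mode_context, dtype=bool)
            keep &= ~(forag & (bathy < -depth_limit_m))
        elif mode_context == "foraging":
            keep &= ~(bathy < -depth_limit_m)
    df = df[keep].reset_index(drop=True)
    # greedy speed gate: keep a fix only if reachable from the last kept fix
    if len(df) > 1:
        t = df["time"].astype("int64").to_numpy() / 3.6e12  # hours
        lon, lat = df["lon"].to_numpy(), df["lat"].to_numpy()
        kept = [0]
        for i in range(1, len(df)):
            j = kept[-1]
            dt = t[i] - t[j]
            d = great_circle_km((lon[j], lat[j]), (lon[i], lat[i]))
            if dt <= 0 or d <= max_speed_kmh * dt:
                kept.append(i)
        df = df.iloc[kept].reset_index(drop=True)
    return Track(turtle_id=track.turtle_id, fixes=df, release_lon=track.release_lon,
                 release_lat=track.release_lat, release_date=track.release_date, site=track.site)


def mean_daily_locations(fixes: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic-mean coordinate per UTC calendar day with at least one fix.

    Averaging within days thins the data to roughly one point per day,
    reducing the temporal autocorrelation that would otherwise bias kernel
    density estimates.
    """
    if len(fixes) == 0:
        return pd.DataFrame(columns=["date", "lon", "lat", "n_fixes"])
    g = fixes.groupby(fixes["time"].dt.date)
    out = g.agg(lon=("lon", "mean"), lat=("lat", "mean"), n_fixes=("lon", "size"))
    out.index.name = "date"
    return out.reset_index()


def travel_distances(track: Track) -> tuple[float, float]:
    """(straight-line km, total path km) from release to the last fix.

    Straight-line is the great-circle release-to-end distance; total path
    sums successive great-circle legs, so total >= straight-line.
    """
    df = track.fixes
    if len(df) < 2:
        raise ValueError("travel distances need at least 2 fixes")
    pts = df[["lon", "lat"]].to_numpy()
    start = (track.release_lon, track.release_lat)
    if track.release_lon is None:
        start = tuple(pts[0])
        legs = great_circle_km(pts[:-1], pts[1:])
    else:
        allpts = np.vstack([start, pts])
        legs = great_circle_km(allpts[:-1], allpts[1:])
    straight = great_circle_km(start, tuple(pts[-1]))
    return float(straight), float(np.sum(legs))
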