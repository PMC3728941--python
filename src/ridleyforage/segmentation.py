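"""Behavioral segmentation: foraging periods and F/F1/F2/F3 site labels.

The per-node behavioral modes from the state-space model are collapsed
into maximal constant-mode runs. The last foraging period of a track is
the turtle's "final" (F) foraging site - unless the track ends while still
in migration, in which case no F site exists and labeling starts at F1.
Earlier qualifying foraging periods are labeled F1, F2, F3 walking
backward in time (sites used just prior to the final destination).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .track_io import Track, filter_fixes, mean_daily_locations

SITE_LABELS = ["F", "F1", "F2", "F3"]


@dataclass
class BehaviorSegment:
    turtle_id: str
    mode: str                  # "foraging" / "migration"
    start: pd.Timestamp
    end: pd.Timestamp
    node_slice: tuple[int, int]  # [start, stop) indices into the StatePath grid
    duration_days: float


@dataclass
class ForagingSite:
    turtle_id: str
    label: str                 # F, F1, F2 or F3
    segment: BehaviorSegment
    fixes: pd.DataFrame | None = None           # filtered raw fixes in the window
    daily_locations: pd.DataFrame | None = None  # mean daily locations
    extras: dict = field(default_factory=dict)   # KDE/fidelity results attach here

    @property
    def arrival(self):
        return arrival_date(self)

    @property
    def duration_days(self) -> float:
        return self.segment.duration_days


def segment_behavior(path) -> list[BehaviorSegment]:
    """Run-length encode a StatePath's mode labels into segments.

    Segment duration is node count x step / 24 h, so durations sum exactly
    to the grid span plus one trailing step.
    """
    modes = np.asarray(path.mode)
    if len(modes) == 0:
        return []
    out = []
    start = 0
    for i in range(1, len(modes) + 1):
        if i == len(modes) or modes[i] != modes[start]:
            out.append(BehaviorSegment(
                turtle_id=path.turtle_id, mode=str(modes[start]),
                start=path.times[start], end=path.times[i - 1],
                node_slice=(start, i),
                duration_days=(i - start) * path.step_hours / 24.0))
            start = i
    return out


def label_foraging_sites(segments: list[BehaviorSegment],
                         min_kde_days: float = 20.0) -> list[ForagingSite]:
    """Assign F / F1 / F2 / F3 labels to qualifying foraging periods.

    The final segment, if foraging, is F regardless of duration (it is the
    turtle's destination). Walking backward, earlier foraging segments of
    at least ``min_kde_days`` days get F1, F2, F3; shorter ones are skipped
    (they still count toward gridded foraging days elsewhere). At most four
    sites are labeled.
    """
    if not segments:
        return []
    sites = []
    rest = segments
    if segments[-1].mode == "foraging":
        sites.append(ForagingSite(turtle_id=segments[-1].turtle_id, label="F",
                                  segment=segments[-1]))
        rest = segments[:-1]
    prior = [s for s in reversed(rest)
             if s.mode == "foraging" and s.duration_days >= min_kde_days]
    start_i = 1  # F1 is the first label for sites before the final one
    for j, seg in enumerate(prior):
        idx = start_i + j
        if idx >= len(SITE_LABELS):
            break
        sites.append(ForagingSite(turtle_id=seg.turtle_id,
                                  label=SITE_LABELS[idx], segment=seg))
    return sites


def arrival_date(site: ForagingSite):
    """Calendar date of the first grid node of the site's foraging period."""
    return site.segment.start.date()


def attach_site_data(sites: list[ForagingSite], track: Track, env=None,
                     depth_limit_m: float = 100.0) -> list[ForagingSite]:
    """Fill each site with its filtered raw fixes and mean daily locations.

    Fixes within the site's time window are re-filtered in foraging context
    (the depth rule applies), then averaged per UTC day.
    """
    for site in sites:
        seg = site.segment
        win = track.fixes[(track.fixes["time"] >= seg.start) & (track.fixes["time"] <= seg.end)]
        sub = Track(turtle_id=track.turtle_id, fixes=win.reset_index(drop=True),
                    release_lon=track.release_lon, release_lat=track.release_lat)
        sub = filter_fixes(sub, env=env, mode_context="foraging", depth_limit_m=depth_limit_m)
        site.fixes = sub.fixes
        site.daily_locations = mean_daily_locations(sub.fixes)
    return sites


def foraging_day_table(path, segments: list[BehaviorSegment], track: Track, env=None,
                       min_period_days: float = 2.0) -> pd.DataFrame:
    """Mean daily foraging locations per period, for the habitat grid.

    Returns rows ``turtle_id, period_id, period_days, date, lon, lat`` -
    one per turtle-foraging-day - covering every foraging period (the
    caller applies the >= 2-day exclusion via ``count_foraging_days``).
    Daily locations come from filtered fixes; grid nodes fill days with no
    fix so a foraging day is never silently lost.
    """
    rows = []
    for pid, seg in enumerate(s for s in segments if s.mode == "foraging"):
        win = track.fixes[(track.fixes["time"] >= seg.start) & (track.fixes["time"] <= seg.end)]
        sub = Track(turtle_id=track.turtle_id, fixes=win.reset_index(drop=True))
        sub = filter_fixes(sub, env=env, mode_context="foraging")
        daily = mean_daily_locations(sub.fixes)
        have = set(daily["date"])
        for _, r in daily.iterrows():
            rows.append((track.turtle_id, pid, seg.duration_days, r["date"], r["lon"], r["lat"]))
        # days in the period with no usable fix: use the SSM path position
        i0, i1 = seg.node_slice
        node_dates = pd.Series(path.times[i0:i1].date)
        for d in sorted(set(node_dates) - have):
            sel = node_dates == d
            rows.append((track.turtle_id, pid, seg.duration_days, d,
                         float(np.mean(path.lon[i0:i1][sel])),
                         float(np.mean(path.lat[i0:i1][sel]))))
    return pd.DataFrame(rows, columns=["turtle_id", "period_id", "period_days",
                                       "date", "lon", "lat"])
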