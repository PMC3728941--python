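"""Fix-table reading, filtering, daily means and travel distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ridleyforage import synthetic
from ridleyforage.geo import great_circle_km
from ridleyforage.track_io import (Track, filter_fixes, mean_daily_locations,
                                   read_argos_table, travel_distances,
                                   write_tracks)


def make_track(rows, tid="t1"):
    df = pd.DataFrame(rows, columns=["time", "lon", "lat", "lc"])
    df["time"] = pd.to_datetime(df["time"], utc=True)
    return Track(turtle_id=tid, fixes=df)


class TestReadArgosTable:
    def _write(self, tmp_path, text):
        p = tmp_path / "fixes.csv"
        p.write_text(text)
        return p

    def test_two_turtles_split_correctly(self, tmp_path):
        p = self._write(tmp_path, "\n".join([
            "turtle_id,utc_timestamp,lon,lat,lc",
            "a,2010-06-01T00:00:00Z,-94.0,28.0,3",
            "b,2010-06-01T01:00:00Z,-94.1,28.1,B",
            "a,2010-06-01T02:00:00Z,-94.2,28.2,1",
        ]))
        tracks = {t.turtle_id: t for t in read_argos_table(p)}
        assert len(tracks) == 2
        assert len(tracks["a"]) == 2
        assert len(tracks["b"]) == 1

    def test_duplicate_timestamp_keeps_better_lc(self, tmp_path):
        p = self._write(tmp_path, "\n".join([
            "turtle_id,utc_timestamp,lon,lat,lc",
            "a,2010-06-01T00:00:00Z,-94.0,28.0,B",
            "a,2010-06-01T00:00:00Z,-95.0,28.5,2",
        ]))
        (track,) = read_argos_table(p)
        assert len(track) == 1
        assert track.fixes.loc[0, "lc"] == "2"
        assert track.fixes.loc[0, "lon"] == -95.0

    def test_lc_z_parsed_but_removed_by_filter(self, tmp_path):
        p = self._write(tmp_path, "\n".join([
            "turtle_id,utc_timestamp,lon,lat,lc",
            "a,2010-06-01T00:00:00Z,-94.0,28.0,Z",
            "a,2010-06-01T08:00:00Z,-94.0,28.0,1",
        ]))
        (track,) = read_argos_table(p)
        assert set(track.fixes["lc"]) == {"Z", "1"}
        filtered = filter_fixes(track)
        assert set(filtered.fixes["lc"]) == {"1"}

    def test_invalid_rows_reported_with_line_numbers(self, tmp_path):
        p = self._write(tmp_path, "\n".join([
            "turtle_id,utc_timestamp,lon,lat,lc",
            "a,2010-06-01T00:00:00Z,-94.0,28.0,3",
            "a,2010-06-01T01:00:00Z,-194.0,28.0,3",
        ]))
        with pytest.raises(ValueError, match="lines \\[3\\]"):
            read_argos_table(p)

    def test_empty_file_warns_and_returns_nothing(self, tmp_path):
        p = self._write(tmp_path, "turtle_id,utc_timestamp,lon,lat,lc\n")
        with pytest.warns(UserWarning, match="empty"):
            assert read_argos_table(p) == []

    def test_write_read_round_trip(self, tmp_path):
        cfg = synthetic.SimConfig(duration_days=30.0, seed=1)
        tt = synthetic.simulate_true_track(cfg, "T1")
        tr = synthetic.simulate_argos_fixes(tt, cfg)
        p = tmp_path / "out.csv"
        write_tracks([tr], p)
        (back,) = read_argos_table(p)
        assert len(back) == len(tr)
        np.testing.assert_allclose(back.fixes["lon"], tr.fixes["lon"], atol=1e-6)


class TestFilterFixes:
    def test_deep_fix_removed_in_foraging_context(self, env):
        # (-94.0, 28.2) sits beyond the 100-m isobath in the shared environment
        t = make_track([
            ("2010-06-01T00:00Z", -94.0, 28.8, "1"),
            ("2010-06-01T08:00Z", -94.0, 28.2, "1"),
            ("2010-06-01T16:00Z", -94.0, 28.8, "1"),
        ])
        assert env.bathymetry.sample(-94.0, 28.2) < -100
        out = filter_fixes(t, env=env, mode_context="foraging", max_speed_kmh=1e9)
        assert len(out) == 2

    def test_deep_fix_retained_in_migration_context(self, env):
        t = make_track([
            ("2010-06-01T00:00Z", -94.0, 28.8, "1"),
            ("2010-06-01T08:00Z", -94.0, 28.2, "1"),
        ])
        out = filter_fixes(t, env=env, mode_context=None, max_speed_kmh=1e9)
        assert len(out) == 2

    def test_on_land_fix_removed(self, env):
        t = make_track([
            ("2010-06-01T00:00Z", -94.0, 28.8, "1"),
            ("2010-06-01T08:00Z", -97.9, 30.9, "1"),  # mainland interior
        ])
        out = filter_fixes(t, env=env, max_speed_kmh=1e9)
        assert len(out) == 1

    def test_speed_filter_drops_later_fix(self):
        t = make_track([
            ("2010-06-01T00:00Z", -94.0, 28.0, "1"),
            ("2010-06-01T01:00Z", -92.0, 28.0, "1"),  # ~196 km in 1 h
            ("2010-06-01T02:00Z", -94.0, 28.1, "1"),
        ])
        out = filter_fixes(t)
        assert list(out.fixes["lon"]) == [-94.0, -94.0]

    def test_idempotent(self, env):
        cfg = synthetic.SimConfig(duration_days=60.0, seed=6)
        tt = synthetic.simulate_true_track(cfg, "T1", env=env)
        tr = synthetic.simulate_argos_fixes(tt, cfg)
        once = filter_fixes(tr, env=env)
        twice = filter_fixes(once, env=env)
        pd.testing.assert_frame_equal(once.fixes, twice.fixes)


class TestMeanDailyLocations:
    def test_same_day_fixes_averaged(self):
        t = make_track([
            ("2010-06-01T00:00Z", 1.0, 28.0, "1"),
            ("2010-06-01T08:00Z", 2.0, 28.0, "1"),
            ("2010-06-01T16:00Z", 3.0, 28.0, "1"),
        ])
        out = mean_daily_locations(t.fixes)
        assert len(out) == 1
        assert out.loc[0, "lon"] == pytest.approx(2.0)

    def test_distinct_days_give_distinct_entries(self):
        t = make_track([
            ("2010-06-01T23:00Z", 1.0, 28.0, "1"),
            ("2010-06-02T01:00Z", 3.0, 28.0, "1"),
        ])
        assert len(mean_daily_locations(t.fixes)) == 2

    def test_count_bounded_by_distinct_dates(self):
        cfg = synthetic.SimConfig(duration_days=25.0, seed=2)
        tt = synthetic.simulate_true_track(cfg, "T1")
        tr = synthetic.simulate_argos_fixes(tt, cfg)
        out = mean_daily_locations(tr.fixes)
        n_dates = tr.fixes["time"].dt.date.nunique()
        assert len(out) == n_dates <= 26

    def test_empty_input(self):
        out = mean_daily_locations(pd.DataFrame(columns=["time", "lon", "lat"]))
        assert len(out) == 0


class TestTravelDistances:
    def test_two_fix_track_straight_equals_total(self):
        t = make_track([
            ("2010-06-01T00:00Z", -94.0, 28.0, "1"),
            ("2010-06-02T00:00Z", -93.0, 27.0, "1"),
        ])
        straight, total = travel_distances(t)
        assert straight == pytest.approx(total)

    def test_collinear_meridian_legs_add(self):
        t = make_track([
            ("2010-06-01T00:00Z", -94.0, 26.0, "1"),
            ("2010-06-02T00:00Z", -94.0, 27.0, "1"),
            ("2010-06-03T00:00Z", -94.0, 28.0, "1"),
        ])
        straight, total = travel_distances(t)
        leg = great_circle_km((-94.0, 26.0), (-94.0, 27.0))
        assert total == pytest.approx(2 * leg, rel=1e-9)
        assert straight == pytest.approx(total, rel=1e-6)

    def test_single_fix_signaled(self):
        t = make_track([("2010-06-01T00:00Z", -94.0, 28.0, "1")])
        with pytest.raises(ValueError):
            travel_distances(t)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_total_at_least_straight_line(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        rows = [(pd.Timestamp("2010-06-01", tz="UTC") + pd.Timedelta(hours=8 * i),
                 rng.uniform(-96, -88), rng.uniform(24, 30), "1") for i in range(n)]
        t = make_track(rows)
        straight, total = travel_distances(t)
        # triangle inequality; cross-check total against brute-force leg sum
        pts = t.fixes[["lon", "lat"]].to_numpy()
        brute = sum(great_circle_km(tuple(pts[i]), tuple(pts[i + 1]))
                    for i in range(len(pts) - 1))
        assert total == pytest.approx(brute, rel=1e-9)
        assert total >= straight - 1e-9
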