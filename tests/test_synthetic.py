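"""Ground-truthed simulator: tracks, Argos observations, environment."""

import numpy as np
import pytest
from scipy import stats

from ridleyforage import synthetic
from ridleyforage.synthetic import SimConfig, generate_environment, simulate_argos_fixes, simulate_true_track


def cfg(**kw):
    kw.setdefault("duration_days", 120.0)
    kw.setdefault("z_fraction", 0.0)
    return SimConfig(**kw)


class TestSimConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(duration_days=0.0),
        dict(switch_matrix=((0.9, 0.2), (0.05, 0.95))),
        dict(gamma_migration=0.2, gamma_foraging=0.8),
        dict(gamma_migration=1.3),
        dict(lc_probs={"3": 0.5, "2": 0.5, "1": 0.2, "0": 0, "A": 0, "B": 0}),
        dict(process_sd_km=-1.0),
    ])
    def test_inconsistent_config_rejected(self, bad):
        with pytest.raises(ValueError):
            cfg(**bad)


class TestTrueTrack:
    def test_zero_persistence_gives_uncorrelated_headings(self):
        c = cfg(gamma_migration=0.0, gamma_foraging=0.0,
                turn_concentration=(0.0, 0.0), duration_days=400.0, seed=5)
        tt = simulate_true_track(c, "t")
        d = np.diff(tt.xy_km, axis=0)
        head = np.arctan2(d[:, 1], d[:, 0])
        # circular autocorrelation of successive headings ~ 0
        r = np.mean(np.cos(head[1:] - head[:-1]))
        assert abs(r) < 3.0 / np.sqrt(len(head))

    def test_identity_switch_matrix_absorbing(self):
        c = cfg(switch_matrix=((1.0, 0.0), (0.0, 1.0)), seed=3)
        tt = simulate_true_track(c, "t")
        # starts in migration; identity matrix -> never leaves state 1
        assert set(tt.states) == {1}

    def test_symmetric_chain_stationary_fraction(self):
        # stationary distribution of [[.95,.05],[.05,.95]] is (1/2, 1/2)
        # (left eigenvector of the transition matrix for eigenvalue 1)
        sm = np.array([[0.95, 0.05], [0.05, 0.95]])
        w, v = np.linalg.eig(sm.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi = pi / pi.sum()
        c = cfg(duration_days=50000 * 8 / 24.0, seed=9)
        tt = simulate_true_track(c, "t")
        frac1 = np.mean(tt.states == 1)
        assert frac1 == pytest.approx(pi[0], abs=0.02)

    def test_dwell_times_geometric_mean(self):
        # mean dwell of a state with stay-probability p is 1/(1-p)
        c = cfg(duration_days=50000 * 8 / 24.0, seed=10)
        tt = simulate_true_track(c, "t")
        runs = [stop - start for _, start, stop in tt.segments]
        assert np.mean(runs) == pytest.approx(1.0 / 0.05, rel=0.05)

    def test_reproducible_and_seed_sensitive(self):
        a = simulate_true_track(cfg(seed=7), "t")
        b = simulate_true_track(cfg(seed=7), "t")
        c2 = simulate_true_track(cfg(seed=8), "t")
        np.testing.assert_array_equal(a.xy_km, b.xy_km)
        np.testing.assert_array_equal(a.states, b.states)
        assert not np.array_equal(a.xy_km, c2.xy_km)

    def test_track_confined_to_water(self, env):
        c = cfg(seed=11, duration_days=150.0)
        tt = simulate_true_track(c, "t", env=env)
        bathy = env.bathymetry.sample(tt.lon, tt.lat)
        # redraw/reflect keeps nearly every node off land
        assert np.mean(bathy <= 0) > 0.99


class TestArgosFixes:
    def test_noise_free_limit_on_truth(self):
        c = cfg(seed=1, lc_error_scale_km={k: 0.0 for k in "3210AB"})
        tt = simulate_true_track(c, "t")
        tr = simulate_argos_fixes(tt, c)
        node_h = (tt.times - tt.times[0]).total_seconds().to_numpy() / 3600.0
        fh = (tr.fixes["time"] - tt.times[0]).dt.total_seconds().to_numpy() / 3600.0
        x = np.interp(fh, node_h, tt.xy_km[:, 0])
        y = np.interp(fh, node_h, tt.xy_km[:, 1])
        ox, oy = tt.projection.forward(tr.fixes["lon"].to_numpy(), tr.fixes["lat"].to_numpy())
        assert np.max(np.hypot(ox - x, oy - y)) < 1e-6

    def test_duty_cycle_gates_fix_times(self):
        c = cfg(seed=2, duty_cycle=(6.0, 6.0))
        tt = simulate_true_track(c, "t")
        tr = simulate_argos_fixes(tt, c)
        fh = (tr.fixes["time"] - tt.times[0]).dt.total_seconds().to_numpy() / 3600.0
        assert np.all((fh % 12.0) <= 6.0 + 1e-9)

    def test_lc_frequencies_match_configured(self):
        probs = {"3": 0.1, "2": 0.1, "1": 0.2, "0": 0.2, "A": 0.2, "B": 0.2}
        c = cfg(seed=3, lc_probs=probs, duration_days=1300.0,
                duty_cycle=None, fixes_per_day_on=10.0, release_fix=False)
        tt = simulate_true_track(c, "t")
        tr = simulate_argos_fixes(tt, c)
        assert len(tr) > 10000
        freq = tr.fixes["lc"].value_counts(normalize=True)
        for k, p in probs.items():
            assert freq.get(k, 0.0) == pytest.approx(p, abs=0.02)

    def test_error_distribution_matches_t_scale(self):
        # one class, isotropic t errors: KS test against the configured t
        c = cfg(seed=4, duration_days=700.0, duty_cycle=None, fixes_per_day_on=8.0,
                release_fix=False,
                lc_probs={"3": 1.0, "2": 0, "1": 0, "0": 0, "A": 0, "B": 0},
                lc_error_scale_km={"3": 2.0, "2": 0.5, "1": 1.5, "0": 5, "A": 8, "B": 15})
        tt = simulate_true_track(c, "t")
        tr = simulate_argos_fixes(tt, c)
        node_h = (tt.times - tt.times[0]).total_seconds().to_numpy() / 3600.0
        fh = (tr.fixes["time"] - tt.times[0]).dt.total_seconds().to_numpy() / 3600.0
        ox, oy = tt.projection.forward(tr.fixes["lon"].to_numpy(), tr.fixes["lat"].to_numpy())
        ex = ox - np.interp(fh, node_h, tt.xy_km[:, 0])
        assert len(ex) >= 5000
        ks = stats.kstest(ex / 2.0, stats.t(df=4).cdf)
        assert ks.pvalue > 0.01


class TestEnvironment:
    def test_same_seed_bit_identical_different_seed_differs(self):
        a = generate_environment(seed=5)
        b = generate_environment(seed=5)
        c = generate_environment(seed=6)
        np.testing.assert_array_equal(a.bathymetry.values, b.bathymetry.values)
        np.testing.assert_array_equal(a.sst.values, b.sst.values)
        assert not np.array_equal(a.bathymetry.values, c.bathymetry.values)

    def test_land_positive_sea_negative(self, env):
        lons, lats = env.bathymetry.cell_centers()
        glon, glat = np.meshgrid(lons, lats)
        import shapely
        pts = shapely.points(glon.ravel(), glat.ravel())
        on_land = shapely.contains(env.mainland, pts).reshape(env.bathymetry.shape)
        vals = env.bathymetry.values
        assert np.all(vals[on_land] > 0)

    def test_bathymetry_near_zero_on_coastline(self, env):
        # sample points along the mainland boundary inside the domain
        import shapely
        from shapely.geometry import box
        bnd = env.mainland.boundary.intersection(box(-97.0, 24.0, -86.5, 30.0))
        pts = []
        for line in getattr(bnd, "geoms", [bnd]):
            pts += [line.interpolate(f, normalized=True)
                    for f in np.linspace(0.05, 0.95, 30)]
        vals = [env.bathymetry.sample(p.x, p.y) for p in pts]
        assert len(vals) > 10
        assert np.nanmax(np.abs(vals)) < 3.0

    def test_sst_within_plausible_band(self, env):
        sea = env.bathymetry.values <= 0
        assert env.sst.values[sea].min() > 20.0
        assert env.sst.values[sea].max() < 30.0

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError):
            generate_environment(bounds=(-90.0, 25.0, -90.0, 27.0))

    def test_mainland_distance_zero_only_on_land(self, env):
        from ridleyforage.geo import distance_to_polygon_km
        assert distance_to_polygon_km((-94.0, 28.0), env.mainland) > 0
        # a point well inside the mainland
        assert distance_to_polygon_km((-97.9, 30.9), env.mainland) == 0.0
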