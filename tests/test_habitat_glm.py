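"""Gridded foraging-day counts and the log-link habitat GLM."""

import numpy as np
import pandas as pd
import pytest

from ridleyforage import habitat_glm as hg
from ridleyforage.geo import DEFAULT_PROJECTION
from ridleyforage.raster import Raster
from ridleyforage.synthetic import EnvironmentFields

#: habitat regression coefficients reported for the Gulf-wide 25-km grid
REFERENCE_BETA = {
    "dist_release_km": -0.0008,
    "dist_mainland_km": 0.0060,
    "sst_c": -0.8138,
    "bathymetry_m": -0.0026,
    "npp_mgc_m2_day": 0.0009,
}


class TestBuildGrid:
    def test_shelf_cells_only(self, env, grid):
        cells, spec = grid
        assert len(cells) > 100
        # every retained cell has some probe water shallower than 100 m;
        # spot-check: no cell center lies in water deeper than ~everything
        bathy = env.bathymetry.sample(cells["center_lon"].to_numpy(),
                                      cells["center_lat"].to_numpy())
        assert np.isfinite(bathy).all()

    def test_cell_centers_spaced_25km(self, grid):
        cells, spec = grid
        assert spec.cell_km == 25.0
        sub = cells.reset_index()
        iy = sub["cell"] // spec.nx
        ix = sub["cell"] % spec.nx
        # two cells adjacent in ix at the same iy are exactly 25 km apart in x
        row = sub[iy == iy.iloc[len(sub) // 2]]
        xs = np.sort(ix[row.index].to_numpy())
        assert np.all(np.diff(xs) >= 1)

    def test_rect_domain_cell_count(self):
        # flat -50 m everywhere, 500 x 250 km domain -> full lattice retained
        proj = DEFAULT_PROJECTION
        lon0, lat0 = proj.inverse(0.0, 0.0)
        lon1, lat1 = proj.inverse(500.0, 250.0)
        cell = 0.02
        nx = int(round((lon1 - lon0) / cell))
        ny = int(round((lat1 - lat0) / cell))
        flat = Raster(lon0=float(lon0), lat0=float(lat0), cell=cell,
                      values=np.full((ny, nx), -50.0))
        from shapely.geometry import box
        env = EnvironmentFields(bathymetry=flat, sst=flat, npp=flat,
                                coastline=box(0, 0, 1, 1), mainland=box(0, 0, 1, 1),
                                bounds=(float(lon0), float(lat0), float(lon1), float(lat1)))
        cells, spec = hg.build_grid(env, cell_km=25.0)
        assert spec.nx * spec.ny >= len(cells) >= 20 * 10


class TestCountForagingDays:
    def _daily(self, rows):
        return pd.DataFrame(rows, columns=["turtle_id", "period_id", "period_days",
                                           "date", "lon", "lat"])

    def test_short_period_excluded(self, env, grid):
        cells, spec = grid
        lon, lat = cells.iloc[10][["center_lon", "center_lat"]]
        lon2, lat2 = cells.iloc[40][["center_lon", "center_lat"]]
        daily = self._daily(
            [("a", 0, 3.0, f"2010-06-0{i}", lon, lat) for i in (1, 2, 3)]
            + [("a", 1, 1.0, "2010-06-09", lon2, lat2)])
        out = hg.count_foraging_days(daily, cells, spec, env.projection)
        assert out.loc[cells.index[10], "foraging_days"] == 3
        assert out.loc[cells.index[40], "foraging_days"] == 0

    def test_pooling_over_turtles(self, env, grid):
        cells, spec = grid
        lon, lat = cells.iloc[25][["center_lon", "center_lat"]]
        daily = self._daily(
            [("a", 0, 5.0, f"2010-06-0{i}", lon, lat) for i in range(1, 6)]
            + [("b", 0, 5.0, f"2010-07-0{i}", lon, lat) for i in range(1, 6)])
        out = hg.count_foraging_days(daily, cells, spec, env.projection)
        assert out.loc[cells.index[25], "foraging_days"] == 10

    def test_count_conservation(self, env, grid, rng):
        cells, spec = grid
        picks = rng.integers(0, len(cells), 200)
        daily = self._daily([
            ("a", i, 4.0, "2010-06-01",
             cells.iloc[k]["center_lon"], cells.iloc[k]["center_lat"])
            for i, k in enumerate(picks)])
        out = hg.count_foraging_days(daily, cells, spec, env.projection)
        assert out["foraging_days"].sum() == len(daily)


class TestSubsampleCells:
    def test_778_cells_give_155(self):
        cells = pd.DataFrame({"x": np.arange(778)})
        assert len(hg.subsample_cells(cells, 0.2, seed=0)) == 155

    def test_fraction_one_keeps_all(self, grid):
        cells, _ = grid
        assert len(hg.subsample_cells(cells, 1.0, seed=0)) == len(cells)

    def test_seed_determinism(self, grid):
        cells, _ = grid
        a = hg.subsample_cells(cells, 0.2, seed=4)
        b = hg.subsample_cells(cells, 0.2, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_fraction_rejected(self, grid):
        cells, _ = grid
        with pytest.raises(ValueError):
            hg.subsample_cells(cells, 0.0, seed=0)


class TestFitLogGLM:
    def _sim_counts(self, sub, rng, beta=REFERENCE_BETA, max_mean=60.0):
        eta = sum(beta[k] * sub[k] for k in beta)
        b0 = np.log(max_mean) - eta.max()
        return rng.poisson(np.exp(b0 + eta)), b0

    def test_reference_coefficients_recovered(self, grid, rng):
        cells, _ = grid
        sub = hg.subsample_cells(cells, 155 / len(cells), seed=0)
        hits = 0
        for _ in range(20):
            y, _ = self._sim_counts(sub, rng)
            d = sub.copy()
            d["foraging_days"] = y
            t = hg.fit_log_glm(d).table
            hits += sum(abs(t.loc[k, "estimate"] - REFERENCE_BETA[k]) <= 2 * t.loc[k, "se"]
                        for k in REFERENCE_BETA)
        # pooled 2-SE coverage across coefficients and replicates (~95% nominal)
        assert hits / (20 * len(REFERENCE_BETA)) >= 0.9

    def test_constant_covariates_give_null_slopes(self, grid, rng):
        cells, _ = grid
        d = cells.iloc[:100].copy()
        for c in hg.COVARIATES:
            d[c] = 1.0
        d["foraging_days"] = rng.poisson(7.0, size=len(d))
        with np.errstate(all="ignore"):
            t = hg.fit_log_glm(d).table
        assert t.loc["intercept", "estimate"] == pytest.approx(
            np.log(d["foraging_days"].mean()), abs=0.2)

    def test_unit_rescaling_halves_coefficient(self, grid, rng):
        cells, _ = grid
        sub = hg.subsample_cells(cells, 155 / len(cells), seed=1)
        y, _ = self._sim_counts(sub, rng)
        d = sub.copy()
        d["foraging_days"] = y
        t1 = hg.fit_log_glm(d).table
        d2 = d.copy()
        d2["sst_c"] = 2.0 * d2["sst_c"]
        t2 = hg.fit_log_glm(d2).table
        assert t2.loc["sst_c", "estimate"] == pytest.approx(
            t1.loc["sst_c", "estimate"] / 2.0, rel=1e-6)

    def test_rmse_shrinks_with_more_cells(self, grid):
        cells, _ = grid
        rng = np.random.default_rng(2)
        rmse = []
        for n in (60, len(cells)):
            sub = cells.iloc[:n]
            errs = []
            for _ in range(15):
                y, _ = self._sim_counts(sub, rng)
                d = sub.copy()
                d["foraging_days"] = y
                t = hg.fit_log_glm(d).table
                errs.append((t.loc["sst_c", "estimate"] - REFERENCE_BETA["sst_c"]) ** 2)
            rmse.append(np.sqrt(np.mean(errs)))
        assert rmse[1] < rmse[0]

    def test_table_shape_and_ci_brackets(self, grid, rng):
        cells, _ = grid
        sub = hg.subsample_cells(cells, 0.3, seed=3)
        y, _ = self._sim_counts(sub, rng)
        d = sub.copy()
        d["foraging_days"] = y
        fit = hg.fit_log_glm(d)
        t = fit.table
        assert list(t.index) == ["intercept"] + hg.COVARIATES
        assert (t["ci_lower"] <= t["estimate"]).all()
        assert (t["estimate"] <= t["ci_upper"]).all()
        assert t["p_value"].between(0, 1).all()

    def test_lognormal_alternative_runs(self, grid, rng):
        cells, _ = grid
        sub = hg.subsample_cells(cells, 0.3, seed=5)
        y, _ = self._sim_counts(sub, rng)
        d = sub.copy()
        d["foraging_days"] = y
        fit = hg.fit_log_glm(d, family="lognormal")
        assert fit.family == "lognormal"
        assert np.isfinite(fit.table["estimate"]).all()

    def test_too_few_cells_signaled(self, grid):
        cells, _ = grid
        with pytest.raises(ValueError):
            hg.fit_log_glm(cells.iloc[:10])
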