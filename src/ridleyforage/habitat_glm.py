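"""Gridded foraging-day counts and the environmental-covariate regression.

Foraging effort is summarized on a 25 x 25 km equal-area lattice limited
to shelf water inside the 100-m isobath. Each turtle mean-daily foraging
location (from foraging periods of at least 2 days) adds one
turtle-foraging-day to its containing cell. Cell counts are regressed on
five covariates sampled at cell centers - distance to the mainland shore,
distance to the mean release location, bathymetry, annual mean SST, and
NPP - with a log-link generalized linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .geo import ProjectionSpec, distance_to_polygon_km, great_circle_km

COVARIATES = ["dist_release_km", "dist_mainland_km", "sst_c", "bathymetry_m", "npp_mgc_m2_day"]


@dataclass
class GridSpec:
    x0: float
    y0: float
    cell_km: float
    nx: int
    ny: int

    def cell_of(self, xy_km: np.ndarray) -> np.ndarray:
        """Flat cell index for planar points; -1 outside the lattice."""
        pts = np.atleast_2d(xy_km)
        ix = np.floor((pts[:, 0] - self.x0) / self.cell_km).astype(int)
        iy = np.floor((pts[:, 1] - self.y0) / self.cell_km).astype(int)
        ok = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        return np.where(ok, iy * self.nx + ix, -1)


@dataclass
class GLMFit:
    """Per-covariate estimates in a tidy frame plus fit metadata."""

    table: pd.DataFrame  # index: term; columns: estimate, se, ci_lower, ci_upper, chi_square, p_value
    family: str
    scale: float
    n_cells: int

    def significant(self, alpha: float = 0.05) -> pd.Series:
        return self.table["p_value"] < alpha


def build_grid(env, projection: ProjectionSpec | None = None, cell_km: float = 25.0,
               depth_limit_m: float = 100.0, release_points=None,
               subsample_check: int = 5) -> tuple[pd.DataFrame, GridSpec]:
    """Lay a ``cell_km`` lattice over the domain and keep shelf-water cells.

    A cell belongs to the grid when any of a ``subsample_check`` x
    ``subsample_check`` probe array inside it lies in water no deeper than
    ``depth_limit_m``. Covariates are sampled at cell centers;
    release distance is measured to the mean of ``release_points``
    (lon/lat) as the tagging-site summary location.
    """
    proj = projection or env.projection
    lon_min, lat_min, lon_max, lat_max = env.bounds
    corners = np.array([[lon_min, lat_min], [lon_max, lat_min],
                        [lon_min, lat_max], [lon_max, lat_max]])
    cx, cy = proj.forward(corners[:, 0], corners[:, 1])
    x0, y0 = float(np.min(cx)), float(np.min(cy))
    nx = int(np.ceil((np.max(cx) - x0) / cell_km))
    ny = int(np.ceil((np.max(cy) - y0) / cell_km))
    spec = GridSpec(x0=x0, y0=y0, cell_km=cell_km, nx=nx, ny=ny)

    frac = (np.arange(subsample_check) + 0.5) / subsample_check
    ox, oy = np.meshgrid(frac * cell_km, frac * cell_km)
    probes = np.column_stack([ox.ravel(), oy.ravel()])

    if release_points is not None:
        rel = np.atleast_2d(np.asarray(release_points, dtype=float)).mean(axis=0)
    else:
        rel = None

    rows = []
    for iy in range(ny):
        for ix in range(nx):
            ll = np.array([x0 + ix * cell_km, y0 + iy * cell_km])
            pl, pb = proj.inverse(*(ll + probes).T)
            b = env.bathymetry.sample(pl, pb)
            wet = np.isfinite(b) & (b <= 0) & (b >= -depth_limit_m)
            if not wet.any():
                continue
            cxy = ll + cell_km / 2.0
            lon, lat = (float(v) for v in proj.inverse(*cxy))
            if not np.isfinite(env.bathymetry.sample(lon, lat)):
                continue  # center outside raster coverage (projection edge)
            rows.append({
                "cell": iy * nx + ix,
                "center_lon": lon, "center_lat": lat,
                "bathymetry_m": float(env.bathymetry.sample(lon, lat)),
                "sst_c": float(env.sst.sample(lon, lat)),
                "npp_mgc_m2_day": float(env.npp.sample(lon, lat)),
                "dist_mainland_km": distance_to_polygon_km((lon, lat), env.mainland, proj),
                "dist_release_km": (great_circle_km((lon, lat), tuple(rel))
                                    if rel is not None else np.nan),
            })
    cells = pd.DataFrame(rows).set_index("cell")
    cells["foraging_days"] = 0
    return cells, spec


def count_foraging_days(daily_points: pd.DataFrame, cells: pd.DataFrame, spec: GridSpec,
                        projection: ProjectionSpec, min_period_days: float = 2.0) -> pd.DataFrame:
    """Accumulate turtle foraging days into grid cells.

    ``daily_points`` needs columns ``turtle_id, period_id, period_days,
    lon, lat`` - one row per mean daily foraging location. Points from
    foraging periods shorter than ``min_period_days`` are excluded; each
    remaining row adds one day to the cell containing it. Points outside
    the grid (or in excluded cells) are dropped with a warning count.
    """
    out = cells.copy()
    out["foraging_days"] = 0
    if len(daily_points) == 0:
        return out
    keep = daily_points["period_days"] >= min_period_days
    pts = daily_points[keep]
    if len(pts) == 0:
        return out
    x, y = projection.forward(pts["lon"].to_numpy(), pts["lat"].to_numpy())
    idx = spec.cell_of(np.column_stack([x, y]))
    valid = np.isin(idx, out.index.to_numpy())
    n_drop = int((~valid).sum())
    if n_drop:
        warnings.warn(f"{n_drop} foraging days fell outside the analysis grid and were dropped")
    counted = pd.Series(idx[valid]).value_counts()
    out.loc[counted.index, "foraging_days"] += counted.astype(int)
    return out


def subsample_cells(cells: pd.DataFrame, fraction: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Random floor(fraction * n) cells without replacement.

    Thinning to a spatially random subset weakens the spatial correlation
    between neighboring cells before regression.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if len(cells) == 0:
        raise ValueError("empty grid")
    n = int(np.floor(fraction * len(cells)))
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(cells), size=n, replace=False)
    return cells.iloc[np.sort(pick)]


def fit_log_glm(cells: pd.DataFrame, family: str = "poisson",
                response: str = "foraging_days") -> GLMFit:
    """Log-link GLM of foraging days per cell on the five covariates.

    ``family="poisson"`` fits a log-link Poisson with Pearson-chi-square
    overdispersion scaling of the standard errors (a day count response);
    ``family="lognormal"`` instead regresses log(y + 1) by ordinary least
    squares. Reports Wald chi-square statistics and 95% CIs per term.
    """
    if len(cells) < 20:
        raise ValueError("need at least 20 cells to fit the habitat model")
    X = cells[COVARIATES].astype(float)
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("non-finite covariate values")
    y = cells[response].astype(float)
    # zero-variance covariates carry no information: excluded from the
    # design, reported with a zero slope
    active = [c for c in COVARIATES if X[c].std() > 0]
    Xc = sm.add_constant(X[active], has_constant="add")
    if family == "poisson":
        model = sm.GLM(y, Xc, family=sm.families.Poisson())
        res = model.fit(scale="X2")
        scale = float(res.scale)
    elif family == "lognormal":
        res = sm.OLS(np.log(y + 1.0), Xc).fit()
        scale = float(res.scale)
    else:
        raise ValueError(f"unknown family {family!r}")
    if not np.isfinite(res.params).all():
        raise ValueError("GLM failed to converge to finite estimates")
    est, se = res.params, res.bse
    chi2 = (est / se) ** 2
    pvals = stats.chi2.sf(chi2, df=1)
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "estimate": est, "se": se,
        "ci_lower": ci[0], "ci_upper": ci[1],
        "chi_square": chi2, "p_value": pvals,
    })
    table.index = ["intercept"] + active
    table = table.reindex(["intercept"] + COVARIATES)
    table.loc[table["estimate"].isna(), "estimate"] = 0.0
    return GLMFit(table=table, family=family, scale=scale, n_cells=len(cells))
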