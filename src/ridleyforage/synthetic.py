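"""Ground-truthed synthetic tracks, Argos-like observations and environment.

The generator emulates the study design the downstream analysis assumes:
post-nesting female Kemp's ridley turtles released on the western Gulf
coast, moving by a two-state first-difference correlated random walk
(state 1 = directed migration with high move persistence, state 2 =
localized foraging with low persistence), observed through duty-cycled,
irregularly timed Argos fixes whose error scale depends on the location
class. Environmental fields (bathymetry, SST, NPP) are smooth seeded
random surfaces over a Gulf-of-Mexico-like shelf domain.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geo import DEFAULT_PROJECTION, ProjectionSpec, project_geometry
from .raster import Raster
from .track_io import Track

LC_CLASSES = ["3", "2", "1", "0", "A", "B"]

#: Literature-order Argos error scales (km) per location class; the t
#: distribution's heavy tails stand in for the occasional wild fix.
DEFAULT_LC_ERROR_SCALE_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 8.0, "B": 15.0}
DEFAULT_LC_ERROR_DF = {c: 4.0 for c in LC_CLASSES}


@dataclass
class SimConfig:
    """Parameters of the two-state track simulator and observation process."""

    n_turtles: int = 5
    duration_days: float | None = None  # None -> drawn uniformly in [98, 342]
    step_hours: float = 8.0
    gamma_migration: float = 0.8
    gamma_foraging: float = 0.2
    #: wrapped-Cauchy concentration of turning angles, per state (migration,
    #: foraging); 1.0 = deterministic rotation by the state's mean turn,
    #: which is the structure the switching DCRW assumes
    turn_concentration: tuple[float, float] = (1.0, 1.0)
    #: mean turn per state: straight-ahead travel in migration, reversing
    #: (area-restricted search) in foraging
    mean_turn: tuple[float, float] = (0.0, np.pi)
    #: per-axis step-noise sd (km); a scalar applies to both states, a pair
    #: gives (migration, foraging) scales - localized foraging moves less
    process_sd_km: float | tuple[float, float] = 3.0
    #: row-stochastic state transition matrix, rows/cols = (migration, foraging)
    switch_matrix: tuple = ((0.95, 0.05), (0.05, 0.95))
    lc_probs: dict = field(default_factory=lambda: {
        "3": 0.05, "2": 0.08, "1": 0.15, "0": 0.12, "A": 0.25, "B": 0.35})
    lc_error_scale_km: dict = field(default_factory=lambda: dict(DEFAULT_LC_ERROR_SCALE_KM))
    lc_error_df: dict = field(default_factory=lambda: dict(DEFAULT_LC_ERROR_DF))
    duty_cycle: tuple[float, float] | None = (6.0, 6.0)  # hours on / off, None = continuous
    fixes_per_day_on: float = 8.0  # mean fix rate while the transmitter is on
    release_fix: bool = True  # include a good-quality fix at deployment time
    z_fraction: float = 0.02  # junk LC-Z fixes injected with very large error
    seed: int = 0

    def __post_init__(self):
        sm = np.asarray(self.switch_matrix, dtype=float)
        if sm.shape != (2, 2) or np.any(np.abs(sm.sum(axis=1) - 1.0) > 1e-12) or np.any(sm < 0):
            raise ValueError("switch_matrix must be 2x2 row-stochastic")
        probs = np.array([self.lc_probs.get(c, 0.0) for c in LC_CLASSES])
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("lc_probs must be a probability vector over LC classes 3,2,1,0,A,B")
        for g in (self.gamma_migration, self.gamma_foraging):
            if not 0.0 <= g <= 1.0:
                raise ValueError("move persistence must be in [0, 1]")
        if self.gamma_migration < self.gamma_foraging:
            raise ValueError("gamma_migration must be >= gamma_foraging for identifiability")
        if self.duration_days is not None and self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        sd = np.atleast_1d(np.asarray(self.process_sd_km, dtype=float))
        if self.step_hours <= 0 or np.any(sd <= 0) or self.fixes_per_day_on <= 0:
            raise ValueError("step_hours, process_sd_km and fixes_per_day_on must be positive")

    def state_sd(self, state: int) -> float:
        """Step-noise sd for state 1 (migration) or 2 (foraging)."""
        sd = np.atleast_1d(np.asarray(self.process_sd_km, dtype=float))
        return float(sd[0]) if (state == 1 or sd.size == 1) else float(sd[1])


@dataclass
class TrueTrack:
    """Latent 8-hourly truth behind a simulated track."""

    turtle_id: str
    times: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    xy_km: np.ndarray  # positions in the projection plane
    states: np.ndarray  # 1 = migration, 2 = foraging
    release: tuple[float, float]
    projection: ProjectionSpec

    @property
    def segments(self) -> list[tuple[int, int, int]]:
        """Run-length segments as (state, start index, stop index exclusive)."""
        out, start = [], 0
        s = self.states
        for i in range(1, len(s) + 1):
            if i == len(s) or s[i] != s[start]:
                out.append((int(s[start]), start, i))
                start = i
        return out


@dataclass
class EnvironmentFields:
    """Shared-grid rasters plus coastline/mainland polygons (lon/lat)."""

    bathymetry: Raster  # metres; <= 0 at sea, > 0 on land
    sst: Raster         # degrees C, annual mean
    npp: Raster         # mg C / m^2 / day
    coastline: shapely.Geometry  # all land incl. barrier islands
    mainland: shapely.Geometry
    bounds: tuple[float, float, float, float]
    projection: ProjectionSpec = DEFAULT_PROJECTION

    def is_land(self, lon, lat):
        b = self.bathymetry.sample(lon, lat)
        return np.asarray(b) > 0


def _child_rng(seed: int, *keys) -> np.random.Generator:
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


def _wrapped_cauchy(rng, mu: float, rho: float, size: int) -> np.ndarray:
    """Sample turning angles from a wrapped Cauchy(mu, rho)."""
    if rho <= 0:
        return rng.uniform(-np.pi, np.pi, size)
    u = rng.uniform(0.0, 1.0, size)
    ang = mu + 2.0 * np.arctan(((1 - rho) / (1 + rho)) * np.tan(np.pi * (u - 0.5)))
    return np.mod(ang + np.pi, 2 * np.pi) - np.pi


DEFAULT_BOUNDS = (-98.0, 23.0, -86.0, 31.0)
DEFAULT_RELEASE = (-96.9, 26.4)  # just offshore of the synthetic west coast


def generate_environment(bounds: tuple = DEFAULT_BOUNDS, seed: int = 0,
                         cell: float = 0.05,
                         projection: ProjectionSpec = DEFAULT_PROJECTION) -> EnvironmentFields:
    """Build seeded synthetic bathymetry/SST/NPP rasters and coast polygons.

    The domain mimics the western/northern Gulf of Mexico: an L-shaped
    mainland coast (west + north), a shelf whose depth grows roughly
    linearly with distance from shore (0.8 m/km, putting the 100-m isobath
    ~125 km offshore), a barrier island distinct from the mainland so that
    nearest-land and mainland distances differ, and smooth seeded SST / NPP
    surfaces with a latitudinal and an onshore-offshore gradient.
    """
    lon_min, lat_min, lon_max, lat_max = bounds
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("degenerate (zero-area) domain")
    rng = _child_rng(seed, "environment")

    # --- coastline curves (smooth, slightly randomized) ---
    amp_w, amp_n = 0.15 + 0.05 * rng.random(), 0.25 + 0.05 * rng.random()
    ph_w, ph_n = rng.uniform(0, 2 * np.pi, 2)

    def west_coast_lon(lat):
        return lon_min + 0.7 + amp_w * np.sin(2 * np.pi * (lat - lat_min) / 5.0 + ph_w)

    def north_coast_lat(lon):
        return lat_max - 1.4 + amp_n * np.sin(2 * np.pi * (lon - lon_min) / 6.0 + ph_n)

    lats = np.linspace(lat_min, lat_max, 200)
    lons = np.linspace(lon_min, lon_max, 200)
    pad = 2.0
    west_strip = Polygon(
        [(lon_min - pad, lat_min - pad)]
        + [(west_coast_lon(la), la) for la in lats]
        + [(lon_min - pad, lat_max + pad)])
    north_strip = Polygon(
        [(lon_min - pad, lat_max + pad)]
        + [(lo, north_coast_lat(lo)) for lo in lons]
        + [(lon_max + pad, lat_max + pad)])
    mainland = unary_union([west_strip, north_strip]).buffer(0)

    # barrier island offshore of the north coast
    isl_lon = lon_min + 3.2
    isl_lat = float(north_coast_lat(isl_lon)) - 0.35
    t = np.linspace(0, 2 * np.pi, 60)
    island = Polygon(np.column_stack([isl_lon + 0.45 * np.cos(t), isl_lat + 0.04 * np.sin(t)]))
    coastline = unary_union([mainland, island])

    # --- rasters ---
    nx = int(round((lon_max - lon_min) / cell))
    ny = int(round((lat_max - lat_min) / cell))
    clons = lon_min + (np.arange(nx) + 0.5) * cell
    clats = lat_min + (np.arange(ny) + 0.5) * cell
    glon, glat = np.meshgrid(clons, clats)
    pts = shapely.points(*projection.forward(glon.ravel(), glat.ravel()))
    mainland_km = project_geometry(mainland, projection)
    island_km = project_geometry(island, projection)
    dist_km = shapely.distance(pts, mainland_km.boundary).reshape(ny, nx)
    on_land = shapely.contains(mainland_km, pts).reshape(ny, nx)
    on_island = shapely.contains(island_km, pts).reshape(ny, nx)

    def smooth_field(sigma_cells=8.0):
        f = gaussian_filter(rng.standard_normal((ny, nx)), sigma_cells)
        return f / max(f.std(), 1e-12)

    noise = smooth_field()
    # noise fades to zero at the shore so bathymetry ~ 0 on the coastline
    fade = np.minimum(dist_km / 30.0, 1.0)
    depth = 0.8 * dist_km + 8.0 * noise * fade
    bathy = np.where(on_land, 1.0 + 0.5 * dist_km, -np.maximum(depth, 0.05))
    bathy = np.where(on_island, 2.0, bathy)

    sst_vals = 27.5 - 0.45 * (glat - lat_min) + 0.6 * smooth_field(10.0)
    sst_vals = np.clip(sst_vals, 23.0, 29.0)
    npp_vals = 1800.0 + 2200.0 * np.exp(-dist_km / 70.0) + 350.0 * smooth_field(6.0)
    npp_vals = np.clip(npp_vals, 300.0, None)

    mk = lambda v: Raster(lon0=lon_min, lat0=lat_min, cell=cell, values=v)
    return EnvironmentFields(bathymetry=mk(bathy), sst=mk(sst_vals), npp=mk(npp_vals),
                             coastline=coastline, mainland=mainland, bounds=bounds,
                             projection=projection)


def simulate_true_track(config: SimConfig, turtle_id: str | int,
                        env: EnvironmentFields | None = None,
                        release: tuple[float, float] = DEFAULT_RELEASE,
                        release_date: str = "2010-06-15") -> TrueTrack:
    """Simulate the latent two-state correlated random walk on the 8-h grid.

    Displacements follow d_t = gamma_s R(theta_t) d_{t-1} + eps_t with the
    turning angle theta_t drawn from a per-state wrapped Cauchy and eps_t
    isotropic Gaussian; the behavioral state s_t is a two-state Markov
    chain starting in migration. Steps that would land on shore are redrawn
    (up to 50 times) and finally reflected, keeping the process CRW-like
    near the coast.
    """
    rng = _child_rng(config.seed, "true_track", turtle_id)
    duration = config.duration_days
    if duration is None:
        duration = rng.uniform(98.0, 342.0)
    n_steps = int(round(duration * 24.0 / config.step_hours))
    if n_steps < 2:
        raise ValueError("track duration too short for the configured step")
    proj = env.projection if env is not None else DEFAULT_PROJECTION

    sm = np.asarray(config.switch_matrix, dtype=float)
    states = np.empty(n_steps + 1, dtype=int)
    states[0] = 1
    u = rng.random(n_steps)
    for t in range(1, n_steps + 1):
        p_stay_row = sm[states[t - 1] - 1]
        states[t] = 1 if u[t - 1] < p_stay_row[0] else 2

    gam = {1: config.gamma_migration, 2: config.gamma_foraging}
    rho = {1: config.turn_concentration[0], 2: config.turn_concentration[1]}
    mu = {1: config.mean_turn[0], 2: config.mean_turn[1]}

    x0, y0 = proj.forward(release[0], release[1])
    pos = np.empty((n_steps + 1, 2))
    pos[0] = (float(x0), float(y0))
    # initial heading: offshore-ish random direction
    ang0 = rng.uniform(-np.pi, np.pi)
    d_prev = config.state_sd(1) * np.array([np.cos(ang0), np.sin(ang0)])

    def on_shore(p):
        if env is None:
            return False
        lon, lat = proj.inverse(p[0], p[1])
        b = env.bathymetry.sample(float(lon), float(lat))
        return (not np.isfinite(b)) or b > 0

    for t in range(1, n_steps + 1):
        s = states[t]
        accepted = None
        for _ in range(50):
            th = float(_wrapped_cauchy(rng, mu[s], rho[s], 1)[0])
            c, sn = np.cos(th), np.sin(th)
            rot = np.array([[c, -sn], [sn, c]])
            d = gam[s] * rot @ d_prev + rng.normal(0.0, config.state_sd(s), 2)
            cand = pos[t - 1] + d
            if not on_shore(cand):
                accepted = (d, cand)
                break
        if accepted is None:  # reflect the last draw
            d = -d
            cand = pos[t - 1] + d
            accepted = (d, cand)
        d_prev, pos[t] = accepted[0], accepted[1]

    lon, lat = proj.inverse(pos[:, 0], pos[:, 1])
    times = pd.date_range(pd.Timestamp(release_date, tz="UTC"),
                          periods=n_steps + 1, freq=pd.Timedelta(hours=config.step_hours))
    return TrueTrack(turtle_id=str(turtle_id), times=times, lon=lon, lat=lat,
                     xy_km=pos, states=states, release=release, projection=proj)


def _fix_times_hours(rng, total_hours: float, duty_cycle, rate_per_day: float) -> np.ndarray:
    """Poisson fix times gated by the transmitter duty cycle (hours)."""
    if duty_cycle is None:
        n = rng.poisson(rate_per_day / 24.0 * total_hours)
        return np.sort(rng.uniform(0.0, total_hours, n))
    on, off = duty_cycle
    period = on + off
    n_full = int(total_hours // period)
    rem = total_hours - n_full * period
    total_on = n_full * on + min(rem, on)
    n = rng.poisson(rate_per_day / 24.0 * total_on)
    s = np.sort(rng.uniform(0.0, total_on, n))  # position within cumulative on-time
    block = np.floor(s / on)
    return block * period + (s - block * on)


def simulate_argos_fixes(track: TrueTrack, config: SimConfig) -> Track:
    """Observe a true track through the Argos-like error/duty-cycle model.

    Fix times are an inhomogeneous Poisson process restricted to duty-cycle
    on-windows; each fix is the linear (in the projected plane) interpolation
    of the truth to the fix time plus isotropic per-axis Student-t error at
    the fix's location-class scale. A small configured fraction of invalid
    LC-Z fixes with very large error is injected.
    """
    if len(track.times) == 0:
        raise ValueError("empty true track")
    rng = _child_rng(config.seed, "argos", track.turtle_id)
    node_h = (track.times - track.times[0]).total_seconds().to_numpy() / 3600.0
    fh = _fix_times_hours(rng, node_h[-1], config.duty_cycle, config.fixes_per_day_on)
    fh = fh[fh <= node_h[-1]]
    if config.release_fix:  # the tag reports a good fix at deployment
        fh = np.concatenate([[0.0], fh[fh > 0]])
    fh = np.round(fh * 3600.0) / 3600.0  # whole seconds, matching the timestamps
    x = np.interp(fh, node_h, track.xy_km[:, 0])
    y = np.interp(fh, node_h, track.xy_km[:, 1])
    true_state = track.states[np.clip(np.searchsorted(node_h, fh, side="right"), 1, len(node_h) - 1)]

    probs = np.array([config.lc_probs[c] for c in LC_CLASSES])
    lcs = rng.choice(np.array(LC_CLASSES), size=len(fh), p=probs / probs.sum())
    scale = np.array([config.lc_error_scale_km[c] for c in lcs])
    df = np.array([config.lc_error_df[c] for c in lcs])
    if config.z_fraction > 0:
        is_z = rng.random(len(fh)) < config.z_fraction
        lcs = np.where(is_z, "Z", lcs)
        scale = np.where(is_z, 30.0, scale)
    if config.release_fix:
        lcs[0] = "3"
        scale[0] = config.lc_error_scale_km["3"]
    err = rng.standard_t(df[:, None], size=(len(fh), 2)) * scale[:, None]
    lon, lat = track.projection.inverse(x + err[:, 0], y + err[:, 1])

    times = (track.times[0] + pd.to_timedelta(np.round(fh * 3600.0), unit="s"))
    df_out = pd.DataFrame({"time": times, "lon": lon, "lat": lat,
                           "lc": lcs, "true_state": true_state})
    df_out = df_out.drop_duplicates(subset="time").sort_values("time")
    return Track(turtle_id=track.turtle_id, fixes=df_out,
                 release_lon=track.release[0], release_lat=track.release[1],
                 release_date=track.times[0], site="PAIS")


def simulate_study(config: SimConfig, env: EnvironmentFields | None = None,
                   release: tuple[float, float] = DEFAULT_RELEASE
                   ) -> tuple[list[TrueTrack], list[Track]]:
    """Simulate ``config.n_turtles`` tracks plus their Argos observations."""
    truths, obs = [], []
    for i in range(config.n_turtles):
        tt = simulate_true_track(config, f"T{i + 1:03d}", env=env, release=release,
                                 release_date=pd.Timestamp("2010-06-01")
                                 + pd.Timedelta(days=3 * i))
        truths.append(tt)
        obs.append(simulate_argos_fixes(tt, config))
    return truths, obs
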