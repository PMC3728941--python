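# Methods

This note documents the models, the synthetic study generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Switching state-space model

The movement model is a two-state switching first-difference correlated
random walk (DCRW) on a regular 8-hour grid. Writing `d_t = x_t − x_{t−1}`
for the displacement into node `t` (positions in an equal-area km plane),

    d_t = γ_{b_t} R(θ_{b_t}) d_{t−1} + ε_t,   ε_t ~ N₂(0, Σ),

with a latent behavioral chain `b_t ∈ {1 = migration, 2 = foraging}`
following first-order Markov dynamics with stay/switch probabilities
`α₁ = Pr(1|1)` and `α₂ = Pr(1|2)`. The first displacement carries a vague
isotropic normal prior (sd 100 km). Σ is shared between states — behavior
expresses itself through persistence `γ_s` and mean turn `θ_s` only, which
matches the model family this analysis descends from; see "Limitations"
for what that costs.

Each Argos fix is tied to the two grid nodes bracketing its time by linear
interpolation, with independent per-axis Student-t errors whose scale is a
per-location-class constant (defaults, km: LC 3 → 0.25, 2 → 0.5, 1 → 1.5,
0 → 5, A → 8, B → 15; 4 degrees of freedom). These scales respect the
published Argos accuracy ordering; the data this package is aimed at do
not come with per-class error estimates, so the constants are
configuration, not estimates. LC Z fixes carry no usable position and are
always excluded.

### Sampler

Metropolis-within-Gibbs, chosen because every conditional is cheap and
the whole fit stays dependency-free:

- **Positions.** Single-node Gaussian random-walk proposals. The process
  term at node `t` touches nodes `t−2 … t+2`, so nodes with indices equal
  mod 3 are conditionally independent and are updated as one vectorized
  block (three blocks per sweep). Proposal scales adapt per node during
  burn-in toward ~0.3 acceptance.
- **Behavioral chain.** Exact forward-filter backward-sampling given the
  current path and parameters.
- **(γ_s, θ_s).** Joint random-walk Metropolis per state. θ is circular:
  proposals wrap, and with probability 0.2 a fresh uniform draw replaces
  the local step so the chain can jump between turn regimes (directed
  travel vs. reversing area-restricted search) without walking through
  low-density angles. Posterior summaries of θ recentre samples on the
  circular mean. The constraint γ₁ > γ₂ (migration is the more
  persistent state) is part of the prior support and fixes the state
  labels.
- **Σ.** Random-walk Metropolis on (log σx, log σy, atanh ρ) with
  half-normal(10 km) priors on the standard deviations.
- **α₁, α₂.** Conjugate Beta(1,1) Gibbs draws from the sampled chain's
  transition counts.

Two independent chains run by default. Convergence is gated
quantitatively: per-parameter split potential-scale-reduction (flag at
PSR > 1.1) and autocorrelation-based effective sample size (Geyer
initial-positive truncation), implemented directly and verified against
the analytic cases (identical chains → PSR ≈ 1, i.i.d. draws → ESS ≈ n).

Presets: the full protocol retains 10 000 samples per chain after a 7000
burn-in, thinned by 5; the `desk` preset (2000 retained, burn-in 1000,
thin 2) is what the test suite and the reproduction script use — at those
settings a 150-day track (451 nodes, ~1800 fixes) fits in ~30 s.

### Mode classification

A node is labeled foraging when the posterior mean behavioral index
`b̄ ∈ [1,2]` is ≥ 1.5 — the symmetric cutoff, and the Bayes rule for 0–1
loss on the marginal state. The three-way scheme (1.25/1.75 with an
"uncertain" band) can be had by passing different cutoffs to
`classify_modes`.

## Segmentation and site labels

Maximal runs of constant mode become behavioral segments. If a track ends
in a foraging segment, that segment is the final site **F** (the animal's
apparent destination — no minimum duration, since the tag simply stopped
there). Walking backward in time, earlier foraging segments of ≥ 20 days
are labeled **F1, F2, F3**; shorter ones are skipped for labeling and
kernel analysis but still contribute to gridded foraging days, where only
periods < 2 days are excluded. The two thresholds deliberately differ:
20 days is about having enough mean daily locations for a stable KDE,
2 days is about not crediting single-day flickers as habitat use. Mode
flickers are not smoothed; robustness to them is the posterior mean's job.

## Kernel core areas

Mean daily locations (arithmetic mean of a UTC day's filtered fixes)
feed a Gaussian product-kernel density in the projected plane. The
bandwidth minimizes the least-squares cross-validation score, computed in
closed form from pairwise squared distances; the minimizer is bracketed
on a 60-point log grid and polished with bounded scalar minimization. If
the per-axis standard deviations differ by more than 1.5×, coordinates
are standardized first and the bandwidth back-scaled per axis. A monotone
CV score (no interior minimum) falls back to the bivariate normal
reference rule `1.06 σ n^(−1/5)` with a warning.

The 50% core area is the superlevel set holding half the discrete cell
mass, found by sorting cell masses (deterministic, no interpolation), on
a grid of resolution bandwidth/4 (capped at 512 cells per axis),
polygonized as the union of grid-cell boxes. The activity-center centroid
is taken from the largest polygon *before* water clipping; the reported
area is the polygon area *after* removing land. Verified against the
closed-form 50% region of an isotropic Gaussian (area `2π ln 2 σ²`).

## Site-fidelity test

The observed site path's mean squared distance about its mean center is
compared with 100 constrained random walks: same step lengths in order,
uniform headings, start at the observed start, every vertex redrawn (up
to 100 times, then reflected) until it lies in the −100..0 m bathymetry
band. `proportion_higher` is the percentage of walks with larger MSD;
fidelity is declared at ≥ 95% (α = 0.05, one-sided). Because observed and
replicate paths face the same constraint, the null distribution of the
exceedance is uniform and the test is calibrated — the suite checks a
5% ± 3% null rejection rate over 200 repeats.

One deliberate deviation from the historical desktop tool: coordinates
are *not* standardized by the observed path's per-axis standard
deviations before the MSD comparison. That rescaling existed to offset
the unequal ground lengths of latitude and longitude degrees; in an
equal-area km plane it is unnecessary, and because the scale would be
derived from the realized path it couples the transform to the draw and
inflates the null exceedance (measured: ~9% null rejection instead of
5%, mean exceedance 60 instead of 50). `sd_ratio_rescale` re-enables it
for comparison with legacy outputs.

## Habitat grid and GLM

A 25 × 25 km lattice in the projection covers the domain; a cell joins
the analysis grid when any of a 5 × 5 probe array inside it lies in water
no deeper than 100 m. Covariates are sampled at cell centers: bathymetry,
annual SST, NPP, distance to the mainland shore (planar distance to the
mainland polygon), and distance to the mean release location. Each
turtle-foraging-day (mean daily location from a ≥ 2-day foraging period)
increments its containing cell; days whose location falls off the shelf
grid are dropped with a warning count, so conservation is exact over
retained points. A seeded 20% subsample of cells (floor(0.2 n)) feeds the
regression, thinning short-range spatial correlation.

The default family is log-link Poisson with Pearson-χ² overdispersion
scaling of the standard errors — the response is a day count and zeros
are legitimate observations. A log-normal alternative (OLS on
log(y + 1)) is available via `family="lognormal"`. The report gives per
coefficient the estimate, SE, 95% CI, Wald χ² and p-value. Zero-variance
covariates are excluded from the design and reported with a zero slope.

## Geometry

All areas and distances are computed in a spherical Albers equal-area
conic plane (centre 90°W 25°N, standard parallels 20°N/30°N, R =
6371 km). The closed-form inverse makes round trips exact to machine
precision, and equal-area is what makes km² KDE areas meaningful;
results are insensitive at the < 1% level to the precise equal-area
choice. Great-circle distances use the haversine formula; geodesic
(ellipsoidal) corrections are out of scope. Rasters are plain regular
lon/lat grids with bilinear sampling, serialized as ESRI ASCII text;
polygons travel as GeoJSON.

## Synthetic study generator

The generator emulates the study design the analysis assumes: 31-turtle
cohorts of post-nesting females released on the western Gulf coast,
track durations drawn uniformly from 98–342 days, duty-cycled (6 h
on/off) Argos observation with class-dependent t-distributed errors and
a small fraction of LC-Z junk, over seeded synthetic fields — an
L-shaped mainland coast, shelf depth growing ~0.8 m per km offshore
(100-m isobath ≈ 125 km out), a barrier island so nearest-land and
mainland distances differ, SST with a latitudinal gradient inside the
24–28 °C band, and NPP decaying offshore.

The movement defaults are the *model-matched* conditions: two states with
γ = 0.8/0.2, stay probabilities 0.95, deterministic per-state rotation
(wrapped-Cauchy concentration 1.0) with mean turns 0 (migration) and π
(foraging — area-restricted search with reversals), shared isotropic step
noise of 3 km. Matching matters for the recovery experiments: with both
mean turns at 0 the two states differ so little per step that even the
exact posterior misclassifies ~15% of nodes, and with per-state step
noise (supported via a `process_sd_km` pair, and more realistic) the
shared-Σ model's persistence estimates bias upward by 0.1–0.25. The
defaults therefore define a simulation the model can in principle invert;
the knobs exist to study both mismatches deliberately.

A deployment-time fix (LC 3) anchors each simulated track, aligning the
SSM's 8-h grid with the generator's — real tags do report at release, and
without that anchor the fitted process is a time-shifted mixture of
adjacent true displacements.

**What passing tests do and do not show.** The simulator draws from
(essentially) the fitted model's own family over smooth fields. Passing
recovery tests therefore demonstrates correctness of the implementation
and calibration of the inference, not robustness to real-Argos
pathologies: tag failure gaps of days to weeks, error scales that drift
with sea state and surfacing behavior, tidal/current-driven drift during
foraging, or true behavior with more than two regimes.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen as the smallest sizes at which each property is statistically
clean: SSM recovery on three 150-day tracks with the reduced (2000
retained) chains; credible-interval coverage over twenty 60-day
single-to-two-state fits; KDE oracle at n = 500 points; fidelity null
calibration over 200 repeats of 30-step paths with 100 replicates each;
GLM recovery over 50 replicate fits at 155 subsampled cells; pipeline
determinism on two 50-day turtles. The full-protocol MCMC settings
remain the library defaults.

## Known limitations

- Shared process covariance between behavioral states; no hierarchical
  pooling across turtles (each track is fitted independently, as the
  study design prescribes).
- Observation-error scales are fixed constants per location class, not
  estimated.
- The land-avoidance rule in the simulator (redraw, then reflect) keeps
  tracks at sea but is not a hydrodynamically meaningful boundary.
- The fidelity test conditions on observed step lengths; if the SSM
  under-smooths a path, step lengths inherit that noise.
- No multi-year site-return analysis; tracks are single deployments.
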