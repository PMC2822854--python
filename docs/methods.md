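# Methods

This note records the models, parameter choices and numerical conventions
behind `shelfbreak`, and what the synthetic-data tests do and do not
demonstrate about real tracking data.

## Geodesy

All distances are great-circle (haversine) on a sphere of radius
6,371,008.8 m (IUGG mean radius). At foraging-trip scales (≤ ~1,000 km)
the difference from an ellipsoidal model is well below GPS positional
noise, and a fixed sphere makes every derived quantity exactly
reproducible. Bearings are degrees clockwise from true north. Trip areas
are planar convex-hull areas in a Lambert azimuthal equal-area projection
centred on the colony; the projection is exactly area-preserving, so the
only approximation is using the hull of the projected points rather than
the projection of the spherical hull (relative error ~10⁻⁵ at 1°
scales). A degenerate (collinear or single-point) hull has zero area.

## Fix filtering

GPS receivers report per-fix satellite counts and/or a solution-quality
flag. A position solved with ≥ 4 satellites ("3D fix") resolves altitude
and is the higher accuracy class, so the filter keeps a fix when
`n_sats ≥ 4` **or** its flag is `FIX3D` — device logs may carry either
field. Fixes with neither field are uninformative and dropped; all drop
counts are reported. Speeds of exactly 0 m s⁻¹ are artefacts of the
receiver's velocity/position solution; they are removed from the *speed
series* (not the positions) before the log transform, where they would be
undefined anyway. Both filters are idempotent.

## Speed mixture (behavioural classification)

Over-ground speed between consecutive fixes (pairs spanning gaps longer
than `max_dt` are skipped) is modelled as a K-component Gaussian mixture
on log speed. EM details:

* **Initialisation** — deterministic K-quantile split of the sorted log
  speeds; each chunk supplies one component's mean, variance and weight.
  The seed only perturbs optional extra restarts (`n_restarts > 1`);
  the default single run is fully deterministic. For well-separated
  bimodal speeds the quantile start is already close to the optimum.
* **Convergence** — relative log-likelihood change ≤ 1e−8 or 500
  iterations; the per-iteration log-likelihood trace is stored and
  asserted non-decreasing (the EM guarantee) throughout the test suite.
* **Degeneracy guards** — component variances are floored at
  1e−10 × the sample variance; an all-equal speed sample is rejected.
* **Component identity** — components are sorted by mean, so index 0 is
  always the slow (drift) mode.

Natural-scale summaries use the exact log-normal moment map
`mean = exp(μ + σ²/2)`, `var = (exp(σ²) − 1)·exp(2μ + σ²)`, and its
inverse is used wherever natural-scale moments parameterise a generator.
Reported natural-scale mode values are therefore interpreted as log-normal
moments of the fitted log-space components.

Classification is maximum posterior probability. Exact posterior ties are
broken toward the *slower* component: misclassifying rest as flight would
inflate apparent foraging range, so the conservative direction is down.
Burst clusters are classified by their representative speed, defined as
the **median** of within-cluster consecutive speeds (robust to single-fix
jitter inside a burst); clusters with fewer than two fixes have no defined
speed, are flagged, and are excluded from behavioural proportions.

Fitting on the high-resolution tracks and transferring the model to
sparse tracks mediates acquisition bias: if sitting birds acquire fixes
more readily than flying birds, a mixture refitted on the sparse sample
sees distorted weights and far fewer observations. The test suite checks
this on simulation: across 100 replicates, mode means estimated by the
transferred high-resolution model are on average closer to truth than
refitting on the biased sparse sample.

## Rotation-null habitat association

The null asks what depths were *available* to a bird conditional on its
track geometry: the track is rigidly rotated about its origin (default:
the first fix, i.e. the colony) through every non-identity multiple of
22.5° — fifteen equally spaced rotations through 360°. Rotation about a
point on the sphere is an isometry, so distances to the origin and along
the track are preserved to ~10⁻⁹ relative. Depths are sampled under each
rotated replicate; locations over land (elevation ≥ 0 — the bathymetry
grid is its own land mask), over nodata cells, or outside the raster
extent are dropped with counts. Behaviour labels carry over from the
unrotated fixes. Depth is positive-down (`depth = −elevation`), and the
shelf-break band 600–1000 m is inclusive on both edges.

Raster sampling is nearest-cell with a floor convention: a point exactly
on a shared cell edge belongs to the cell whose index interval has that
edge as its lower bound (i.e. `floor` of the fractional index, in both
axes). The east and south outer edges are outside the grid.

The observed-vs-null comparison repeats a two-sample KS test `n_runs`
(default 1000) times against equally sized subsamples of the null pool,
drawn without replacement; the result records every run's D and p, the
proportion of runs with p < α, and median D and p. "Significant overall"
is defined as proportion ≥ 0.95 (configurable) — an aggregation
convention, stated as such. For high-resolution tracks, fixes should
first be merged into two-minute windows (one location per window at the
mean position, timestamped at the window centre) to blunt the extreme
autocorrelation of 5-s fixes; merging a track already merged at the same
window is a no-op. No multiple-testing correction is applied across
tracks or bands; tests are reported per track.

KS details: D is an exact ECDF sweep over the pooled sample (ties
handled exactly); p is the asymptotic Kolmogorov survival function at
`sqrt(n₁n₂/(n₁+n₂))·D`. The asymptotic p is known to be slightly
conservative at small effective n; the calibration test below measures
the realised level.

**Calibration protocol.** The level of the repeated procedure cannot be
read off a single call: all runs share one observed sample, so their
outcomes are strongly correlated, and if the observed values also sit in
the subsampling pool the overlap biases D down. The calibration test in
this package therefore estimates the level from 50 independent observed
draws × 20 runs each (1000 KS tests), with each observed sample held out
of the pool it is tested against. Measured levels on the synthetic
foraging setup are 0.04–0.05 at α = 0.05.

## Tortuosity (entropy) profile

The per-fix unpredictability score is a self-contained operator: within a
±5-minute window around each fix, the (turn angle, segment speed) pairs
are binned on a fixed 8 × 4 grid — turn-angle bins uniform over
(−180°, 180°], speed bins delimited by the track's own speed quartiles so
the operator is scale-free across individuals — and the fix's score is
the Shannon entropy (bits) of the normalised histogram, in [0, log₂ 32].
Fixes with fewer than 5 pairs in the window are flagged undefined. Speeds
are rounded to 10⁻⁹ m s⁻¹ before binning so float noise cannot scatter a
perfectly steady leg across a quartile edge. Turn angles are signed
changes in initial bearing (right turns positive), wrapped to
(−180°, 180°]; they are invariant under rigid rotation of the track, so
the profile is too. For display, entropies are categorised into
within-track quantile bins (default 5), a monotone mapping; an all-equal
profile collapses to category 1. This operator reproduces the *role* of
spatio-temporal predictability scores from the machine-learning tracking
literature — low entropy on straight commuting legs, high entropy in
tortuous search — not any specific published estimator, and no
figure-level numerical agreement is claimed.

## Synthetic data: what it emulates, and what it does not

The two-state simulator draws per-step speeds log-normally with
natural-scale moments (0.83, 0.13) for drift and (10.20, 27.0) for flight
— the flight variance stands in for wind-driven ground-speed variation,
which is not modelled explicitly — switches states with per-step Markov
probabilities (default 0.005 at a 5-s step, mean bout ≈ 17 min), and
walks the heading with von Mises noise (κ = 50 in flight, 0.5 in drift).
Duty-cycling keeps 60-s bursts every 2 h (burst length is a logger
configuration choice, not a property of the analysis); acquisition bias
thins fixes independently with state-dependent probabilities. The
synthetic bathymetry deepens with longitude only: land, a shallow shelf
(150 m), a steep slope, a monotone 600–1000 m shelf-break band, and a
2,500 m abyssal plain, with small (2 m) seeded cell noise outside the
band; the default cell is 0.0025° (~270 m), the resolution class of
national bathymetry grids. The shelf-foraging simulator alternates fast
commuting legs with slow drift bouts steered over the band, giving an
end-to-end positive control with a known depth preference.

Passing tests on these generators show that the *pipeline* recovers what
it assumes: well-separated log-normal speed modes, Markov switching,
rotation-invariant geometry, and a depth preference expressed through
position. Real tracks add what the generators omit: wind and current
advection, smooth speed transitions during take-off and landing, spatially
correlated GPS error, tide-coupled drift, and coastline geometry that
constrains rotations asymmetrically. Results on synthetic data therefore
validate correctness of the machinery, not ecological effect sizes.

## Deployment log

The bundled 14-record deployment log (February 2006, Great Barrier
Island) reproduces deployment-level bookkeeping; the recovered-with-data
rule leaves the 9 deployments that yield analysable tracks. Trip-level
area summaries use the convex hull, which is well-defined but generous
for non-convex excursions; published area figures for such deployments
depend on the (often unstated) area definition and are not comparable
across definitions.

## Problem sizes

Default test and acceptance runs use 5,000-speed mixture samples (100
replicates for recovery rates), 12–24 h simulated tracks, 1,000-run KS
repetitions, and 50-replicate end-to-end power checks — sizes at which
every Monte-Carlo acceptance band is stable to the seed while the whole
suite runs in well under a minute per module.
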