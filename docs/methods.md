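# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Trip segmentation

A *visit* is an inferred drinking event. With hourly fixes the animal is
rarely observed exactly at water, so a fix belongs to a visit when its
distance to the nearest water-retaining waterhole is **strictly below**
the threshold `d_thr_km` (default 1.0 km). The rationale for ~1 km: an
animal pausing ~15 min at water and otherwise walking a straight line at
no more than 3 km/h moves at most ~1 km within the hour around the stop,
so every true visit produces at least one sub-threshold fix. Each maximal
run of consecutive sub-threshold fixes collapses to the single
closest-to-water fix (earliest fix on an exact tie — deterministic and
order-stable); the visited site is the nearest waterhole to that fix
(lower `site_id` on a tie). Only water-retaining sites participate; a
table with no water-retaining site is a fatal error.

Trips are the segments between consecutive visits, inclusive of both
boundary fixes (adjacent trips share exactly one fix). A trip is
*looping* when start and end sites coincide, *commuting* otherwise.

**Gap rule.** When a within-trip fix interval exceeds `gap_limit_h`
(1.5 h), we compute the speed that a detour from the last acquired fix to
its nearest water-retaining waterhole and back to the current fix would
have required. If that speed is below `v_max_kmh` (3 km/h) the animal
could have drunk unobserved, the trip boundary is untrustworthy, and the
whole trip is removed (`status = removed_gap_rule`). The nearest
waterhole is taken from the *last* fix, reading the rule's "from the last
acquired location to the closest waterhole" literally. Trips shorter than
12 h are flagged, never auto-removed: the original screening of short
trips was a manual, visual step that an algorithmic pipeline should
surface rather than silently reproduce.

A mid-trip pass within `d_thr_km` of any water-retaining waterhole counts
as a visit and cuts the trip. The data cannot distinguish passing from
drinking; this is one consistent reading and it keeps the partition
property (every interior fix belongs to exactly one trip).

## Geometry

All distances are Euclidean meters in a local azimuthal-equidistant frame
centered (by default) on the waterhole centroid. The projection is built
from Vincenty inverse/direct geodesics on WGS84, so distances from the
origin are exact geodesics and pairwise distances are within 0.005% of
the geodesic over a 150 km extent (tested against an independent
meridian-arc oracle) — far below both the GPS error (30 m at 95%) and the
segmentation threshold. Timestamps are normalised to UTC; no local-time
analysis exists downstream, so the (unknown) collar timezone is
irrelevant.

## Models

*Trip-level* (response ∈ {distance traveled, max distance to start/end
waterhole, mean speed}): fixed effects = looping intercept, commuting
offset, trip duration, commuting × duration; random intercept plus
random slopes (commuting, duration) by individual. Fitted with
statsmodels `MixedLM`. When the random-slope fit fails to converge (small
simulated datasets often put slope variances on the boundary) the model
falls back to a random intercept and the fit is marked accordingly — the
same fallback the original analysis strategy describes for its
within-trip models.

*Within-trip speed*: four candidates — distance-to-water or progression
(% of trip duration elapsed), linear or quadratic — each fully crossed
with trip type and duration (the quadratic progression model has the full
12-term layout), random intercept by individual, all fitted by **maximum
likelihood** on the identical step table and ranked by AIC with
k = fixed effects + variance parameters. ML (not REML) is required for
AIC comparison across different fixed-effect structures. Progression
enters as a raw (not orthogonalised) polynomial so coefficients are
directly readable against the reported table layout.

Random-intercept models are estimated by an exact profiled-ML solver:
for a fixed variance ratio λ = σ²_b/σ²_e the GLS problem whitens to OLS
via x → x − γ_g·mean_g(x), γ_g = 1 − (1+λn_g)^{−1/2}, leaving a
one-dimensional bounded optimisation over log λ (boundary λ = 0 checked
explicitly). This makes the tens of thousands of bootstrap refits cheap
and is validated against statsmodels ML estimates in the test suite.

**Parametric bootstrap.** Each replicate simulates a response from the
fitted model — fixed effects + new group effects drawn from the estimated
random-effect covariance + residual noise — and refits the same
specification; CIs are percentile intervals (the simplest consistent
reading; basic/BCa are deliberately not offered), significance = CI
excludes zero. Failed refits are redrawn once then dropped; >5% failures
is an error. Default `n_boot = 10000`; tests and the acceptance script
use scaled-down values (200–1000) with the default documented here.

**Classical tests.** Duration distributions of looping vs commuting trips
are compared by a chi-square test of homogeneity over the five reporting
bins (≤12, 12–36, 36–60, 60–84, >84 h; right-closed, so exactly 12 h is
in the first bin); all-empty bins are dropped and bins with expected
count < 1 are merged with a neighbor (the merge is reported — the
original binning for the test is not documented, so this rule is the
package's own). Seasonal speeds are compared by a Welch t-test, with the
wet-season exceedance fractions above 0.8/1.0/1.2 km/h reported.

**Closest-waterhole analysis.** The reference point from which "closest"
is judged is genuinely ambiguous; the package uses the trip's *apogee*
(the fix attaining the maximum distance to the start/end waterholes) as
the natural turning point, with an alternative `return_min` reference
(minimum over the whole return leg) behind a switch. A 0.1 km tolerance
keeps GPS noise (95% radius 30 m) from flipping the classification.

## Synthetic-data generator

The generator emulates the study design the analysis assumes:

- **Sampling**: 1 fix/h over a 3-week burst (504 h) for 10 individuals;
  interior fixes dropped independently at rate 0.008, reproducing the
  ~0.8% of intervals > 1.5 h; isotropic Gaussian GPS error with per-axis
  σ = 30/√(−2 ln 0.05) ≈ 12.26 m so the 95% radial error is 30 m.
- **Landscape**: 30 waterholes uniform over a 50 km square with ≥ 2 km
  spacing (rejection sampling); all retain water by default.
- **Trip durations**: lognormal mixture with components at modes
  6/24/48/72 h, weights (0.167, 0.382, 0.377, 0.074) — the five observed
  duration-bin proportions with the two top bins pooled on the 72-h
  component — and log-sd 0.12, chosen so the implied bin proportions are
  ≈ (16.7, 37.7, 36.4, 7.6, 0.9)%. A four-mode mixture cannot match all
  five bins exactly; mode preservation was preferred. Durations are
  rounded to whole hours so trip boundaries fall on sampling ticks.
- **Trip types**: commuting with probability 0.4 when another
  water-retaining site is in reach, else looping (counted). Destinations
  are drawn uniformly among sites within reach.
- **Speed**: commanded hourly speed = a + b·p + c·p² + noise, truncated
  at 0, with p the progression in %; defaults a = 0.777, b = −0.027,
  c = 2.81·10⁻⁴ km/h (a U-shape: fast leaving water, slow mid-trip, fast
  returning). Commuting adds an intercept premium 0.318 − 0.004·duration
  and small b/c offsets, so short commuting trips are the fastest.
  Individuals get a N(0, 0.1) intercept offset (the random-intercept
  structure the models assume). A feasibility floor rescales a trip's
  speeds upward when its travel budget could not clear the detection zone
  and reach the end site — the same short-trip speed premium the data
  show.
- **Paths**: per-minute waypoints; outbound correlated random walk
  (5°/min heading noise) pushed off the start site, then homing toward
  the end site with terminal guidance so every trip ends exactly at its
  destination on a tick. Candidate paths whose mid-trip ticks dip inside
  the waterhole detection zone, or whose approach/departure is not
  monotone within it, are redrawn (≤30 times, give-ups counted):
  this guarantees that on noise-free data the visit detector recovers the
  generator's trips *exactly*, which is what the truth-recovery tests
  assert.
- **Wet season**: hourly speeds lognormal with mean 0.33 and sd
  0.52 km/h; the implied exceedance above 0.8/1.0/1.2 km/h is
  ≈ 8.8/6.0/4.4%.

**What passing tests do and do not show.** The generator reproduces the
*statistical structure* the pipeline assumes: tick-aligned trips, a
U-shaped speed profile in progression, lognormal duration modes,
independent Gaussian GPS error, independent fix drops. Real telemetry has
autocorrelated errors, behaviour-dependent fix failure, trips that pause
at water without drinking, and speed profiles that vary between
individuals in shape, not just level. Exact truth recovery on clean
synthetic data therefore validates the *implementation* of the
segmentation rules, not their ecological adequacy; the threshold
sensitivity sweep is the in-package check that conclusions do not hinge
on the 1 km choice. Hourly sampling of the per-minute path underestimates
true path length (tortuosity), as telemetry always does; recorded truth
speeds are tick-scale displacement speeds so that recovery is exact.

## Numerical choices and degenerate inputs

- Threshold comparisons are strict (`< d_thr`); a fix at exactly the
  threshold is outside.
- Profiled-ML search over log λ ∈ [−12, 12] with the λ = 0 boundary
  evaluated explicitly; design matrices are solved by SVD least squares
  after whitening (stable under the 10⁻⁷…10⁶ scale spread of the
  progression² × duration interactions).
- A response with zero residual variance yields zero estimates and a
  `zero residual variance` note rather than a crash.
- Zero-length step intervals are an error (they would produce infinite
  speeds); duplicate timestamps are removed at read time, so they can
  only arise from hand-built inputs.
- Trips with fewer than 2 fixes are excluded from statistics; fewer than
  2 visits yields an empty trip list, not an error.
- Problem sizes in tests and the acceptance script (5–10 individuals,
  150–504 h windows, n_boot 200–1000, 40–300 replicates) are scaled-down
  versions of the default study conditions, chosen to exercise every
  code path at comfortable runtimes; the defaults remain the documented
  study-scale values.

## Known limitations

- No behavioural-state segmentation (HMMs), day/night splitting,
  home-range or habitat-selection analyses; no autocorrelated-residual or
  GAMM speed models.
- The bootstrap treats the fitted variance components as truth
  (parametric); with few individuals the random-intercept variance is
  estimated noisily and coverage for *variance* parameters is not
  assessed (fixed effects only).
- The visit definition cannot distinguish drinking from passing near
  water; with real data this inflates visit counts near well-traveled
  waterholes.
- The wet-season comparison uses a parametric stand-in for wet-season
  steps rather than simulated wet-season trajectories (wet-season
  movement is not organised around waterholes, so the trip machinery does
  not apply).
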