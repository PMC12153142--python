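# Methods

This note documents the models implemented in detourkit, the
operational definitions chosen where the underlying field conventions
are loose, the parameter defaults and their calibration, and what the
synthetic-data generator does and does not emulate.

## Route geometry

**Distances.** Route lengths are WGS84 ellipsoid geodesics (Vincenty's
inverse formula, validated against `geosphere::distGeo`), summed over
consecutive fixes.  Great-circle *construction* — reference routes,
initial bearings, along-route interpolation — is spherical (mean radius
6 371 008.8 m), matching `geosphere::gcIntermediate`.  The mixed
convention is deliberate: it mirrors the de-facto toolchain of movement
ecology, and the sphere-vs-ellipsoid discrepancy is below 0.5 % at
migration scales, which the test suite asserts.  Reference routes are
sampled at ≤ 100 km spacing with the smallest point count that
satisfies the bound.  Near-antipodal distance queries fall back to the
spherical law of cosines; antipodal route construction is a hard error.

**Fix filtering.** GPS and ARGOS classes LC1–LC3 are always kept,
LCA/LCB always dropped.  LC0 is kept only when its cross-track distance
to the great circle through the nearest retained neighbours is below a
threshold (default 100 km, configurable) — an explicit, reproducible
stand-in for the manual "no significant deviation from the route"
screening usually applied to duty-cycled tags.  LC0 fixes without
retained neighbours on both sides are dropped.

**Stopovers.** A "day" is the UTC calendar day.  A day's travel is the
*net* displacement between the track's interpolated positions at the
day's boundaries, which stays well defined across multi-day ARGOS
silences.  Stopovers are maximal runs of consecutive days each below
50 km/day, kept only when strictly longer than 3 days; intervals are
half-open `[arrival, departure)`.  Net (not summed-path) displacement
was chosen because within-day foraging loops should not disqualify a
stationary day.

**Movement segments.** PTT mode: runs of daytime fixes (default window
00:00–14:00 UTC, the tags' programming window) within one UTC day,
kept when displacement > 50 km and duration ≥ 4 h.  GPS mode: one
segment per UTC day from the day's first to last fix; single-fix days
are skipped.  The segment midpoint is the fix nearest the temporal
middle, ties toward the earlier fix.  Segments are built from the
stopover-filtered track: stationary stopover days would otherwise
contribute spurious near-zero "movement" segments that dilute the wind
analysis.

**Projection onto the reference route.** For the tailwind comparison,
each fix is mapped to the point at the same fraction of cumulative
route distance along the reference route, keeping its timestamp.
Distance-fraction matching is our choice among several defensible
alignments (the common alternative, matching by longitude, fails for
near-meridional routes like this one); users comparing against other
implementations should be aware of it.

## Flight energetics

The chemical power curve follows the standard fixed-wing decomposition:

* induced power `k (m g)^2 / (2 ρ v Sd)`, disc area `Sd = π b²/4`;
* parasite power `½ ρ v³ Sb CDb`, body frontal area
  `Sb = 0.00813 m^0.666`;
* profile power, a constant `8.4 / aspect-ratio` times the absolute
  minimum of induced + parasite;
* chemical power = 1.1 × mechanical / η + BMR (the additive basal term
  can be switched off).

BMR uses the non-passerine allometry `78.3 · M^0.723` kcal/day
(thermochemical kilocalorie, 4 186.8 J, stated to avoid a 0.07 %
dialect discrepancy), soaring power is 4 × BMR, and the cross-country
speed maximises `v c / (c + s(v))` with sink rate
`s(v) = P_mech(v)/(m g)`.  V_mp and V_mr are solved numerically
(bounded scalar minimisation, tolerance 1e-10) on a 1–60 m/s bracket;
an optimum at a bracket edge is an error except for V_cc, where very
strong climbs legitimately push the optimal glide to the fastest speed
considered.

**Calibration (frozen).** Two constants are calibration parameters
rather than literature values, fixed once and shipped as defaults:

* muscle conversion efficiency **η = 0.113**.  With the textbook
  efficiency of 0.23 a rigid fixed-wing curve prices flapping flight at
  ~0.62 J/m for this morphology — roughly half the cost that
  flapping-kinematics models assign to a 291 g flap-gliding harrier,
  whose wingbeat adds substantial induced and inertial losses the
  fixed-wing idealisation omits.  Folding those losses into the
  conversion efficiency is the single-knob choice that keeps every
  aerodynamic constant at its published value; 0.113 sits at the low
  end of empirically reported whole-animal efficiencies (≈ 0.10–0.23).
  With it, C1 evaluates to 1.1599 J/m for the study morphometrics.
* default thermal climb rate **c = 2.29 m/s**, a typical mid-day
  convective climb for a light soaring raptor; it yields
  V_cc = 15.24 m/s and C2 = 0.40796 J/m.

Both are ordinary config fields (`FlightConstants`) and can be
overridden; they are never re-fitted at run time.  The barrier distance
Y_b is an input to the detour model — computed, when rasters are
available, by the terrain module as the along-route extent above the
elevation contour — not an energetics quantity.

## Wind drift analysis

Wind is interpolated trilinearly (bilinear in lon/lat, linear in time)
from a 2.5°, 6-hourly u/v grid at one pressure level; out-of-bounds
queries raise rather than extrapolate or clamp.  Per segment, the wind
is the (1, 2, 1)/4 weighted average of onset, midpoint and end,
emphasising mid-segment conditions.

The intended direction of a track is the initial great-circle bearing
from its start to its end fix.  Wind and the segment's daily
displacement vector are rotated into that frame; the perpendicular
axis is positive to the *right* of the goal bearing for both wind and
movement.  Only sign agreement enters the behaviour labels, so any
consistent convention reproduces them; outputs print both the vector
("blowing toward") and meteorological ("blowing from") wind direction
to avoid ambiguity.  The movement vector uses the great-circle bearing
and geodesic distance from segment onset to end on a local tangent
plane — at segment scales (< 600 km) the planar error is < 0.3 %.

Labels: |perpendicular movement| > 50 km/day with the sign of the
crosswind is **drift**; within ±50 km/day is **compensation**;
beyond the threshold against the crosswind is **overcompensation**;
beyond the threshold with exactly zero crosswind is **unclassified**
(the sign comparison is undefined — such records are reported, not
silently binned).  Latitude banding (< 30°, 30–40°, > 40°N) uses the
segment midpoint fix.  Band tables get a Pearson chi-square (empty
bands excluded with a warning), regressions are ordinary least squares
per season, and the AMR-vs-GCR tailwind comparison is a paired
two-sided t-test over segments matched by identity (same timestamps,
positions projected onto the reference route); unpaired tracks are
excluded and logged, never guessed at.

One caveat worth stating: because the intended direction is estimated
from the realised endpoints, sustained one-sided drift rotates the
frame downwind and is partially absorbed into it.  The synthetic
full-drift test therefore classifies against the generator's intended
bearing; with real data the bias is small whenever net lateral
displacement is small relative to route length.

## Terrain and habitat

Raster sampling is nearest-cell with no interpolation, matching the
point-sampling convention of desktop GIS; nodata is propagated as
missing, never as a value.  Raster I/O uses the plain-text ESRI ASCII
grid format (readable by QGIS/GDAL), keeping fixtures
human-inspectable.  Barrier extent along a sampled route is the summed
length of maximal above-threshold runs, each extended to the midpoints
of its flanking sample intervals (clipped at route ends) — an unbiased
crossing-length estimate that is monotone non-increasing in the
threshold.  Elevation band summaries (10° bands, 8–58°N) use the
unpaired Mann–Whitney rank-sum test, since the two routes contribute
unequal point counts and are not meaningfully paired point-by-point.
Altitude above ground preserves negative values (GPS error) flagged
rather than clipped.  The 37-code ESA-CCI → 8-class reclassification
ships as an editable TOML (`detourkit/data/esa_cci_reclass.toml`) with
our best-guess grouping documented code-by-code; unmapped codes are a
named error.  Stopover footprints are planar convex hulls of lon/lat
fixes (100 % MCP, counter-clockwise ring) — adequate below ~200 km
extents where metric distortion is far below raster cell size.  Monthly
NDVI means test cell centres against the polygon, boundary inclusive.

## Synthetic data

The generator targets the *statistical structure* the analysis
assumes, not behavioural realism: no fly-and-forage, energy budgets or
thermoregulation.  Defaults emulate the study population: 9
individuals, 40 tracks between ~9°N and ~47°N, daily travel
~120–220 km/day (Normal(170, 25), floored at 60), stopovers of 5 days
at 45 % of the route, GPS cadence of 10-min fixes by day (movement
executed 00:00–14:00 UTC) and hourly fixes by night, or a 10 h ON /
48 h OFF ARGOS duty cycle with per-class positional noise
(LC3 0.15 km … LCB 25 km).  Winds live on a 2.5°, 6-hourly grid with
zonal bands — easterlies south of ~27.5°N, westerlies north of
~32.5°N, a linear transition whose knots sit on grid latitudes so
trilinear interpolation reproduces the analytic field exactly — plus
optional seeded noise.  The elevation raster is a flat background with
a Gaussian ridge across the direct corridor, parameterised directly by
its width at the 3 500 m contour (default 700 km, peak 6 000 m) and
tapered west of 66°E so the detour corridor stays clear.

Movement is simulated in the coordinate frame of the reference path
(optionally routed through waypoints to force a detour): the along-path
coordinate advances by the daily draw; the perpendicular offset
performs the drift random walk `y += β · crosswind + Normal(0, σ)`
with β = 24.7 km/day per m/s by default and no homing correction —
exactly the linear model the drift regression estimates.  The daily
crosswind is sampled the way the analysis measures it ((1, 2, 1)/4
over the day's onset, temporal midpoint and end), so parameter
recovery is an exact statement rather than an approximate one.  All
draws flow from one seeded generator per dataset; ground truth
(stopovers, β, per-day vectors, route length, goal bearing) is
serialised beside every output.

What passing tests therefore show: the pipeline recovers what the
generator put in — stopover intervals exactly, the drift coefficient
within sampling error, constructed barrier widths within the sampling
resolution.  What they do not show: robustness to heavy-tailed ARGOS
error, behaviourally driven route choice, vertical wind structure, or
observation gaps correlated with behaviour — none of which the
generator emulates.

## Numerical and interface choices

* All time intervals are half-open `[start, end)`; timestamps are UTC.
* Optimisation tolerances: 1e-10 (speed solves); interpolation
  equalities asserted at 1e-9 … 1e-12 in tests.
* Wind NetCDF I/O is NETCDF3_CLASSIC via xarray's scipy backend
  (reanalysis `uwnd`/`vwnd` dialect, `m/s` units validated on load).
* The pipeline's self-contained mode runs a 6-track synthetic cohort
  routed through a western waypoint (~19 % configured detour); problem
  sizes throughout the test suite (4–20 tracks, ~150 segments for
  regression recovery) were chosen as the smallest cohorts whose
  recovery statistics are stable across seeds.
* Degenerate inputs raise named errors (`ValidationError`,
  `DegenerateTrackError`, `DegenerateGeometryError`, `NumericalError`,
  `OutOfBoundsError`) rather than returning sentinel values.

## Known limitations

* The fixed-wing power curve with calibrated efficiency is a
  transparent surrogate for a full flapping-kinematics model; absolute
  powers inherit the calibration, while the *shape*-derived quantities
  (V_mp < V_mr, convexity) are model-generic.
* MCP and the tangent-plane movement decomposition are planar
  approximations with documented validity ranges.
* No state-space filtering of ARGOS error, no behavioural change-point
  segmentation, no reanalysis download clients, no reprojection beyond
  geographic-CRS conventions.
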