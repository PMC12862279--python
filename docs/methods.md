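# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Dive detection and metrics

Depth is positive-down (m) with UTC timestamps throughout; bathymetry is
converted to the same convention (land = 0).

**Zero-offset correction.** Pressure transducers drift slowly, so raw
surface readings wander away from 0 m. The correction subtracts a centred
rolling minimum of the depth trace (default window 30 min) and clips at 0.
Any 30-min window contains at least one surface interval provided no dive
exceeds the window length, so the rolling minimum tracks the surface
baseline; the generator caps dive durations below 30 min for the same
reason. The operation is idempotent, and on a drift-only (noise-free)
record it recovers dive depths to better than 0.5 m (half the within-window
drift at 2 m/h). With sensor noise the subtracted minimum is biased by the
most negative noise excursion in the window, on the order of 2–3 noise
standard deviations; this bias is common to all depths in a window and does
not affect dive detection or classification.

**Dive definition.** A dive is a maximal span of samples deeper than a 2-m
surface gate whose maximum depth is at least 25 m and whose duration is at
least 32 s (both inclusive). The 2-m gate is a design choice: the
convention for this kind of detector uses a small surface gate below the
25-m qualifier and above sensor noise, and it is configurable. Dive
duration is counted as submerged samples × sampling interval, which makes
dive plus surface durations add up to the record length exactly.

**Phases.** The bottom phase is the contiguous span between the first and
last sample at ≥ 80% of the dive's maximum depth; descent and ascent are
what precede and follow it. The 80% rule is the standard
pinniped-literature convention; it is exposed as a parameter
(`bottom_fraction`) because it is a stand-in for unpublished tool-specific
phase definitions. Note the rule places short descent/ascent tails inside
the bottom phase of steep dives; metrics and the benthic bottom-phase KDE
inherit those tails.

**Metrics.** W counts maximal monotone vertical excursions in the bottom
trace with amplitude ≥ the wiggle threshold (default 5 m — "wiggle" has no
published magnitude, so the threshold is configurable); V is the summed
|Δdepth| over the bottom phase; R the bottom depth range; T the bottom
duration. Descent rate is depth at the bottom-phase start divided by time
from the dive start; ascent rate likewise from the bottom-phase end.

## Classification

Each detected dive gets exactly one label, testing **foraging → drift →
benthic → transit** in that order (the order the criteria are usually
presented; the original decision tree is not public, so precedence is a
documented, configurable default).

- **Foraging**: `FII = W·V/R + (W·V/R)·(V/T) > 35`, strict. `W = 0` or
  `R = 0` gives index 0.
- **Drift**: Gaussian KDE of the whole dive's vertical speed (first
  differences over the sampling grid). Drift iff the global peak's density
  height exceeds 1 s/m; the drift rate is the peak location.
- **Benthic** (only for dives that failed both tests above): (a)
  |max depth − bathymetry| < 100 m (absolute difference — dives can appear
  deeper than a coarse grid cell); (b) bottom-phase speed KDE peak within
  ±0.08 m/s (inclusive) and height > 1.5; (c) least-squares lines through
  the descent-phase and bottom-phase depth-vs-time points intersect at a
  time where the vertical distance between the intersection and the
  observed profile is < 15 m. The 15-m criterion is read as a vertical
  offset because depth–time space has mixed units; a Euclidean distance
  would be meaningless. Dives without an assignable bathymetry fail the
  benthic test with a `no-bathy` flag.
- **Transit**: the residual class.

**KDE details.** Bandwidth follows Silverman's rule of thumb,
`0.9·min(sd, IQR/1.34)·n^(−1/5)`, with a 10⁻³ m/s floor; evaluation is on a
2048-point grid spanning the sample ± 6 bandwidths, so the density
integrates to 1 within 10⁻⁶ and the peak height is in honest density units
(s/m). At least 10 speed samples are required; shorter phases return
"no peak" and cannot be drift or benthic. The height thresholds (1 and 1.5)
are bandwidth-sensitive — the robust IQR term makes the bandwidth collapse
when more than half the sample sits in one tight mode, which is precisely
what makes the drift criterion sharp — so the bandwidth rule is exposed as
a parameter and the sensitivity is deliberate, documented behaviour rather
than something the package hides.

## Geolocation

The upstream state-space track model is an external tool; the package
substitutes a forward speed filter (drop fixes implying > 3 m/s to the last
retained fix) followed by great-circle interpolation at exact 3-h steps.
This is adequate because downstream analyses only need regular positions at
trip scale, where location error is small relative to movement. The regular
grid always includes the final fix time so positions near the trip end are
interpolated rather than pinned to the last whole 3-h step. Per-dive
positions interpolate in time between bracketing grid positions (nearest
endpoint, flagged, outside the span). Distances use the haversine on a
sphere of radius 6371.0088 km. Bathymetry lookup is nearest-cell — matching
the semantics of a coarse 4-arc-minute raster and keeping the 100-m benthic
gate conservative — and ESRI ASCII grids are read with ETOPO conventions
(positive elevations → land → 0, negative → positive-down depth).
Longitudes are normalised to (−180, 180]; antimeridian-crossing polygons
are out of scope for the study region (NE Pacific).

## Shelf-crossing analysis

A dive is *on-shelf* iff it is benthic with max depth ≤ 140 m (the
shelf-break isobath, inclusive). Within the first and last 72 h of a trip
(trip start/end = first/last detected dive), run-length encoding of the
on-shelf flags yields *qualifying blocks* (≥ 5 consecutive on-shelf dives)
and *sustained off-shelf runs* (≥ 5 consecutive dives that are not
on-shelf; the symmetric count quantifies the otherwise-unquantified
"sustained/extended", and is configurable). Departure: duration from the
first dive of the first qualifying block to the last on-shelf dive before
the first sustained off-shelf run; the transition is the first dive of that
run. Arrival: duration spans the on-shelf dives from the first qualifying
block that follows a sustained off-shelf run to the last such dive; the
transition is the first dive of that block. Windows without a qualifying
block produce a flagged missing record and are excluded from duration
summaries. Metric summaries split each phase window at the transition time
and aggregate in two stages: per-seal means first, then grand mean ± SE
across seals (SE = 0, flagged, for single-seal cells).

## Diel timing and circular statistics

Sunrise/sunset use the NOAA solar-position equations (fractional-year
expansions of the equation of time and solar declination, zenith 90.833° =
refraction plus solar radius), accurate to about ±2 min at non-polar
latitudes; polar day/night returns a flagged sentinel. A dive is *daytime*
iff it starts in [sunrise, next sunset) — sunrise inclusive, sunset
exclusive.

Departure (first dive) and arrival (last dive) clock hours are mapped to
angles θ = 2π·hour/24 and summarised by the mean resultant length
R̄ = |Σe^{iθ}|/n, the circular mean hour, and the Rayleigh uniformity test
with Z = nR̄² and Zar's series p-value, clamped to (0, 1]; a Monte-Carlo
p-value is available for very small samples. Hours default to colony local
clock time (UTC−7); local solar hour at the event longitude is also
computed. R̄ is rotation-invariant and the test's type-I error is
calibrated (≈ 0.05 at α = 0.05 under uniform timing).

## Summaries

Type tables pool dives (not seals) within each stratum; dives without
locations are counted in a separate column but kept in totals. Predator
percentages are taken over benthic dives: shark, orca, union ("total"), and
intersection ("overlap"), so overlap ≤ min(shark, orca) ≤ total ≤ 100 by
construction. Binned dive-type proportions use lower-exclusive,
upper-inclusive bins ((k−1)·w, k·w] with w = 200 m for bathymetry and
300 km for colony distance; a value of exactly 0 joins the first bin.

## Synthetic-data generator

The generator is the package's test bed: it produces seeded,
ground-truth-labelled cohorts with the statistical structure the analysis
assumes. Per trip: an opening run of benthic dives over the shelf, a
transit leg crossing the slope, a deep-water interior drawn from the
configured type mixture (defaults 40/35/20/5% transit/foraging/drift/
benthic) out and back, a returning slope leg, and a closing benthic run.
Horizontal distance advances at a constant ground speed per phase (1.2 m/s
while diving on station, 2.3 m/s on the directed slope crossings) so the
3-h track grid resolves the crossings and never trips the 3 m/s filter.

Archetype geometry is built so that each class satisfies its defining
criterion with margin: foraging bottoms carry 4–8 wiggles of 8–15 m at
0.4–0.9 m/s (index comfortably above 35); drift dives spend ≥ ~75% of
samples at one rate drawn from ±(0.22–0.38) m/s with fast (1.8 m/s)
descent/ascent so the whole-dive speed density concentrates sharply;
benthic dives hold a flat bottom within ~4 m of the seafloor (flat holds
punctuated by small alternating 2-m steps — a sharp zero-speed density peak
without a degenerate sample) at 40–45% of the dive duration, so the
bottom-phase KDE clears 1.5 while the whole-dive peak stays below the drift
threshold of 1; transit dives are V-shaped with jittered rates. All dives
clear 25 m and 32 s unless generated with the subthreshold flag (shallow
~12–20 m excursions used to exercise the detector's rejection path).

Realism constants chosen once: 8-s default sampling; ±2 m/h linear
surface-offset drift (typical transducer magnitude, sign randomised);
0.3 m Gaussian sensor noise truncated at ±3σ (bounded noise keeps dive
boundaries crisp at the 2-m gate, mimicking quantised TDR readings); shelf
width 10 km with depth 120 m at the edge, a 10-km slope to a 600-m open
ocean (the 140-m isobath falls a finite, bisection-recoverable distance
offshore); 90–180-s post-dive intervals; departures drawn from a weak von
Mises concentration (κ = 0.4, R̄ ≈ 0.2) around 19:00 colony time; ~170
interior dives per trip (runtime-friendly scale; trips span ~2 days rather
than months). Tracks are noise-free at the interpolated 3-h resolution —
the generator does not emulate Argos error classes, haul-out behaviour,
bathymetric roughness (seamounts), prey fields, or multi-month trip
durations, so passing tests demonstrate the pipeline's correctness on
records with the assumed structure, not robustness to every field
pathology. Interior benthic dives near the shelf-slope speed change can be
assigned slope bathymetry by the 3-h interpolation and fail the 100-m gate
— a realistic interpolation-error effect that appears as a ≲0.1% benthic →
transit confusion.

## Numerical choices and edge cases

- Strict inequalities for "greater than"/"exceeded"/"less than" thresholds
  (35, 1, 1.5, 15 m, 100 m); inclusive for "at least" (25 m, 32 s), the
  ±0.08 m/s window, and the ≤ 140 m shelf criterion.
- Degenerate dives (< 5 samples) get a flagged single-sample bottom phase;
  constant speed samples fall back to a delta-like KDE peak at the common
  value; parallel descent/bottom fits fail the corner test.
- Timestamps are UTC nanosecond-precision internally; generator trips start
  on whole seconds so CSV round-trips are exact.
- Seed handling: one integer seed fans out to per-seal independent streams
  via `SeedSequence.spawn`; identical configuration and seed reproduce
  byte-identical outputs.

## Known limitations

- The classification precedence and the 80% bottom-phase rule are
  documented stand-ins for unpublished conventions of the original
  MATLAB tooling; both are configurable.
- Peak-height thresholds interact with the bandwidth rule; results with a
  different KDE bandwidth are not comparable.
- GLM/GLMM model fitting is out of scope; `export_model_tables` writes
  analysis-ready per-dive and per-seal-phase tables (with a data
  dictionary) for external statistics software.
- No map or rose-plot rendering; outputs are tables.
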