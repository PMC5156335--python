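# Methods

This note documents the models, rules and numerical choices behind `xema`,
and what the synthetic-data tests do and do not establish about real
geolocator data.

## Threshold geolocation

Each tag records one sunrise/sunset pair per UTC day. With sun elevation
angle `a` (the calibration angle at which the tag's light threshold is
crossed), declination `δ` and latitude `φ`, the half-day hour angle `H`
satisfies

    cos H = (sin a − sin φ sin δ) / (cos φ cos δ).

Longitude comes from the twilight midpoint: `lon = −15°/h · (t_mid − 12 h +
EoT)`, with the midpoint taken on the shorter arc so sunsets past midnight
UTC average correctly, and the equation of time (EoT) from a truncated
Fourier ephemeris (Spencer-type coefficients; declination accurate to
~0.2°, EoT to ~0.5 min — far below tag noise). Latitude is recovered from
day length `D = 2H/15` by root-finding on `φ ∈ [−85°, 85°]` (Brent's
method, xtol 1e-7); day length is monotone in latitude for fixed `δ ≠ 0`,
so the root is unique. Both the forward model (used by the simulator) and
the inverse evaluate the ephemeris at 12:00 UTC of the record's date, so
zero-noise round trips are exact to solver tolerance (criterion: 0.2° lon /
0.5° lat).

Sentinels: no real solution of the hour-angle equation maps to POLAR_DAY /
POLAR_NIGHT. The sun angle defaults to −3.44°, a conventional geolocator
calibration; it is a config key because real tags require per-deployment
calibration.

**Conditioning.** The latitude error is (twilight noise) / |dD/dφ|. The
sensitivity |dD/dφ| collapses both when `δ → 0` (the equinoxes: ~12 h days
everywhere) and at low latitudes generally. Days with |δ| < 5° are
`equinox_flagged` (≈ ±13 days around each equinox — a window tied to the
actual ill-conditioning rather than fixed dates). The pipeline additionally
computes |dD/dφ| by finite difference and treats any day below
4 min/° (≈ 1.4° expected error at the default 4-min twilight noise) as
needing SST support (`sst_scope="auto"`; `"equinox"` and `"all"` are
available).

## SST latitude correction

For a day needing support, the 8-day composite whose [start, start+8 d)
interval contains the date is scanned along the twilight longitude (nearest
grid column averaged with its two neighbours) within ±15° of the threshold
latitude (unbounded when the threshold latitude is flagged or missing).
Latitudes whose profile temperature lies within 0.5 °C of the tag value
form candidate runs; each contiguous run contributes its best-matching
latitude (the crossing), and the candidate nearest the previous day's
latitude wins — the disambiguation rule for multi-crossing profiles. Two
practical refinements:

- the daily tag series is 1:2:1-presmoothed before matching (daily minimum
  SST is noisy relative to 8-day composites; a centred average reduces
  noise without lagging a moving bird);
- a run wider than 6° means the profile is locally flat and its
  best-match point is noise, so the whole run is kept and the
  nearest-to-previous rule makes the smallest move consistent with the tag
  temperature.

Longitude is never altered. A day that needs support but has no tag sample,
no covering grid, or no candidate is marked invalid and dropped — this is
what the "percent valid locations" statistic counts. Single-day matching
(rather than a windowed correlation) is an explicit interpretation of the
SST-correlation approach; tolerance, band and scope are config keys.

## Track cleaning

**Speed filter.** "No faster than 13.9 m/s (50 km/h) sustained over 48 h"
is operationalized in the root-mean-square form of the classic sustained-
speed filters: for each retained position, the RMS of implied speeds
(great-circle km × 1000 / elapsed s) to every retained neighbour within
±48 h; the worst offender above the ceiling is removed and speeds are
recomputed, until none remains. A single fast pair therefore does not
condemn a point (`strict_pairwise=True` restores per-pair removal).
Colony-fixed positions are never removed. The filter is idempotent by
construction.

**Smoothing.** Each interior position is replaced by the 1:2:1 weighted
mean of its previous/current/next positions, computed simultaneously from
the pre-smoothing values (order independence). Longitudes are unwrapped
around each 3-day window so antimeridian crossings average correctly.
Not smoothed (but still used as neighbours): colony-fixed positions, track
ends, and positions moving more than 4° of longitude or 6° of latitude to
either neighbour (raw displacement between consecutive positions), flagged
`unsmoothed_jump`. Smoothing is variance-reducing on jump-free tracks and
leaves collinear equal-spaced positions fixed.

## Segmentation and phases

A two-state machine scans forward from a stopover start (birds begin at the
breeding site): in stopover, if ≥ 3 days of the forward window [i, i+4]
move > 100 km/d, travel begins at the first such day; the return transition
is symmetric (< 100 km/d). Truncated windows at the series end apply the
same count. Window anchoring (`forward`/`centered`) and the transition day
(`first_qualifying`/`window_start`) are config keys because neither is
uniquely determined by the verbal rule; the defaults are the most local
reading. Multi-day gaps contribute distance ÷ elapsed days, so sparse
coverage cannot fake travel.

**Burst travel.** A run of 1–2 consecutive stopover days each exceeding the
threshold, flanked by stopover on both sides, is relabelled travel when the
flanking stopover clusters' centroids are more than 2 × threshold km apart
— an automated surrogate for what was a manual judgement ("fast and far,
clearly relocating"); the multiplier is a config key.

**Wintering area and phases.** The wintering area is the 50% occupancy
contour of pooled winter positions per basin (≥ 30 required). Arrival
needs the polygon and the polygon needs post-migration positions, so the
pipeline bootstraps in two passes: pass 1 pools stopover-classified days
south of 0° lying within 500 km of the track terminus ("post-migration"
without an arrival rule — robust to occasional mid-winter state flips, and
excluding en-route stopovers); pass 2 defines departure (first travel day
after the initial breeding stopover), arrival (first stopover day inside
the polygon) and the BREEDING < FALL_MIGRATION < WINTER partition. Tracks
that never enter a polygon are direction-only: basin from the final
longitude (Pacific west of −70°, the South American divide), metrics
absent. Breeding-site residency is anchored by fixing the leading run of
days without usable twilights (polar day at 75.8° N lasts into late
August) to the colony coordinates.

## Space use

Projection: spherical Albers equal-area conic (authored from the standard
formulas; no projection library is a dependency), fitted with standard
parallels at the 1/6 and 5/6 latitude quantiles, or the conventional South
America / Africa presets. Point sets spanning > 160° of longitude are
rejected (split per basin). Forward/inverse agree to ~1 m; projected areas
match the spherical closed form to < 0.5%.

Density: quartic (biweight) kernel `3/(πh²)(1 − r²/h²)²` with compact
support equal to the 200 km search radius — the kernel family implied by
GIS "search radius" semantics — on a 10 km grid padded by one bandwidth,
normalized to unit volume. A Gaussian option uses σ = radius/2.58.

Occupancy contours are highest-density regions: the p% threshold is the
largest `t` whose super-level set reaches p/100 of the volume, so regions
nest exactly across levels. Polygons follow cell boundaries (union of cell
boxes) and are simplified at 10 km; membership tests use the exact cell
mask. Colony-fixed positions are excluded from pooled density estimation by
default (configurable).

## Migration metrics and statistics

Distances are great-circle on a sphere of radius 6371.0 km. Travel distance
sums adjacent-pair distances whose later day is travel-classified within
[departure, arrival); travel speed divides by the travel days so counted;
duration is arrival − departure. Stopover movement is excluded by
definition, and travel + stopover distances telescope exactly to the fall
path length. Welch's t (Welch–Satterthwaite df), one-way ANOVA
(df = (k−1, N−k)) and Tukey HSD (studentized-range distribution, evaluated
numerically) are provided through scipy behind this module's interface.

## The synthetic cohort

The generator emulates the study conditions: colony at (75.8° N, 96.3° W);
departures around 18 August (σ 5 d); great-circle travel legs at
300–420 km/d along basin-specific ocean corridors to a Humboldt-like
(10° S, 85° W) or Benguela-like (25° S, 10° E) centre; 2–4 en-route
stopovers totalling ~46 d (each within 50 km of its site); total fall
durations ~ 60–110 d, centred near ~84 d with along-route distances around
13–14,000 km; then 60 d of winter residency as a mean-reverting roam
(per-axis step σ 40 km, reversion 0.15, steps capped just below the
100 km/d threshold). Stopover days therefore move < 100 km/d and travel
days > 100 km/d *by construction*, making the generator's labels a valid
segmentation oracle. All randomness flows from one seed (spawned
per-bird), so equal seeds give bit-identical cohorts.

Observables: twilights from the solar forward model + independent Gaussian
noise (σ 4 min, ≈ 1° of longitude; polar days yield sentinels — equinox
degradation emerges from the model, it is not injected); tag SST = field at
the true position + noise (σ 0.3 °C, 5% missing); grids = the field on a
0.25° × 1° lat/lon raster per 8-day period + cell noise (σ 0.1 °C). The
default SST field is linear, `T(φ) = 21.6 − 0.31·φ` °C: monotone,
physically ranged (−1.9 °C at the colony to ~35 °C at 45° S), and
informative over the whole corridor; a two-front tanh profile is available.
The resulting position errors (median ~65 km, p90 ~140 km after cleaning)
sit at the optimistic end of published geolocator accuracy.

What the simulator does **not** emulate: along-track SST structure beyond
the meridional gradient (zonal fronts, eddies), autocorrelated sensor
error, wind-drifted or looping flight, shading/weather twilight outliers
beyond Gaussian noise, and non-monotone SST (real southern-hemisphere
water cools toward the pole; monotonicity is required for a well-posed
single-profile inversion). Passing tests therefore demonstrate the
correctness and internal consistency of the chain under a realistic noise
budget — not field performance on any particular real dataset.

## Measured behaviour at the defaults

Quantities the test suite and `scripts/acceptance.py` recompute (problem
sizes chosen to exercise the full chain at cohort scale): zero-noise
round-trip recovery ≤ 0.2°/0.5° (200 positions); equinox-window corrected
latitude RMSE ~0.7–0.8° (flagged days over three 6-bird cohorts); ≥ 99% of
injected 2,000-km spikes removed with ≤ 0.1% collateral (20 tracks, 5%
spike rate); day-state accuracy ~95% with departure/arrival mean absolute
errors ~1.4/~1.7 d (20 birds × 3 seeds; the error is reported as a cohort
mean because departures preceding the polar-day twilight resumption are
censored by physics); KDE volume 1 ± 0.01 with capture fractions within
~2 points of nominal at n = 2000; 10/10 basin assignment with cohort-mean
travel speed within ~7% and distance within ~3% of truth on the scaled-down
(10-bird) rerun.

## Known limitations

- Latitude error is reported but not propagated as uncertainty; there is no
  state-space smoothing (deliberately out of scope — the chain mirrors the
  threshold + SST workflow, not Kalman/HMM geolocation).
- Arrival detection against a hard 50% polygon has a heavy right tail for
  birds wintering at the contour's edge (observed up to ~2 weeks late in
  ~1 bird in 20); this is a property of the definition, not of the
  implementation.
- Single-day SST matching degrades where the field is flat; the wide-run
  guard makes it conservative rather than wrong there.
- The burst-travel rule is an automated interpretation of a manual step;
  its centroid-separation multiplier (2×) is a judgement exposed in config.
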