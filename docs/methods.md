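# Methods

`felimove` analyses combined GPS + tri-axial accelerometer collar data
from small territorial felids and ships a synthetic collar-data
generator so every stage can be validated against known ground truth.
This note records the models, the defaults and why they were chosen,
the numerical decisions, and the limits of what the synthetic tests
demonstrate.

## Synthetic collar data

**Movement.** Behaviour is a two-state (resting/active) Markov chain at
1-min resolution.  Each minute the previous state is kept with
probability `state_persistence` (default 0.995, i.e. mean bout length
about 3.3 h, in line with felid resting/hunting bouts); otherwise the
state is redrawn as active with probability `diel_weights[hour]`.
Because the redraw probability is the target, the diel weight is
exactly the stationary active probability of its clock hour.  The
default weights encode the nocturnal-plus-crepuscular pattern typical
of wildcats: ~0.8 at night, peaks of 0.90/0.92 near dawn (06 h) and
dusk (19 h), ~0.2 at midday.  While active, position follows the exact
Ornstein-Uhlenbeck transition around the territory centre with motion
variance `diffusion_sigma2` (default 20 m²/s) and mean-reversion
`attraction` (default 1e-4 s⁻¹, relaxation time ~2.8 h).  These two
defaults give a stationary positional SD of ~316 m and hence 95%
home-range areas of roughly 1.5–2 km², inside the 0.94–4.43 km² span
reported for collared wildcats in lowland Greece.  While resting the
animal does not move.

**Resting-site fidelity.** Each territory holds `n_rest_sites` (default
8) preferred resting sites drawn from the stationary OU distribution.
A resting bout that begins within `rest_site_snap_m` (300 m) of a site
is spent at that site plus a 5 m physical jitter (the spread of a den
or thicket).  This reproduces the monthly reuse of resting locations
observed in the field (a handful of >20-fix clusters per animal-month);
without it a pure OU walk essentially never re-visits a 30 m square
often enough to form a detectable site.  Set `n_rest_sites=0` for the
pure OU process.

**GPS sampling.** Fixes every `gps_interval` (1800 s → 48 waypoints per
day) with isotropic Gaussian error of SD `gps_error_sd` (20 m); the RMS
radial error is therefore 20·√2 m.  The optional adaptive rule halves
the interval while the latest burst ODBA exceeds 10,000 counts; it is
off by default because the bridge estimator assumes at most 30-min
spacing anyway and the rule only densifies.

**Accelerometry.** One 4-s, 10-Hz, 3-axis burst per 2-min slot (720
daily slots).  Units are dimensionless collar counts with gravity fixed
at 1000 counts.  A burst is a constant within-burst gravity projection
(uniform random orientation) plus iid Gaussian dynamic noise whose
amplitude is calibrated so the burst's ODBA matches a per-burst target
drawn from the state's distribution — N(800, 100) resting, N(4000, 600)
active by default, truncated at zero.  The calibration constant is
3·√(2/π)·√((k−1)/k) for k = 40 samples (mean absolute deviation of
mean-subtracted Gaussian noise, summed over three axes).  Setting a
state mean to zero produces exactly constant bursts for that state.

**Environment.** One covariate row per day: day length from the NOAA
solar equations at the study latitude (40.7° N default), moon phase
from the synodic cycle (0 = new, 1 = full, anchored at the 2000-01-06
18:14 UT new moon; the cycle fraction is available as an alternative
convention), a seasonal temperature sinusoid (≈4 °C in late January,
≈26 °C in late July) with correlated daily min/mean/max, winter-weighted
exponential precipitation and gamma wind — a Mediterranean climate.
`env_effects` (default `{"tmin": 0.05}`) applies a linear multiplier to
the active-state ODBA target per day and is recorded with the table as
recovery ground truth; the default is deliberately weak, matching the
weak environmental effects seen in the field.  For model-recovery
experiments `simulate_daily_activity` generates daily responses with an
exactly linear covariate effect (default 250 counts per SD of minimum
temperature against a 700-count residual SD, a moderate ~0.36 SD
effect chosen so a real driver is detectable at the n = 800 scale of
the recovery experiments) plus a 300-count per-animal intercept SD.

**Land cover.** 10-m rasters of tree-cover density (%) and a small
woody feature flag, written as plain-text ESRI ASCII grids: `uniform`,
`half` (half-plane) and `patches` (seeded woodland blobs in an open
agricultural matrix plus hedgerow SWF lines).

## ODBA and aggregation

ODBA of a burst is the sum over axes of the mean absolute dynamic
acceleration, where the static component is the whole-burst per-axis
mean (a 4-s window) by default; a shorter running-mean window is
available (`static_window`).  Using the *mean* absolute deviation
rather than the sum keeps values comparable across burst lengths.  With
the whole-burst window ODBA is exactly translation-invariant per axis
and scales linearly with dynamic amplitude.

Hourly values average all 2-min values of a clock hour (burst-weighted;
with complete bursts this equals minute weighting).  Daily (24 h)
activity is the mean of the date's 24 hourly values, so on complete
days it equals the mean of hourly means.  Nighttime activity uses the
fixed local-clock window 18:30–06:30 binned into 13 equal-weight bins
(the 18:30–19:00 and 06:00–06:30 half-hours plus the 11 full hours
between), attributed to the date the night starts.  Days with fewer
than half the expected bins are dropped, since partial collar days bias
diel-weighted means.  The fixed night window intentionally differs from
the sun-based darkness covariate below; both are part of the protocol.
Hours without data are reported absent (NaN), never zero.

All timestamps are naive local civil time; solar computations take the
longitude and a UTC offset (defaults 23.3° E, UTC+2).

## Home range

**Bridge model.** Between successive fixes the path is a conditioned
Brownian motion: at relative time a = t/T the position is Gaussian
around the linear interpolation of the endpoints with per-coordinate
variance T·a(1−a)·σ²ₘ + (1−a)²δ² + a²δ², with δ the location-error SD
(20 m default).  Tracks drop fixes within 24 h of release and break at
gaps longer than 120 min.

**Motion variance.** σ²ₘ is estimated by the leave-one-out likelihood:
each interior fix of a consecutive triple is scored under its
neighbours' bridge, and the product likelihood is maximised by bounded
1-D search (boundary solutions raise a warning).  By default the
scoring variance also includes the interior fix's own δ², because the
scored quantity is the *observed* fix; omitting it (the classic form,
available via `include_target_error=False`) biases σ̂²ₘ upward by about
δ²/(T·a(1−a)) — ~0.9 m²/s at 30-min spacing with 20 m error, which
would dominate small motion variances.  A power note: with 30-min
fixes and δ = 20 m the bridge-variance signal is T·a(1−a)·σ²ₘ ≈ 450·σ²ₘ
against ~600 m² of error variance, so relative recovery precision is
only attainable for σ²ₘ of order 1 m²/s and above; recovery tests use
σ²ₘ = 1 (CV bound ≈ 6%).

**Utilization distribution.** Each segment contributes Gaussian
densities at midpoint times spaced `time_step` (900 s, the protocol's
15-min step, interpreted as the bridge time-discretisation of the UD
integral) divided by an optional `sub_steps` refinement; contributions
are weighted by segment duration (the BBMM time integral), integrated
over 50-m cells by exact per-axis normal CDF differences, and
normalised to total mass 1.  The grid is the fix bounding box padded by
3 maximum bridge SDs (≥ 99.9% of bridge mass); exceeding a configurable
cell cap raises an error advising coarser cells.

**Contour and MCP.**  The 95% home range is the smallest set of cells
holding 95% of UD mass: cells ranked by density with a stable row-major
tie-break, shortest prefix reaching the level — deterministic under
ties (so a uniform UD over 100 cells yields exactly 95 cells).  The 95%
MCP removes the floor of 5% of fixes farthest from the arithmetic
centroid (the common default of home-range software) and takes the
planar convex hull area; collinear degenerate hulls return zero with a
warning.  Seasonal estimates split fixes by calendar trimester
(Oct–Dec, Jan–Mar, Apr–Jun; Jul–Sep labelled "other").

## Activity analysis

Each 2-min ODBA value is assigned to its temporally nearest fix, ties
to the earlier fix, and kept if within ±15 min (boundaries inclusive);
fixes retaining fewer than 13 of the at-most-15 values are excluded.  A
location is resting iff mean + 2·SD < 2000 **and** max < 2000 (strict,
raw counts; SD uses ddof = 1).  Resting sites are found per
animal-month by a greedy scan: repeatedly take the 30×30 m square
covering the most unassigned resting fixes, accept while the count
exceeds 20.  The default scan anchors candidate squares on a 5-m
lattice (sliding-window histogram); an exhaustive point-anchored scan
(exact, since some optimal square touches a point on its left and
bottom edges) serves as the test oracle.  Sites of one animal whose
centres fall within 30 m across months share an identity for
site-fidelity counts.

Percent forest cover is the share of 10-m cells whose centres lie
within 100 m and that have TCD > 20% or the SWF flag.  Darkness is 1
from 30 min after sunset up to (exclusive) 30 min before sunrise.

## Mixed models and selection

Linear mixed models (identity link, Gaussian errors) with a per-animal
random intercept, fit by maximum likelihood through statsmodels'
`MixedLM` (L-BFGS with Powell/Nelder-Mead fallbacks when the boundary
produces a non-finite likelihood).  The protocol names a "nested"
random effect without stating the nesting; a single per-animal
intercept is used.  Predictors not already on a 0–1 scale are z-scored.
AIC = 2k − 2 logLik with k = fixed effects (intercept included) +
random-intercept variance + residual variance.  Selection: univariate
AIC screen against the intercept-only model; among informative
variables correlated at |r| > 0.7 (a common ecological convention,
configurable) only the lower-AIC member survives; all subsets of
survivors are fit; the ΔAIC < 2 set is retained with Akaike weights
renormalised within it; coefficients are full (zero-substituted)
model averages with the Burnham–Anderson unconditional SE.  P-values
use a normal approximation to the t statistic rather than Satterthwaite
degrees of freedom — at the sample sizes involved (hundreds of
animal-days) the difference is negligible and the validation surface is
simulation-based recovery, not df replication.  Significance threshold
0.001; goodness of fit is the squared correlation between fitted values
(including random effects) and observations.  The location-activity
model regresses non-resting mean location ODBA on z-scored forest
cover, its square, darkness and the cover×darkness interaction;
zero-variance columns (e.g. darkness in an all-daylight subset) are
dropped and flagged inestimable.

## Numerical and degenerate-input decisions

- Bridge SDs are floored at 1e-6 m so σ²ₘ = 0 with tiny δ remains
  integrable (the mass then concentrates on the straight chord).
- A constant response returns a degenerate model (zero slopes, zero
  variance, singular flag) instead of failing.
- MCP accepts three points (the smallest polygon); the contour level
  must lie in (0, 1].
- Written burst samples are rounded to integer counts (collar raw
  units); the induced ODBA round-trip error is below one count.
- All random streams derive from a single seed via independent
  `(seed, animal, stage)` keys, so identical seed + config give
  byte-identical outputs.

## What the synthetic tests do and do not show

The generator produces pure Gaussian location error, stationary
territories, a two-state behaviour process and ODBA distributions that
match the resting/active calibration by construction.  Passing tests
therefore demonstrate the *estimators* (bridge quadrature, variance
likelihood, contouring, peeling, linking, screening/averaging) are
implemented correctly and recover known truth under the stated
conditions; they do not certify performance on real collars with
autocorrelated multipath error, drifting territories, or behaviours
between rest and travel.  In particular, the ≥99% resting-classifier
recovery holds for windows in a single behavioural state (the stated
mixture); windows straddling a state switch are counted non-resting by
the printed rule, so majority-state accuracy on switching tracks is
intrinsically lower.  Test problem sizes (one-to-four animals,
one-week to 200-day windows, 25–200 replicates) were chosen as the
smallest scales at which the Monte-Carlo error of each check is well
below its tolerance.
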