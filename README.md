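# felimove

Biologging analysis for small felids wearing combined GPS +
tri-axial-accelerometer collars — written for movement ecologists who
want the full chain from raw collar dialects to home ranges, diel
activity profiles and environmental models, plus a synthetic collar
simulator with known ground truth to validate every step.

The package follows the field protocol used for European wildcats
(*Felis silvestris*) collared in a lowland wetland-agricultural mosaic:
GPS fixes every 30 min (48 waypoints/day, ~20 m error SD) and 4-s
accelerometer bursts at 10 Hz every 2 min (720 daily logs).

## What it computes

- **ODBA** (overall dynamic body acceleration) per 2-min burst:
  ODBA = Σ_axes mean|a − ā|, with the static component ā the
  whole-burst per-axis mean.  Aggregates: hourly means, 24-h daily
  means, nighttime (18:30–06:30) means, and hour-of-day diel profiles.
- **Home ranges** from the Brownian bridge movement model: between
  fixes z₀, z₁ spaced T seconds the position at relative time a is
  N(z₀ + a(z₁−z₀), T·a(1−a)·σ²ₘ + (1−a)²δ² + a²δ²) per coordinate;
  σ²ₘ is fit by the leave-one-out triple likelihood, the utilization
  distribution is integrated on a 50-m grid, and the home range is the
  95% density contour.  95% minimum convex polygons (centroid peeling)
  are computed for comparison with older studies.
- **Resting behaviour**: each fix gets the 13–15 ODBA values within
  ±15 min; it is resting iff mean + 2·SD < 2000 and max < 2000 (raw
  collar counts).  Resting sites are 30×30 m squares with >20 resting
  fixes per animal-month, matched across months for site fidelity.
- **Environmental drivers**: linear mixed models (per-animal random
  intercept, ML) of daily/nightly activity on temperature,
  precipitation, wind, day length and moon phase, with univariate AIC
  screening, a |r| > 0.7 correlation filter, all-subsets search,
  ΔAIC < 2 retention and Akaike-weight model averaging; plus a
  habitat model of non-resting location activity on forest cover and
  darkness.
- **Synthetic campaigns**: state-switching Ornstein–Uhlenbeck movement
  with diel modulation, resting-site fidelity, calibrated raw-unit
  accelerometer bursts, NOAA solar / synodic lunar covariates, and
  plain-text land-cover rasters — all reproducible from one seed.

## Worked example

Run the default synthetic campaign (two animals, 60 autumn days at
40.7° N) end to end:

```python
import felimove as fm

summary = fm.run_pipeline(fm.PipelineConfig(), "demo_out")
print(summary.home_ranges.round(2))
print(summary.site_counts)
```

which prints (seed 0 defaults):

```
   animal  period estimator  area_km2
wildcat01   total        BB      1.62
wildcat01   total       MCP      1.64
wildcat01 oct_dec        BB      1.62
wildcat01 oct_dec       MCP      1.64
wildcat02   total        BB      1.74
wildcat02   total       MCP      1.82
wildcat02 oct_dec        BB      1.74
wildcat02 oct_dec       MCP      1.82

   animal  unique_sites  2020-10  2020-11  2020-12
wildcat01             4        2        2        1
wildcat02             2        1        3        0
```

The 95% Brownian bridge areas (1.6–1.7 km²) sit inside the 0.94–4.43
km² range reported for wildcats in this landscape, the MCPs are
slightly larger as expected of a hull-based estimator, and each animal
reuses a handful of resting sites per month.  `demo_out/` also receives
the Movebank-style fix CSV, the 2-min ODBA series, diel profiles, daily
activity, fitted model coefficient tables and the land-cover grids.
The same stages are scriptable from the shell:

```
felimove simulate --out data --seed 1
felimove homerange --fixes data/fixes.csv --cell 50 --time-step 900 \
    --max-lag 7200 --loc-error 20 --level 0.95 --out hr
felimove activity --fixes data/fixes.csv --odba data/odba.csv \
    --covars data/covariates.csv --raster data/landcover --out act
felimove run --out full_run --seed 1
```

## Layout

```
src/felimove/
  simulate.py     synthetic collar campaigns (movement, bursts, environment)
  solar.py        NOAA solar equations, synodic moon phase
  odba.py         ODBA and hourly/daily/diel aggregation
  homerange.py    bridge segments, motion variance, UD, contours, MCP
  activity.py     ODBA-fix linking, resting rule, sites, cover, darkness
  mixedmodels.py  mixed models, AIC selection, model averaging
  io.py           Movebank-style CSV, burst dialect, ASCII grids, GeoJSON
  reference.py    published campaign summary tables
  pipeline.py     orchestration + descriptive statistics
  cli.py          the `felimove` command
```
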