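# Methods

## The comparison problem

Expert tolerance tables state climatic limits as extremes: the annual
precipitation exceeded in 80 % of years at the driest station of a species'
range ("minimum precipitation"), the mean annual precipitation at the
wettest station ("maximum precipitation"), and the record minimum
temperature.  Gridded climatologies are multi-decadal averages.  Comparing
the two data sources therefore requires (i) mapping average climate onto
the extreme scale, (ii) estimating empirical limits from occurrence records
robustly, and (iii) a signed statistic whose sign says which source implies
the broader niche.  The package implements that workflow end to end and
validates it on synthetic data with known ground truth.

## Climate corrections

A linear gain/offset model `extreme = a·average + b` is fitted by ordinary
least squares, separately per variable, on calibration pairs:

* **minimum precipitation** — per location, the average of its annual
  precipitation totals versus the 20th percentile of the same series
  (linear-interpolation quantile).  Locations with fewer than 5 years are
  dropped.
* **minimum temperature** — per station, the mean of all daily January
  minima versus their global minimum.  Stations with fewer than 5 daily
  values are dropped.
* **maximum precipitation** — an explicit identity model: the expert value
  is itself a station mean, so no transformation is applied.

Unweighted OLS is the minimal reading of "linear gain and offset"; the fit
R² is reported.  Corrected minimum temperature is capped *after* the linear
map at −60 °C (approximately the coldest temperature measured in the USA):
the cap bounds correction overshoot, is idempotent, and only ever raises
values.  Corrected precipitation is floored at 0 mm — a physical
constraint — with the number of floored cells logged.  The precipitation
model is calibrated on per-location series and the temperature model on
stations, then both are applied grid-wide, mirroring the asymmetric data
sources the schemas come from.  For real-data use,
`sample_calibration_points` draws uniform random points over valid grid
cells (default n = 50 000).

## Niche estimation

Records are clipped to a region mask supplied as data (a grid's valid
cells or a GeoJSON polygon — never hard-coded geometry, so synthetic worlds
work identically), exact duplicate rows are removed as presumed database
duplicates, and species with five or fewer surviving records are excluded
(re-checked after records on NoData cells are dropped).  Climate is
extracted by nearest cell with a half-open convention (a point on a shared
edge belongs to the cell to its east/south); no interpolation, since each
record should carry the value of the cell containing it.

Limits come in two flavours.  The *trimmed* limit removes the most extreme
5 % of values in the direction of the limit — the 5th percentile for
minimum precipitation and minimum temperature, the 95th for maximum
precipitation — which is the only reading under which trimming makes the
limit *more* robust to outliers; the alternative (the 95th percentile for
every variable) is available via `trim_direction="upper"`.  The *absolute*
flavour is the raw min/max.  Quantiles interpolate linearly between order
statistics.  Limits are computed per record, not per unique cell: repeated
collections in one cell all count.

Range size is the area of the convex hull of the records (computed after
filtering), evaluated on a sphere of radius 6371.0088 km by fanning the
hull into spherical triangles and summing their L'Huilier excesses — exact
for convex polygons, and spherical rather than ellipsoidal area is
adequate at hull scale.  Fewer than 3 distinct or collinear points give
area exactly 0.  If the longitudinal spread of a species exceeds 180°, the
points are recentred modulo 360 first so dateline-spanning ranges do not
wrap the globe.

## The ΔCN statistic and the comparison battery

ΔCN is the like-for-like difference of limits, oriented so positive values
mean the occurrence data imply the broader niche: `expert − occurrence`
for the two lower-tail variables, `occurrence − expert` for maximum
precipitation.  This is the one orientation consistent with the published
worked example (expert 2337 mm vs empirical 1255 mm maximum precipitation
→ ΔCN = −1082).  Percent-broader summaries use strict ΔCN > 0; ties count
as not broader.

* **Mann–Whitney–Wilcoxon** (unpaired, two-sided) compares the expert and
  occurrence limit distributions per variable.  The statistic is the U of
  the first sample from midrank sums.  The exact null distribution is used
  when min(n, m) ≤ 8 and the pooled sample is tie-free; otherwise the
  tie-corrected normal approximation *without* continuity correction, so
  the two-group Kruskal–Wallis identity χ² = z² holds exactly.  The data
  are species-paired, but the unpaired test matches the magnitude of the
  published statistics; a paired signed-rank variant is provided.
* **Range-size regression**: OLS of ΔCN on untransformed hull area (log
  area optional), slope t-test with df = n − 2.
* **Growth forms**: Kruskal–Wallis (midranks, tie correction, df = k − 1)
  per variable and on range size (one observation per species), with
  Nemenyi all-pairs post-hoc tests.  The default Nemenyi variant compares
  the standardized mean-rank difference to the studentized-range
  distribution with infinite df (the Tukey form); a tie-corrected
  chi-square form is the option.  Vines are excluded by default — 3 % of
  species is too few for group comparisons.  No multiple-testing
  correction is applied across the three variables.

## The synthetic study

The generator encodes the study conditions.  Growth-form shares default to
28 % forb, 27 % tree, 23 % grass, 19 % shrub, 3 % vine; records per species
are log-uniform on [6, 2000]; expert narrowing δ is drawn uniformly on
[0.05, 0.25] per species and variable (experts compress limits toward
typical conditions).  Climate fields are a latitudinal minimum-temperature
gradient (+10 °C south to −30 °C north) and a longitudinal annual
precipitation gradient (3000 mm west to 400 mm east), each with
low-frequency cosine-mode noise, a smooth ~5 % NoData "ocean", and all
values quantized to 0.1 units to mimic gridded products.  Monthly stacks
are generated first and the annual/coldest layers *derived* from them, so
internal consistency is exact.

Species niches are rectangles in (annual precipitation, coldest-month
minimum temperature).  Relative widths follow growth form (grass 0.55 ≥
forb 0.50 > shrub 0.40 > tree 0.33 of the realized range, vine 0.36,
±15 % jitter) so the observed range-size ordering is recoverable; a flag
disables the coupling for null tests.  Bounds are snapped to the extrema
actually attained on the in-niche cell set, making true limits exactly
recoverable in the dense-sampling limit.  Occurrences are drawn uniformly
over in-niche cells (uniform within the cell), the simplest model under
which the empirical extreme converges to the true limit; a configurable
fraction of species can instead be sampled only from the warm half of its
niche to emulate non-equilibrium distributions (off by default).

True average→extreme relations are gain 0.70 / offset −20 mm (noise sd
30 mm) for precipitation and gain 1.30 / offset −12 °C (noise sd 1.5 °C)
for temperature — chosen so that corrected values stay away from the 0 mm
floor and the −60 °C cap under the default fields.  Calibration series are
constructed by affine rescaling: each location's year series is a
right-skewed template (dry years clustered, long wet tail) rescaled so its
mean equals the gridded average *exactly* and its 20th percentile equals
`a·avg + b + ε` *exactly* (both statistics are affine-equivariant);
station daily series likewise pin the mean and the record minimum.  With
ε ≡ 0 the fitted correction therefore recovers (a, b) to numerical
precision.  Defaults: 500 precipitation locations × 33 years, 80 stations
× 51 Januaries; expert limits on the comparison scale are
`true_limit ± δ·width`, so E[ΔCN] = δ·width per variable.

What the generator does *not* emulate: spatially autocorrelated collection
effort, taxonomic noise in species names, coordinate error beyond cell
quantization, abundance structure within the niche, and non-rectangular
(correlated) niches.  Passing tests therefore show the *pipeline* is
correct and calibrated, not that real occurrence data satisfy its sampling
assumptions.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation between order statistics throughout
  (recorded in the limits API so alternatives are switchable).
* Convergence tolerances: the temperature lattice makes one quantization
  step (0.1 °C) the natural recovery tolerance; annual precipitation is a
  sum of 12 quantized monthly layers, so attained cell values near a niche
  edge are spaced several mm apart and recovery tests bound the gap by the
  order-statistic spacing of attained values instead.
* Identity-scenario checks (δ ≡ 0) use noise-free calibration series:
  calibration noise alone shifts all corrected values by more than the
  quantization step, and noisy-calibration recovery is tested separately
  at the calibration stage.
* Degenerate guards: all-identical calibration averages, empty value
  vectors, zero-variance range size and hulls of < 3 distinct points are
  rejected or defined (area 0) explicitly; a species whose niche matches
  no cell yields zero records with a warning.
* Determinism: every random draw flows from the scenario seed through
  named substreams (fields, niches, occurrences, expert, series), so
  bundles are byte-identical for a fixed seed and independent of call
  order.

## Problem sizes

The validation suite uses 200-species scenarios with 4000 records per
species for dense recovery, 100-replicate calibration-recovery runs at
50 000 points, 500-replicate null-distribution checks, and 2000-replicate
regression type-I runs; the acceptance script uses a 200-species
default-conditions study plus a 100-species dense-recovery scenario.
These sizes give Monte-Carlo standard errors well below the effects being
measured while keeping a full run in seconds on one CPU.

## Known limitations

* Only geographic (unprojected) coordinates; no reprojection.
* Grid dialects are ESRI ASCII and CSV triplets; single-band, square cells.
* The hull is computed in longitude/latitude with dateline recentring;
  ranges spanning more than 180° of longitude after recentring (circum-
  polar distributions) are not handled.
* The correction is a single global linear map; no spatially varying or
  nonlinear corrections, no downscaling.
* Taxonomic reconciliation is an exact-match join plus an optional
  user-supplied synonym map.
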