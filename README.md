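# nichecompare

Compare **expert-based climatic tolerance estimates** with **climatic niches
derived from species occurrence records**.

Expert tables such as the USDA PLANTS "characteristics" data state, per
plant species, a minimum precipitation tolerance (the 20th-percentile
annual precipitation at the driest station in the range), a maximum
precipitation tolerance (mean annual precipitation at the wettest station)
and an absolute record minimum temperature.  Occurrence archives (GBIF-style
`species,lon,lat` tables) plus gridded climatologies (WorldClim-style
layers) give an independent, empirical view of the same limits.  The two
are not directly comparable — the expert limits are climatic *extremes*
while gridded climatologies are multi-decadal *averages* — so the package:

1. fits linear **gain/offset corrections** `extreme = a·average + b` on
   calibration time series (per-location annual precipitation years; station
   daily January minima), capping corrected minimum temperature at −60 °C
   and leaving maximum precipitation untransformed (both sides are means);
2. filters occurrence records (region clip, duplicate removal, species with
   five or fewer records excluded), extracts corrected climate at each
   record by nearest grid cell, and computes per-species niche limits in
   two flavours — **percentile-trimmed** (trimming the most extreme 5 % of
   values in the direction of the limit, robust to bad coordinates) and
   **absolute** (true min/max) — plus **range size** as the spherical area
   (km², R = 6371.0088 km) of the convex hull of the records;
3. computes the signed comparative niche statistic, per species and
   variable,

   ```
   ΔCN(min precip) = expert_min − occurrence_min
   ΔCN(min temp)   = expert_min − occurrence_min
   ΔCN(max precip) = occurrence_max − expert_max
   ```

   so that **positive ΔCN means the occurrence data imply a broader
   niche**, and runs the comparison battery: Mann–Whitney–Wilcoxon tests of
   the two limit distributions, OLS regression of ΔCN on range size, and
   Kruskal–Wallis with Nemenyi post-hoc pairwise tests across growth forms
   (vines excluded by default).

Because real GBIF/WorldClim/PRISM downloads are out of scope, the package
ships a first-class **synthetic-study generator**: gridded climate fields,
virtual species with known true niches, an expert table narrowed inward by
a known fraction δ of the niche width, occurrence samples drawn from inside
the true niche, and calibration series built to follow known linear
average→extreme relations.  Every downstream estimate therefore has an
analytic expectation (e.g. E[ΔCN] = δ·width), which is how the pipeline is
validated.

Audience: biogeographers and ecoinformaticians evaluating climatic
tolerance data sources, and anyone needing a tested reference
implementation of percentile-trimmed niche limits, hull range size, or the
ΔCN workflow.

## Worked example

```
nichecompare simulate --seed 42 --n-species 60 --out demo/inputs
nichecompare run --scenario demo/inputs --out demo/results --flavor both
nichecompare report --out demo/results
```

The report prints (excerpt):

```
## Fitted corrections
- min_precip: extreme = 0.6995 x average -18.95 (r2 = 0.9970, n = 500)
- min_temp: extreme = 1.2884 x average -12.03 (r2 = 0.9910, n = 80, cap -60.0 C)

## dCN summary (absolute limits)
- max_precip: mean 172.1, median 165.6, 95.0% of species broader (n=60)
- min_precip: mean 136.6, median 134.8, 96.7% of species broader (n=60)
- min_temp: mean 3.5, median 3.4, 96.7% of species broader (n=60)

- Kruskal-Wallis by growth form, max_precip: chi2 = 13.5, df = 3, p = 0.00373
```

Reading it: the fitted corrections recover the scenario's true linear
relations (gain 0.70 / 1.30); with the expert table narrowed inward by a
random δ ∈ [0.05, 0.25] of each niche width, nearly all species show
positive ΔCN (occurrence-derived niches broader), the effect is larger for
absolute than for trimmed limits, and ΔCN differs across growth forms —
the qualitative pattern the method is designed to detect.  The same
commands with real-data files in the documented schemas run unchanged.

The library surface mirrors the stages: `grids` (I/O, derived layers,
point extraction), `correction` (series summaries, OLS fit, capped
application), `niche` (filtering, limits, range size), `compare` (ΔCN and
statistics), `synth` (scenario generator), `pipeline` (orchestration).

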