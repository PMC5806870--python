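# sedscape

Watershed soil-loss and sediment-export modelling: USLE erosion routed
downslope with per-cell vegetative trapping, rating-curve processing of
outlet gauge records, ensemble calibration under parameter uncertainty, and
gradual land-use restoration scenarios — plus a synthetic-watershed
generator so the whole pipeline runs and tests offline.

## What it does

- **terrain** — depression filling (priority flood), D8 steepest-descent
  flow routing, flow accumulation and stream extraction, Horn percent
  slope, the Desmet–Govers LS factor with McCool steepness, and Euclidean
  distance to streams.
- **erosivity** — rainfall erosivity (R factor) from multi-gauge daily
  precipitation: monthly climatology → Cressman interpolation → per-cell
  `R = 68.730 · Σ (p_t²/P)^0.841`.
- **gauging** — stage→discharge and piecewise discharge→turbidity rating
  curves (packaged default plus least-squares fitting),
  turbidity→suspended-sediment, and observed sediment export
  `SE = 31.536·Q·SS/DA` aggregated over Oct–Sep hydrological years.
- **erosion_model** — per-pixel USLE soil loss `A = R·K·LS·C·P` routed
  along flowpaths; each strictly-downstream hillslope cell traps its
  retention-efficiency share, streams absorb, and exported + retained mass
  equals eroded mass to machine precision.
- **buffer_theory** — the whole-buffer trapping efficiency
  `Te = 1 − (1 − SRE)^(l/r)`, its exact inverse, and band fitting against
  literature width–trapping points.
- **calibration** — the 24-member ensemble (3 K options × 2 forest
  retention options × 2 initial C × 2 C-linkage directions), two-stage
  deterministic search of pasture retention efficiency and pasture C to a
  10% export tolerance, with member dismissal.
- **scenarios** — anthropized baseline and gradual riparian /
  steepest-slope / 2-way restoration series hitting prescribed forest
  fractions, compared as percent reductions over the calibrated ensemble.
- **synthetic** — seeded watershed bundles (DEM, soils, land use, five
  rain gauges, twice-daily outlet series) whose known "truth" parameters
  close exactly through both the routing model and the gauging equations.
- **workflow** — YAML-configured end-to-end driver producing calibration
  tables, strategy curves, reduction tables and a summary JSON.

## CLI

A single umbrella command:

```sh
sedscape synth --seed 42 --size mini --out bundle/       # synthetic bundle
sedscape terrain --dem bundle/dem.asc --threshold 60 --out terr/
sedscape erosivity --gauges bundle/rain_gauges.csv --dem bundle/dem.asc \
    --start 2010-10-01 --end 2015-09-30 --out r.asc
sedscape gauging --series series.csv --area-ha 1200
sedscape buffer --sre 0.65 --width 20 --pixel 5
sedscape calibrate --seed 42 --size mini --out calibration.csv
sedscape run --seed 42 --out runs/demo                   # full experiment
```

Rasters are ESRI ASCII grids (`.asc`); tables are CSV; summaries are JSON.
Sizes: `mini` (64×64, fast) and `full` (1200 ha at 5 m resolution).

## Reproducibility

All randomness flows through explicitly seeded `numpy` generators: the same
seed gives byte-identical bundles, calibrations, and pipeline summaries.
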