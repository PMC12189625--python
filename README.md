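# nichecast

Presence-background niche modelling with climate-scenario projection and
range-change analytics on regular lon/lat grids.

The package implements a complete, reproducible pipeline:

1. **synthetic_data** — seeded generation of spatially autocorrelated
   environmental layers (9 variables: temperature/salinity mean and
   long-term extremes, current velocity, primary productivity, nitrate),
   scenario offsets (SSP1-1.9 / SSP2-4.5 / SSP5-8.5 × 2030s / 2060s /
   2090s), bathymetry with 20 m / 5 m depth masking, presence records drawn
   from a known truth surface, and polygonal marine-protected-area (MPA)
   masks. Every generator has known ground truth so all downstream stages
   are testable without external data.
2. **data_io** — occurrence CSV loading with past (< 2000) / present
   (≥ 2000) era labels, one-record-per-0.05°-cell deduplication, layer
   stacks with a shared validity mask, CSV-grid raster round-trips, and
   GeoJSON MPA rasterization by cell-center containment.
3. **maxent_core** — a from-scratch presence-background maximum-entropy
   model: linear/quadratic/hinge features scaled to [0,1] on the
   background, an L1-penalized convex objective fitted by a monotone
   accelerated proximal-gradient solver, raw/logistic/cloglog outputs,
   permutation-based percent contributions, and response curves.
4. **model_selection** — iterative variable screening (mean contribution
   < 5 % or pairwise |r| > 0.7 excluded), a beta-multiplier sweep
   (1.0–10.0 by 0.5, mean test AUC argmax), and a VIF < 5 gate.
5. **evaluation** — replicate 70/30 presence splits, Mann–Whitney AUC,
   max-threshold TSS, and mean ± sd aggregation.
6. **projection** — replicate-mean habitat-suitability fields, 0.2° block
   averaging, the five-level suitability classification, and the ≥ 0.4
   binary suitability rule.
7. **change_analysis** — Absence/Constriction/Expansion/Stability change
   categories, cosine-weighted suitable areas (10³ km²) with per-latitude
   bands, percent trends, HSI-weighted latitudinal centroids, multi-species
   richness, and MPA overlap classes with protected fractions.
8. **cli** — YAML-configured orchestration of
   simulate → select → fit → project → change → report.

## Test

```sh
python -m pytest -q tests/
```

The suite includes per-module unit tests, hypothesis property tests, and
`tests/test_acceptance.py` with one test (class) per acceptance criterion,
including a stochastic 10-seed parameter-recovery check (~1 min).

## CLI

```sh
nichecast run-all --seed 1 --outdir runs/demo
nichecast simulate --config config.yaml --outdir runs/sim
```

A YAML config may override any `RunConfig` field (seeds, thresholds, beta
grid, grid geometry, species list, `output_transform: logistic|cloglog`…).
Runs are deterministic given config + seed; summary CSVs are byte-identical
across reruns. Exit codes: 0 success, 2 configuration error, 3 data error,
4 convergence error.

Outputs per run directory: `env_present.csv` (layer stack), per-species
occurrence CSVs, `selection.csv` (variable, contribution, VIF, status),
`evaluation.csv` (per-replicate AUC/TSS plus a `mean±sd` row),
`change_summary.csv` (species × scenario × period areas and trends),
`mpa_overlap.csv`, per-species model JSON, and `run_record.json` with the
package version, config hash and all seeds.

## File formats

Everything is plain text: rasters as long-format CSV with an embedded
`# grid: {...}` header (one row per valid cell), occurrences as
`species,lon,lat,year` CSV, MPA masks as GeoJSON polygons or 0/1 CSV grids,
models as versioned JSON documents.
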