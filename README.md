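# firescape

A tested, reusable pipeline for mapping war-related forest damage on
synthetic landscapes: temporal segmentation of annual NBR trajectories into
dated loss segments, per-patch disturbance-agent attribution (stand-replacing
fire / harvest / non-stand-replacing), elevated-fire-hazard analysis by
land-cover adjacency, design-based stratified area estimation with combined
uncertainty, and fire-weather anomaly detection — all exercised end-to-end on
seeded synthetic scenarios so nothing needs to be downloaded.

## Modules

| module | what it does |
| --- | --- |
| `firescape.synthetic_scenario` | seeded nine-class land-cover mosaics, disturbance events with agent-specific spectral/geometric signatures, annual NBR/NDVI/tasseled-cap stacks, daily fire-weather series with injectable anomaly years, reference samples |
| `firescape.raster_core` | `Grid` raster primitive, patch labeling, fractal shape index, Euclidean distance transform, majority resampling, single-pixel noise filter, 3-km² hexagonal aggregation, ASCII-grid/TIFF I/O |
| `firescape.spectral_composites` | NBR/NDVI/tasseled-cap, leaf-on median composites, before/after delta stacks, seeded random-forest damage classifier with accuracy report |
| `firescape.disturbance_segmentation` | piecewise-linear segmentation of NBR series (dynamic-program vertex search + least-squares refinement), loss segments with the ΔNBR ≥ 0.1 and 1–3 yr rules, primary/secondary ranking |
| `firescape.agent_attribution` | per-patch feature vectors (spectral magnitudes, duration, rate, area, fractal index), stratified-holdout agent classifier, per-agent annual area series |
| `firescape.fire_hazard` | fire-supporting vs fire-inhibiting reclassification, ≥ 1 ha supporting-patch filter, edge-distance computation, elevated-hazard flags and proportions at the 0.09 ha / 1 ha thresholds |
| `firescape.area_uncertainty` | stratified area estimator with standard errors, product-rule combination of forest-mask and damage-model uncertainty, cross-region aggregation (linear by default, quadrature by flag) |
| `firescape.weather_anomaly` | March–September seasonal means of FWI/ISI/DC, z-score anomaly flags (thresholds 3 / 2), OLS regression of burned area on seasonal indices |
| `firescape.cli` | YAML-configured pipeline orchestration with per-stage outputs and a checksummed run manifest |

## CLI

Each stage regenerates the seeded scenario deterministically, so stages can
run standalone. `run-all` executes simulate → classify → segment → attribute
→ hazard → estimate-area → anomaly → report:

```sh
firescape run-all --out runs/demo --seed 7            # built-in demo config
firescape run-all --config my.yaml --out runs/x       # custom scenario
firescape simulate --out runs/sim-only --seed 3       # scenario only
```

Results land under `--out` as CSV / YAML / ASCII-grid files, ending with
`report.yaml` (damaged area ± uncertainty, hazard proportions at both patch
thresholds, per-agent area time series, abnormal years, burned-area
regressions) and `run_manifest.yaml` with per-file checksums. Exit codes:
0 success, 2 configuration error, 3 data error.

A config file has a `scenario` section (grid size, seed, class proportions,
disturbance schedule, noise levels, weather anomaly years) plus optional
`hazard`, `area` and `aggregation` sections; see `DEFAULT_CONFIG` in
`firescape/cli.py` for the full shape.

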