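# vinecwsi

Thermal crop-water-stress mapping for vineyards, in 2D (orthomosaic rasters)
and 3D (attributed point clouds).

The package implements a full desk-side workflow:

- **geodata** — shared spatial data model (`RasterGrid`, `AttributedPointCloud`,
  `RoiPolygon`) with GeoTIFF, delimited-text, LAS 1.2 and PLY I/O.
- **synthetic** — a vineyard scene generator (VSP rows, half-ellipsoid
  canopies with closed-form volumes, inclined terrain, soil warmer than
  canopy, vertical in-canopy temperature gradient, optional missing plants)
  so every stage is testable with known ground truth.
- **canopy2d** — canopy height model (DSM − DTM), binary canopy mask
  (strictly above a 0.5 m threshold by default) and masked thermal extraction.
- **canopy3d** — progressive-TIN ground classification, statistical-outlier
  noise filtering, rule-based understory removal, bottom trimming for
  reference clouds and per-cell top segmentation.
- **cwsi_core** — simplified CWSI: wet/dry references from the 0.5%
  histogram tails, the affine index `(T − T_wet)/(T_dry − T_wet)` (never
  clipped), Kelvin→Celsius conversion and per-dataset summaries.
- **plants** — equal-cell plant grid over the ROI aligned to the row azimuth,
  per-plant mean CWSI and convex-hull canopy volumes.
- **evaluation** — paired OLS regressions between data models, flights and
  reference volumes, keyed by plant id.
- **cli** — the stages as composable subcommands with manifests and
  deterministic, seeded outputs.

## CLI

Run the whole pipeline on a synthetic scene (no external data needed):

```sh
vinecwsi all --outdir out --seed 7
```

or stage by stage (`simulate`, `mask2d`, `classify3d`, `cwsi2d`, `cwsi3d`,
`plants`, `volumes`, `evaluate`). Useful flags: `--threshold-m`,
`--tail-fraction`, `--grid N_ALONG N_ACROSS`, `--row-azimuth`, `--trim-m`,
`--top-depth-m`, `--reference-cloud`, `--config cfg.yaml` (flat key-value;
flag > file > default). Each stage writes its outputs plus a
`manifest_<stage>.json` recording parameters, input hashes and the seed; two
runs with the same seed produce identical text outputs. Exit code 2 signals a
contract error (bad parameters or a missing upstream artifact).

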