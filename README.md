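# coralhsm

Habitat suitability modelling for deep-sea corals on a 500 m analysis grid:
seafloor environmental layer construction from depth-binned climatologies,
presence-record quality control, a from-scratch maximum-entropy
presence-background model, spatially partitioned cross-validation with
thresholded consensus mapping, and overlap accounting against protected-area
polygons, substrate classes and trawl-intensity surfaces.

Everything runs end to end on synthetic seascapes with known ground truth, so
no external data are required.

## Modules

| module | what it does |
| --- | --- |
| `coralhsm.synthetic_seascape` | Shelf–slope–canyon bathymetry with survey-track soundings, depth-binned climatology volumes, presences sampled from a known suitability function (with injected contaminants carrying a hidden answer key), bottle casts, sanctuary polygons, slope-correlated substrate and vessel-tagged trawl lines. Fully deterministic under the configured seed. |
| `coralhsm.bathymetry_terrain` | Sounding cleaning/audit, per-cell-median gridding with nearest-neighbour coarse infill, multi-window Horn slope (exact on planes). |
| `coralhsm.env_layers` | IDW interpolation of each depth bin, nearest-level extrusion to the seafloor (a partition with per-cell bin provenance), bottle-cast validation (post-2001 / bottom-flag / 5 % depth filters, Pearson r²), |r| > 0.7 correlation pruning with a keep-list. |
| `coralhsm.presence_qc` | The four elimination rules (trawl gear, < 50 m, unknown family, spatial duplicates per taxon and cell) applied in order with a per-rule audit; taxon sets with a modelability threshold. |
| `coralhsm.maxent_sdm` | Regularised Gibbs model over a background sample: linear/quadratic/hinge/product features enabled by presence count, L1-regularised fit with KKT moment matching, logistic HSI `e^H q / (1 + e^H q)`, regularised training gain, jack-knife variable importance. |
| `coralhsm.spatial_cv` | Four-region partitioning (quadrants, alongshore bands, or supplied polygons), presence-background AUC (= normalised rank-sum) with significance and bootstrap SD, threshold statistics, AUC > 0.7 retention, 0.5/0.75 binary thresholds and 0..K consensus grids. |
| `coralhsm.overlap_reports` | Zonal areas per suitability class inside polygons (km² and nm²), substrate cross-tabs with majority resampling, 3 km-radius trawl-line density with a < 3-vessel privacy mask, intensity-by-class histograms, presence-niche summaries. |
| `coralhsm.pipeline` | Wires all stages together (`run_pipeline`). |

Rasters are exchanged as ESRI ASCII grids, vectors as GeoJSON, soundings as
XYZ text and tables as CSV.

## CLI

```sh
coralhsm simulate --config cfg.json --out seascape/       # generate inputs
coralhsm terrain --soundings seascape/soundings.xyz \
    --shape 100 100 --windows 1000,5000,10000,20000 --out terrain/
coralhsm layers --climatology clim/ --bathy terrain/bathymetry.asc \
    --validate seascape/bottle_casts.csv --out layers/
coralhsm qc --records seascape/presences.csv --grid terrain/bathymetry.asc --out qc/
coralhsm cv --config cfg.json --out cv/                   # full pipeline + reports
```

`cfg.json` holds `SeascapeConfig` fields, e.g.
`{"seed": 7, "grid_extent": [100, 100], "n_presences": 300}`.

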