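# canopystack

Turn discrete spaceborne-LiDAR footprint metrics into wall-to-wall forest
stock volume (FSV) maps: footprint quality control, variography,
footprint-to-surface interpolation (ordinary kriging, sequential Gaussian
conditional simulation, and exponent-tuned inverse-distance weighting),
multi-source predictor derivation with a VIF + SHAP feature screen, and a
multi-level stacking ensemble with a pass-through baseline. A synthetic-data
module generates spatially autocorrelated fields, track-sampled footprints
and calibration plots so the entire workflow runs offline at desk scale.

## Command line

All stages are exposed under one entry point:

```bash
canopystack run --seed 1 --out runs/demo            # full synthetic workflow
canopystack simulate --seed 1 --out data/           # synthetic inputs only
canopystack variogram --footprints fp.csv --out variograms.json
canopystack interpolate --footprints fp.csv --metric rh98 --method sgcs \
    --n-real 25 --seed 1 --out surfaces/
canopystack select-features --features table.csv --vif-threshold 5 --top-k 6 \
    --out selection.json
canopystack harmonize --plots plots.csv --delta-years 3 --cell-size 30 \
    --out plots_harmonized.csv
canopystack train --features table.csv --mode mlsem --out model/
canopystack map --stack model/ --rasters layers/ --out map/
```

`canopystack run` executes QC → variography → interpolation with the
R² ≥ 0.50 retention gate → predictor assembly (terrain, band reflectances,
11 vegetation indices, 8 co-occurrence textures) → VIF + SHAP screening →
stack training/evaluation → the volume map with areal totals, writing every
stage artifact plus a machine-readable `run_report.json`. Without `--config`
a bundled tiny synthetic configuration is used (completes in about a minute
on one CPU); rasters are read and written as ESRI ASCII grids.

## Layout

- `canopystack.grids` — grid geometry, rasters, ASCII-grid I/O
- `canopystack.synthdata` — Gaussian-field simulation, track sampling, plots, QC
- `canopystack.variogram` — empirical variograms, model fitting, dependence classes
- `canopystack.interpolate` — OK, SGCS, IDW (+ PSO/GA/grid exponent tuning),
  hold-out evaluation and gating, nearest-neighbor harmonization
- `canopystack.predictors` — reflectance scaling, indices, GLCM textures,
  terrain, feature extraction, VIF + SHAP screen (exact tree SHAP in
  `canopystack._treeshap`)
- `canopystack.harmonize` — stand density index, growth projection, areal scaling
- `canopystack.stacking` — learner registry, OOF meta-features, the
  multi-level stack, the pass-through baseline, metrics, map application
- `canopystack.pipeline` — config-driven orchestration and run reports
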