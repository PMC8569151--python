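# rgbphen

Plot-level canopy trait estimation from aerial RGB imagery: estimate peanut
leaf area index (LAI) and lateral growth (LG, cm) from vegetation indices
derived from UAV orthomosaics.

The pipeline goes from per-plot digital numbers (DN) in three co-registered
RGB rasters, through panel-based exponential DN→reflectance calibration and
six RGB vegetation indices, to published frozen prediction equations,
refitting machinery (OLS, AIC stepwise selection, a small deterministic
MLP), evaluation statistics, and trait→yield regression. A synthetic
field-trial scene generator makes every stage testable offline.

## Modules

| Module | Role |
| --- | --- |
| `rgbphen.plot_geometry` | Raster/fishnet I/O, per-plot zonal mean DN, two-row averaging |
| `rgbphen.radiometry` | Exponential calibration `reflectance = a·b^DN`: fit, apply, invert, built-in 2017/2019 sets |
| `rgbphen.vegindices` | BGI, RGR, NPPR, NGRDI, PPR, NCPI from reflectance triples |
| `rgbphen.trait_models` | Frozen models reg1–reg4, OLS refits, stepwise selection, MLP (5-4-3 hidden, lr 0.001, momentum 0.99, 10 000 epochs) |
| `rgbphen.evaluation` | R², RMSE, PRESS, AIC/BIC/ASE, validation μ/σ/R², Pearson r, paired t, ANOVA + Tukey HSD, cubic yield fits |
| `rgbphen.synthetic_data` | RCBD trial tables, model-consistent VI tables, rendered scenes with an 8-shade panel |
| `rgbphen.workflow` / `rgbphen.cli` | Pipeline glue and the `rgbphen` command |

Rasters are plain TIFF/PNG files with ESRI world files (`.tfw`/`.pgw`);
fishnets are GeoJSON FeatureCollections; all tabular artifacts are CSV and
models serialize to JSON.

## CLI

```sh
# simulate a synthetic campaign (rasters + fishnet + ground truth)
rgbphen simulate --preset 2017 --seed 1 --out-dir scratch/sim

# stage by stage
rgbphen extract --scene scratch/sim/scene_red.tif --scene scratch/sim/scene_green.tif \
    --scene scratch/sim/scene_blue.tif --fishnet scratch/sim/fishnet.geojson --out dn.csv
rgbphen calibrate --panel-csv panel.csv --out cal.json
rgbphen indices --reflectance-csv refl.csv --out vis.csv
rgbphen estimate --vi-csv vis.csv --model reg1 --model reg2 --out estimates.csv
rgbphen fit --table-csv table.csv --trait LAI --mode sum --out model.json
rgbphen evaluate --table-csv pairs.csv --out metrics.json
rgbphen validate --train-csv train.csv --validation-csv val.csv --model reg1 --out report.json

# or the whole pipeline from a YAML config
rgbphen run --config config.yaml
```

A `run` config is a YAML mapping with `scene_paths`, `fishnet_path`,
`out_dir`, and optionally `calibration` (a builtin label `2017`/`2019`, a
calibration JSON, or a panel CSV to fit), `model_ids`, `ground_truth_path`,
`bit_depth`, and `seed`.

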