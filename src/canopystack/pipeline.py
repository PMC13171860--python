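"""Config-driven end-to-end orchestration at desk scale.

Runs footprint QC, variography, interpolation with the accuracy gate,
predictor assembly, the two-stage feature screen, stack training and the
wall-to-wall volume map, writing per-stage artifacts and a machine-readable
run report. One global seed fans out to per-stage seeds via a stable hash,
so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import interpolate, predictors, refdata, stacking, synthdata
from .grids import GridSpec, Raster, write_ascii_grid
from .harmonize import harmonize_plots
from .variogram import VariogramModel, empirical_variogram, fit_variogram

__all__ = ["default_config", "load_config", "run", "stage_seed"]

log = logging.getLogger("canopystack")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed and the stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def default_config() -> dict:
    """The bundled 'tiny' configuration: a fully synthetic desk-scale run."""
    return {
        "synthetic": {
            "grid": {"origin_x": 0.0, "origin_y": 0.0, "cell_size": 30.0,
                     "n_rows": 48, "n_cols": 48},
            "metrics": {
                "cover": {"kind": "exponential", "nugget": 0.005, "partial_sill": 0.04,
                          "range_m": 600.0, "mean": 0.6},
                "rh98": {"kind": "exponential", "nugget": 2.0, "partial_sill": 30.0,
                         "range_m": 700.0, "mean": 18.0},
                "fhd_normal": {"kind": "exponential", "nugget": 0.02, "partial_sill": 0.2,
                               "range_m": 500.0, "mean": 2.5},
            },
            "dem": {"kind": "spherical", "nugget": 0.0, "partial_sill": 2000.0,
                    "range_m": 900.0, "mean": 1500.0},
            "bands": {"nugget": 1e-4, "partial_sill": 2e-3, "range_m": 500.0,
                      "means": {"b1": 0.05, "b2": 0.07, "b3": 0.09, "b4": 0.08,
                                "b5": 0.3, "b6": 0.2, "b7": 0.12}},
            "footprints": {"along_m": 60.0, "across_m": 240.0, "noise_sd": 0.0,
                           "qc_fail_fraction": 0.15},
            "plots": {"n": 143, "noise_sd": 8.0},
        },
        "qc": {"sensitivity_min": 0.9, "require_quality": True},
        "interpolation": {
            "methods": ["ok", "sgcs", "idw", "gs-idw"],
            "n_realizations": 10,
            "threshold": 0.5,
            "split_frac": 0.8,
        },
        "selection": {"vif_threshold": 5.0, "top_k": 6},
        "stacking": {"oof_folds": 10, "test_frac": 0.2},
        "harmonization": {"delta_years": 0, "cell_size": 30.0},
        "seed": 0,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _model_from_cfg(cfg: dict) -> VariogramModel:
    return VariogramModel(cfg["kind"], cfg["nugget"], cfg["partial_sill"], cfg["range_m"])


def _generate_synthetic(cfg: dict, seed: int):
    g = cfg["grid"]
    grid = GridSpec(g["origin_x"], g["origin_y"], g["cell_size"],
                    g["n_rows"], g["n_cols"], crs_tag="synthetic")
    fields = {}
    for i, (name, mcfg) in enumerate(cfg["metrics"].items()):
        model = _model_from_cfg(mcfg)
        fields[name] = synthdata.simulate_gaussian_field(
            grid, model, mcfg.get("mean", 0.0), seed=stage_seed(seed, f"field:{name}")
        )
    dem_cfg = cfg["dem"]
    dem = synthdata.simulate_gaussian_field(
        grid, _model_from_cfg(dem_cfg), dem_cfg.get("mean", 0.0),
        seed=stage_seed(seed, "field:dem"),
    )
    bands = {}
    bcfg = cfg["bands"]
    for bid, mean in bcfg["means"].items():
        model = VariogramModel("exponential", bcfg["nugget"], bcfg["partial_sill"],
                               bcfg["range_m"])
        r = synthdata.simulate_gaussian_field(
            grid, model, mean, seed=stage_seed(seed, f"band:{bid}")
        )
        bands[bid] = Raster(grid, np.clip(r.values, 1e-4, 1.0))
    fp_cfg = cfg["footprints"]
    footprints = synthdata.sample_footprints(
        fields, grid,
        along_m=fp_cfg["along_m"], across_m=fp_cfg["across_m"],
        noise_sd=fp_cfg["noise_sd"], qc_fail_fraction=fp_cfg["qc_fail_fraction"],
        seed=stage_seed(seed, "footprints"),
    )
    p_cfg = cfg["plots"]
    height = fields.get("rh98", next(iter(fields.values())))
    cover = fields.get("cover", next(iter(fields.values())))
    plots = synthdata.simulate_plots(
        {"height": height, "cover": cover},
        n=p_cfg["n"], noise_sd=p_cfg["noise_sd"],
        seed=stage_seed(seed, "plots"),
    )
    return grid, fields, dem, bands, footprints, plots


def run(config: dict, out_dir) -> dict:
    """Execute the full workflow; returns the run report (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {"seed": seed, "stages": {}, "config": config}
    t_start = time.time()

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start": time.time() - t_start}
        return report["stages"][name]

    # --- inputs -----------------------------------------------------------
    st = stage("inputs")
    if "synthetic" in config:
        grid, fields, dem, bands, footprints, plots = _generate_synthetic(
            config["synthetic"], seed
        )
    else:
        paths = config["paths"]
        for key in ("footprints", "plots"):
            if not Path(paths[key]).exists():
                raise FileNotFoundError(f"inputs stage: missing {key} file {paths[key]}")
        footprints = pd.read_csv(paths["footprints"])
        plots = pd.read_csv(paths["plots"])
        from .grids import read_ascii_grid

        dem = read_ascii_grid(paths["dem"])
        grid = dem.grid
        bands = {bid: read_ascii_grid(p) for bid, p in paths.get("bands", {}).items()}
        fields = {}
    footprints.to_csv(out / "footprints_raw.csv", index=False)
    plots.to_csv(out / "plots.csv", index=False)
    st["n_footprints"] = len(footprints)
    st["n_plots"] = len(plots)

    # --- QC ---------------------------------------------------------------
    st = stage("qc")
    qc = config.get("qc", {})
    kept = synthdata.filter_footprints(
        footprints,
        sensitivity_min=qc.get("sensitivity_min", 0.9),
        require_quality=qc.get("require_quality", True),
    )
    kept.to_csv(out / "footprints_qc.csv", index=False)
    st["n_retained"] = len(kept)

    metric_names = [
        c for c in kept.columns
        if c not in {"id", "x", "y", "sensitivity", "quality_flag"}
    ]

    # --- variography ------------------------------------------------------
    st = stage("variogram")
    fits = {}
    for m in metric_names:
        ev = empirical_variogram(kept, m)
        best, _ = fit_variogram(ev)
        fits[m] = best
    st["fits"] = {m: rep.to_dict() for m, rep in fits.items()}
    (out / "variograms.json").write_text(json.dumps(st["fits"], indent=2))

    # --- interpolation + gate --------------------------------------------
    st = stage("interpolation")
    icfg = config.get("interpolation", {})
    methods = icfg.get("methods", ["ok", "sgcs"])
    threshold = icfg.get("threshold", 0.5)
    reports = []
    for m in metric_names:
        for method in methods:
            rep = interpolate.evaluate_interpolation(
                kept, m, method,
                model=fits[m].model, grid=grid,
                split_frac=icfg.get("split_frac", 0.8),
                threshold=threshold,
                n_realizations=icfg.get("n_realizations", 10),
                seed=stage_seed(seed, f"interp:{m}:{method}"),
            )
            reports.append(rep.to_dict())
    st["reports"] = reports
    (out / "interpolation_reports.json").write_text(json.dumps(reports, indent=2))

    best_method = icfg.get("surface_method", "sgcs")
    retained_metrics = sorted(
        {r["metric"] for r in reports if r["method"] == best_method and r["retained"]}
    )
    if not retained_metrics:  # fall back to the best-scoring metric surfaces
        by_metric = {}
        for r in reports:
            if r["method"] == best_method:
                by_metric[r["metric"]] = r["r2_test"]
        retained_metrics = sorted(by_metric, key=by_metric.get, reverse=True)[:2]
        st["gate_fallback"] = True
    st["retained_metrics"] = retained_metrics

    # --- surfaces for retained metrics -----------------------------------
    st = stage("surfaces")
    surfaces = {}
    for m in retained_metrics:
        if best_method == "sgcs":
            stack = interpolate.sgcs(
                kept[["x", "y"]].to_numpy(float), kept[m].to_numpy(float),
                grid, fits[m].model,
                n_realizations=icfg.get("n_realizations", 10),
                seed=stage_seed(seed, f"surface:{m}"),
            )
            surfaces[m] = stack.mean_raster()
        else:
            surfaces[m] = interpolate.ordinary_kriging(
                kept[["x", "y"]].to_numpy(float), kept[m].to_numpy(float),
                grid, fits[m].model,
            ).estimates
        write_ascii_grid(surfaces[m], out / f"surface_{m}.asc")
    st["surfaces"] = list(surfaces)

    # --- harmonization ----------------------------------------------------
    st = stage("harmonization")
    hcfg = config.get("harmonization", {})
    plots_h = harmonize_plots(
        plots, delta_t=hcfg.get("delta_years", 0),
        cell_size=hcfg.get("cell_size", grid.cell_size),
    )
    plots_h.to_csv(out / "plots_harmonized.csv", index=False)

    # --- predictor assembly ----------------------------------------------
    st = stage("predictors")
    candidate = predictors.assemble_candidate_rasters(surfaces, bands, dem)
    table = predictors.extract_at_points(candidate, plots_h)
    feature_cols = list(candidate)
    table = table.dropna(subset=feature_cols)
    table.to_csv(out / "feature_table.csv", index=False)
    st["n_candidates"] = len(feature_cols)
    st["n_rows"] = len(table)

    # --- feature screen ---------------------------------------------------
    st = stage("selection")
    scfg = config.get("selection", {})
    sel = predictors.vif_select(
        table[feature_cols + ["volume_per_ha"]],
        threshold=scfg.get("vif_threshold", 5.0),
    )
    sel = predictors.shap_rank(
        table, sel, top_k=scfg.get("top_k", 6),
        seed=stage_seed(seed, "shap"),
    )
    st["selection"] = sel.to_dict()
    (out / "selection_report.json").write_text(json.dumps(sel.to_dict(), indent=2))

    # --- stacking ---------------------------------------------------------
    st = stage("stacking")
    kcfg = config.get("stacking", {})
    spec = stacking.StackSpec(
        oof_folds=kcfg.get("oof_folds", 10),
        seed=stage_seed(seed, "stack") % 2**31,
    )
    X = table[sel.final_features].to_numpy(float)
    y = table["volume_per_ha"].to_numpy(float)
    rng = np.random.default_rng(stage_seed(seed, "split"))
    n = len(y)
    perm = rng.permutation(n)
    n_test = int(round(kcfg.get("test_frac", 0.2) * n))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    fs = stacking.fit_mlsem(X[train_idx], y[train_idx], spec,
                            feature_names=sel.final_features)
    pred_test = stacking.predict_stack(fs, X[test_idx])
    holdout = stacking.evaluate(y[test_idx], pred_test)
    cv = stacking.evaluate(y[train_idx], stacking.predict_stack(fs, X[train_idx]))
    st["ranking"] = fs.ranking
    st["holdout"] = holdout.to_dict()
    st["train_fit"] = cv.to_dict()

    # --- wall-to-wall map -------------------------------------------------
    st = stage("map")
    layer_stack = {name: candidate[name] for name in sel.final_features}
    volume_map, summary = stacking.apply_map(fs, layer_stack,
                                             cell_size=hcfg.get("cell_size", grid.cell_size))
    write_ascii_grid(volume_map, out / "volume_map.asc")
    st["summary"] = summary

    report["elapsed_s"] = time.time() - t_start
    report["thresholds"] = {
        "sensitivity_min": qc.get("sensitivity_min", 0.9),
        "gate": threshold,
        "vif": scfg.get("vif_threshold", 5.0),
        "top_k": scfg.get("top_k", 6),
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
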