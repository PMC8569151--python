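"""Pipeline glue: extract -> calibrate -> indices -> estimate -> evaluate.

All intermediate artifacts are plain CSV/JSON so any stage can be inspected
or replaced; a manifest records seeds and input hashes (no timestamps, so
identical configs give byte-identical runs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import pearson_r, validation_stats
from .plot_geometry import (
    Fishnet,
    SceneRaster,
    average_rows_to_plot,
    read_fishnet,
    read_scene,
    zonal_mean_dn,
    zonal_results_to_frame,
)
from .radiometry import (
    BANDS,
    CalibrationSet,
    builtin_calibrations,
    fit_calibration_set,
    read_calibration_json,
    read_panel_csv,
)
from .trait_models import LinearTraitModel, fit_linear_trait_model, frozen_model
from .vegindices import compute_vis_frame

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "resolve_calibration",
    "extract_plot_reflectance",
    "run_estimation",
    "run_validation",
]

log = logging.getLogger("rgbphen")


class PipelineError(RuntimeError):
    """A stage failure with plot/file context attached."""


@dataclass
class PipelineConfig:
    scene_paths: list[str]
    fishnet_path: str
    out_dir: str
    calibration: str = "2017"  # builtin label, calibration .json, or panel .csv
    model_ids: list[str] = field(default_factory=lambda: ["reg1", "reg2", "reg3", "reg4"])
    bit_depth: int = 8
    ground_truth_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def resolve_calibration(spec: str, scene=None, panel_fishnet=None) -> CalibrationSet:
    """A builtin campaign label, a calibration JSON, or a panel CSV to fit."""
    p = Path(spec)
    if p.suffix == ".json" and p.exists():
        return read_calibration_json(p)
    if p.suffix == ".csv" and p.exists():
        return fit_calibration_set(read_panel_csv(p), label=p.stem)
    return builtin_calibrations(spec)


def extract_plot_reflectance(
    scene: SceneRaster, fishnet: Fishnet, calibration: CalibrationSet
) -> pd.DataFrame:
    """Zonal DN means, calibrated per row polygon, then averaged per plot.

    Row polygons are grouped by their ``parent`` property (falling back to
    the polygon id); two-row plots are averaged at the reflectance level.
    Returns columns plot_id, red, green, blue, pixel_count.
    """
    results, errors = zonal_mean_dn(scene, fishnet)
    if errors:
        details = "; ".join(f"{e.plot_id}: {e.reason}" for e in errors)
        raise PipelineError(f"zonal extraction failed for {len(errors)} plot(s): {details}")
    parent_of = {
        p.plot_id: str(p.extra.get("parent", p.plot_id)) for p in fishnet
    }
    rows = []
    for res in results:
        triple = tuple(
            calibration[band].apply(dn)
            for band, dn in (
                ("red", res.mean_dn_red),
                ("green", res.mean_dn_green),
                ("blue", res.mean_dn_blue),
            )
        )
        rows.append(
            {
                "parent": parent_of[res.plot_id],
                "triple": triple,
                "pixel_count": res.pixel_count,
            }
        )
    out = []
    frame = pd.DataFrame(rows)
    for parent, sub in frame.groupby("parent", sort=False):
        triples = list(sub["triple"])
        if len(triples) == 1:
            red, green, blue = triples[0]
        elif len(triples) == 2:
            red, green, blue = average_rows_to_plot(triples)
        else:
            raise PipelineError(
                f"plot {parent}: expected 1 or 2 row polygons, got {len(triples)}"
            )
        out.append(
            {
                "plot_id": parent,
                "red": red,
                "green": green,
                "blue": blue,
                "pixel_count": int(sub["pixel_count"].sum()),
            }
        )
    return pd.DataFrame(out)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_estimation(config: PipelineConfig) -> dict:
    """Run the full estimation pipeline and write CSV/JSON artifacts.

    Returns a summary dict with the output paths and per-model metrics.
    Raises :class:`PipelineError` with context on any stage failure.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    for path in [*config.scene_paths, config.fishnet_path]:
        if not Path(path).exists():
            raise PipelineError(f"input file not found: {path}")

    log.info("reading scene (%d band files)", len(config.scene_paths))
    scene = read_scene(config.scene_paths, config.bit_depth)
    fishnet = read_fishnet(config.fishnet_path)
    log.info("fishnet: %d polygons", len(fishnet))

    calibration = resolve_calibration(config.calibration)
    refl = extract_plot_reflectance(scene, fishnet, calibration)
    log.info("extracted reflectance for %d plots", len(refl))
    refl.to_csv(out_dir / "reflectance.csv", index=False)

    vis = compute_vis_frame(refl)
    vis.to_csv(out_dir / "vegetation_indices.csv", index=False)

    est_rows = []
    for model_id in config.model_ids:
        model = frozen_model(model_id)
        values = model.predict(vis)
        for pid, val in zip(vis["plot_id"], values):
            est_rows.append(
                {
                    "plot_id": pid,
                    "model": model_id,
                    "trait": model.trait,
                    "estimate": float(val),
                    "below_zero": bool(val < 0),
                }
            )
    estimates = pd.DataFrame(est_rows)
    estimates.to_csv(out_dir / "estimates.csv", index=False)
    log.info("estimates: %d rows (%d models)", len(estimates), len(config.model_ids))

    metrics: dict[str, dict] = {}
    if config.ground_truth_path:
        truth = pd.read_csv(config.ground_truth_path)
        for model_id in config.model_ids:
            model = frozen_model(model_id)
            col = model.trait.lower()
            if col not in truth.columns:
                continue
            merged = estimates[estimates["model"] == model_id].merge(
                truth[["plot_id", col]], on="plot_id"
            )
            if len(merged) < 3:
                continue
            vs = validation_stats(merged[col], merged["estimate"])
            metrics[model_id] = {
                "trait": model.trait,
                "n": len(merged),
                "pearson_r": pearson_r(merged[col], merged["estimate"]),
                "mean_error": vs.mean_error,
                "sd_error": vs.sd_error,
                "r2": vs.r2,
            }
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "calibration": config.calibration,
        "model_ids": list(config.model_ids),
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [*config.scene_paths, config.fishnet_path]
        },
        "outputs": sorted(
            p.name for p in out_dir.iterdir() if p.suffix in (".csv", ".json")
            and p.name != "manifest.json"
        ),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"out_dir": str(out_dir), "n_plots": len(refl), "metrics": metrics}


def run_validation(
    train_table: pd.DataFrame,
    validation_table: pd.DataFrame,
    model: str | LinearTraitModel,
    refit: bool = False,
):
    """Apply a model from the training campaign to a validation campaign.

    ``model`` is a frozen id or a fitted :class:`LinearTraitModel`; with
    ``refit`` the model is re-estimated on the training table first.  Both
    tables must carry the model's VI columns and its trait column.
    """
    if isinstance(model, str):
        model = frozen_model(model)
    missing = [
        c
        for c in (*model.predictor_names, model.trait)
        if c not in validation_table.columns
    ]
    if missing:
        raise PipelineError(f"validation table missing column(s): {missing}")
    if refit:
        model = fit_linear_trait_model(
            train_table, model.predictor_names, model.trait, mode=model.mode
        )
    predicted = model.predict(validation_table)
    observed = validation_table[model.trait].to_numpy(dtype=float)
    return validation_stats(observed, predicted)


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
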