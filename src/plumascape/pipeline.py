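"""End-to-end orchestration: simulate/load -> biovars -> window scan ->
covariate selection -> forest fit -> validation -> ensemble prediction.

One master seed drives every stage through named derived seeds, so a
config re-run reproduces all numbers and any stage can be re-run on its
own. The run manifest (JSON) records the seeds, the chosen window,
covariates and mtry, all validation metrics, and a checksum of every
artifact written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _shapely_shape

from ._seeds import derive_seed
from .covariates import build_covariate_stack
from .ensemble import RFConfig, choose_mtry, fit_ensemble_predict, fit_rf, partial_dependence, permutation_importance
from .grids import (
    GeoGrid,
    GridError,
    GridStack,
    extract_at_points,
    read_geotiff,
    read_samples_csv,
    descriptive_stats,
    write_geotiff,
)
from .selection import RFESpec, rfe_select
from .synthetic import (
    SimConfig,
    climatology_from_stack,
    d2hp_monthly_from_stack,
    simulate_samples,
    simulate_surfaces,
    static_from_stack,
)
from .validation import compute_metrics, repeated_kfold_predictions, split_train_test
from .windows import scan_windows

__all__ = ["PipelineConfig", "run_pipeline", "mask_to_polygon"]

logger = logging.getLogger("plumascape")


@dataclass
class PipelineConfig:
    """Everything one isoscape run needs.

    Either ``sim`` (synthetic mode) or ``samples_csv`` plus grid
    directories must be provided. The master ``seed`` propagates to
    every stage.
    """

    out_dir: str = "plumascape_run"
    seed: int = 0
    sim: SimConfig | None = None
    samples_csv: str | None = None
    grids_dir: str | None = None

    window_lengths: tuple[int, ...] = (3,)
    candidate_covariates: list[str] | None = None
    rfe_k_folds: int = 10
    rfe_n_trees: int = 300
    rf_n_trees: int = 500
    n_ensemble: int = 20
    train_fraction: float = 0.8
    cv_k: int = 10
    cv_repeats: int = 5
    mask_geojson: str | None = None


def mask_to_polygon(grid: GeoGrid, polygon) -> GeoGrid:
    """Set cells whose centers fall outside the polygon to nodata."""
    polygon = _shapely_shape(polygon) if isinstance(polygon, dict) else polygon
    if polygon.is_empty:
        raise GridError("mask polygon is empty")
    lon, lat = np.meshgrid(grid.x_centers, grid.y_centers)
    inside = shapely.contains_xy(polygon, lon.ravel(), lat.ravel()).reshape(lon.shape)
    vals = grid.values.copy()
    vals[~inside] = np.nan
    return grid.with_values(vals)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise GridError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _load_monthly(grids_dir: Path, prefix: str) -> list[GeoGrid]:
    out = []
    for m in range(1, 13):
        path = grids_dir / f"{prefix}_{m:02d}.tif"
        if not path.exists():
            raise GridError(f"missing monthly grid {path}")
        out.append(read_geotiff(path))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full isoscape chain; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "checksums": {}}
    artifacts: list[Path] = []

    # ---- stage 1: data -----------------------------------------------------
    with _stage("prepare-data"):
        if config.sim is not None:
            stack = simulate_surfaces(config.sim)
            samples, truth = simulate_samples(stack, config.sim)
            clim = climatology_from_stack(stack, config.sim)
            d2hp = d2hp_monthly_from_stack(stack)
            static = static_from_stack(stack)
            samples_path = out / "samples.csv"
            samples.to_csv(samples_path, index=False)
            artifacts.append(samples_path)
            truth_path = out / "truth.json"
            truth_path.write_text(
                json.dumps(
                    {
                        "coef": truth.coef,
                        "window": [truth.window.start_month, truth.window.length],
                        "noise_sd": config.sim.noise_sd,
                        "site_sd": config.sim.site_sd,
                    },
                    indent=2,
                )
            )
            artifacts.append(truth_path)
        else:
            if config.samples_csv is None:
                raise GridError("config is missing the samples path")
            if config.grids_dir is None:
                raise GridError("config is missing the grids directory")
            samples = read_samples_csv(config.samples_csv)
            gdir = Path(config.grids_dir)
            from .bioclim import MonthlyClimatology

            clim = MonthlyClimatology(
                tmin=_load_monthly(gdir, "tmin"),
                tmax=_load_monthly(gdir, "tmax"),
                prec=_load_monthly(gdir, "prec"),
            )
            d2hp = _load_monthly(gdir, "d2hp")
            static = GridStack()
            for name in ("solar", "wind", "vapor", "altitude"):
                p = gdir / f"{name}.tif"
                if p.exists():
                    static.add(name, read_geotiff(p))
        manifest["stages"]["samples"] = descriptive_stats(samples)

    # ---- stage 2: window scan ---------------------------------------------
    with _stage("window-scan"):
        scan = scan_windows(samples, d2hp, clim.prec, lengths=config.window_lengths)
        window = scan.best_window
        scan.table.to_csv(out / "window_scan.csv", index=False)
        artifacts.append(out / "window_scan.csv")
        manifest["stages"]["window"] = {
            "best_start_month": window.start_month,
            "best_length": window.length,
            "best_r2": float(
                scan.table.loc[
                    (scan.table.start_month == window.start_month)
                    & (scan.table.length == window.length),
                    "r_squared",
                ].iloc[0]
            ),
            "annual_r2": scan.annual_r2,
        }

    # ---- stage 3: covariates + RFE ----------------------------------------
    with _stage("select-covariates"):
        cov_stack = build_covariate_stack(
            clim, d2hp, static, window, include=config.candidate_covariates
        )
        matrix = extract_at_points(cov_stack, samples)
        if matrix.dropped_nodata:
            logger.warning("dropped %d sample(s) on nodata: %s",
                           len(matrix.dropped_nodata), matrix.dropped_nodata[:10])
        rfe = rfe_select(
            matrix,
            RFESpec(
                k_folds=config.rfe_k_folds,
                seed=derive_seed(config.seed, "rfe"),
                n_trees=config.rfe_n_trees,
            ),
        )
        rfe.rmse_by_size.to_csv(out / "rfe_profile.csv", index=False)
        artifacts.append(out / "rfe_profile.csv")
        (out / "rfe_selected.json").write_text(json.dumps(rfe.chosen_variables, indent=2))
        artifacts.append(out / "rfe_selected.json")
        manifest["stages"]["rfe"] = {
            "chosen_size": rfe.chosen_size,
            "chosen_variables": rfe.chosen_variables,
        }
        matrix = matrix.subset_columns(rfe.chosen_variables)

    # ---- stage 4: fit + validation ----------------------------------------
    with _stage("fit-validate"):
        train_tbl, test_tbl = split_train_test(
            samples, config.train_fraction, seed=derive_seed(config.seed, "split")
        )
        train = matrix.subset_rows(
            [i for i in train_tbl["sample_id"].astype(str) if i in matrix.data.index]
        )
        test = matrix.subset_rows(
            [i for i in test_tbl["sample_id"].astype(str) if i in matrix.data.index]
        )
        mtry = (
            choose_mtry(train, n_trees=config.rf_n_trees, seed=derive_seed(config.seed, "mtry"))
            if train.n_covariates >= 2
            else 1
        )
        rf_cfg = RFConfig(
            mtry=mtry,
            n_trees=config.rf_n_trees,
            seed=derive_seed(config.seed, "rf"),
            n_ensemble=config.n_ensemble,
        )
        model = fit_rf(train, rf_cfg)
        importance = permutation_importance(
            model, train, seed=derive_seed(config.seed, "importance")
        )
        importance.to_csv(out / "importance.csv")
        artifacts.append(out / "importance.csv")
        for cov in train.columns:
            pdp = partial_dependence(model, train, cov)
            pdp.to_csv(out / f"pdp_{cov}.csv", index=False)
            artifacts.append(out / f"pdp_{cov}.csv")

        cv_pairs = repeated_kfold_predictions(
            train,
            rf_cfg,
            k=config.cv_k,
            repeats=config.cv_repeats,
            seed=derive_seed(config.seed, "cv"),
        )
        cv_pairs.to_csv(out / "cv_observed_vs_predicted.csv", index=False)
        artifacts.append(out / "cv_observed_vs_predicted.csv")
        cv_metrics = compute_metrics(cv_pairs["observed"], cv_pairs["predicted"])
        manifest["stages"]["cv"] = cv_metrics.to_dict()
        manifest["stages"]["mtry"] = mtry
        manifest["stages"]["importance"] = importance["pct_inc_mse"].to_dict()

    # ---- stage 5: spatial prediction --------------------------------------
    with _stage("spatial-prediction"):
        product = fit_ensemble_predict(
            train,
            cov_stack.subset(train.columns),
            RFConfig(
                mtry=mtry,
                n_trees=config.rf_n_trees,
                seed=derive_seed(config.seed, "ensemble"),
                n_ensemble=config.n_ensemble,
            ),
        )
        mean_grid = product.mean_grid
        if config.mask_geojson:
            geo = json.loads(Path(config.mask_geojson).read_text())
            geom = geo["features"][0]["geometry"] if geo.get("type") == "FeatureCollection" else geo
            mean_grid = mask_to_polygon(mean_grid, geom)
        for name, grid in (
            ("isoscape_mean", mean_grid),
            ("isoscape_sd", product.sd_grid),
            ("isoscape_cv", product.cv_grid),
        ):
            path = out / f"{name}.tif"
            write_geotiff(grid, path)
            artifacts.append(path)

        # holdout validated against the ensemble-mean prediction at test sites
        grid_lookup = extract_at_points(
            GridStack({"pred": product.mean_grid}), test_tbl
        )
        holdout = compute_metrics(
            grid_lookup.y, grid_lookup.data["pred"].to_numpy()
        )
        manifest["stages"]["holdout"] = holdout.to_dict()
        manifest["stages"]["isoscape"] = {
            "predicted_min": float(np.nanmin(product.mean_grid.values)),
            "predicted_max": float(np.nanmax(product.mean_grid.values)),
            "member_count": product.member_count,
            "training_range": list(product.training_range),
        }

    for p in artifacts:
        manifest["checksums"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
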