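"""Random-forest fitting, OOB diagnostics and ensemble spatial prediction.

The forest is the standard regression random forest (bagged trees with
`mtry` candidate covariates per split). `mtry` is chosen by out-of-bag
RMSE over a candidate set that excludes 1 (single-covariate splits
overfit weak spatial signals). Covariate importance is the %IncMSE
permutation measure: the percentage increase in out-of-bag MSE when one
covariate's values are shuffled. Spatial prediction averages an
ensemble of forests that differ only by seed, trained on the identical
training matrix, yielding per-cell mean, SD and coefficient-of-variation
uncertainty surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ._seeds import derive_seed
from .grids import CovariateMatrix, GeoGrid, GridError, GridStack

__all__ = [
    "RFConfig",
    "IsoscapeProduct",
    "choose_mtry",
    "fit_rf",
    "oob_predictions",
    "permutation_importance",
    "partial_dependence",
    "fit_ensemble_predict",
]


@dataclass
class RFConfig:
    """Forest and ensemble settings.

    ``mtry="auto"`` picks by OOB error via :func:`choose_mtry`;
    ``n_ensemble`` forests (20 by default) make up the spatial
    prediction ensemble. ``bootstrap_members`` additionally resamples
    the training rows per member (off by default: members differ only
    by seed).
    """

    mtry: int | str = "auto"
    n_trees: int = 500
    seed: int = 0
    n_ensemble: int = 20
    bootstrap_members: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 50:
            raise ValueError("n_trees must be at least 50")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be at least 1")
        if self.mtry != "auto":
            self.mtry = int(self.mtry)
            if self.mtry < 1:
                raise ValueError("mtry must be positive")


@dataclass
class IsoscapeProduct:
    """Ensemble prediction surfaces plus provenance."""

    mean_grid: GeoGrid
    sd_grid: GeoGrid
    cv_grid: GeoGrid
    member_count: int
    seeds: list[int]
    covariates: list[str]
    training_range: tuple[float, float] = (np.nan, np.nan)


def _make_forest(n_features: int, mtry: int, n_trees: int, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=min(mtry, n_features),
        bootstrap=True,
        oob_score=False,
        random_state=int(seed),
        n_jobs=1,
    )


def fit_rf(matrix: CovariateMatrix, config: RFConfig) -> RandomForestRegressor:
    """Fit one regression forest on the covariate matrix."""
    if matrix.n_samples < 2:
        raise GridError("cannot fit a forest on fewer than 2 samples")
    mtry = config.mtry
    if mtry == "auto":
        if matrix.n_covariates >= 2:
            mtry = choose_mtry(matrix, n_trees=config.n_trees, seed=config.seed)
        else:
            mtry = 1
    if matrix.n_covariates >= 2 and mtry < 2:
        raise GridError("mtry must be >= 2 when two or more covariates are offered")
    model = _make_forest(matrix.n_covariates, int(mtry), config.n_trees, config.seed)
    model.fit(matrix.X, matrix.y)
    model.feature_names_ = matrix.columns  # carried for prediction-time checks
    return model


def oob_predictions(model: RandomForestRegressor, X: np.ndarray) -> np.ndarray:
    """Per-sample out-of-bag prediction (NaN where a sample was never OOB)."""
    n = X.shape[0]
    total = np.zeros(n)
    count = np.zeros(n)
    for tree, in_bag in zip(model.estimators_, model.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[in_bag] = False
        if oob.any():
            total[oob] += tree.predict(X[oob])
            count[oob] += 1
    with np.errstate(invalid="ignore"):
        pred = total / count
    pred[count == 0] = np.nan
    return pred


def _oob_mse(model: RandomForestRegressor, X: np.ndarray, y: np.ndarray) -> float:
    pred = oob_predictions(model, X)
    ok = np.isfinite(pred)
    return float(np.mean((y[ok] - pred[ok]) ** 2))


def choose_mtry(
    matrix: CovariateMatrix,
    candidates: Sequence[int] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> int:
    """Pick mtry by out-of-bag RMSE over a candidate set.

    The default candidate set is 2..p: mtry = 1 is excluded because
    single-covariate splits overfit. Ties go to the smaller value.
    """
    p = matrix.n_covariates
    if p < 2:
        raise GridError("mtry selection needs at least 2 covariates")
    if candidates is None:
        candidates = range(2, p + 1)
    candidates = sorted(int(c) for c in candidates)
    if any(c < 2 or c > p for c in candidates):
        raise GridError(f"mtry candidates must lie in 2..{p}, got {candidates}")
    best, best_rmse = None, np.inf
    for m in candidates:
        model = _make_forest(p, m, n_trees, seed)
        model.fit(matrix.X, matrix.y)
        rmse = np.sqrt(_oob_mse(model, matrix.X, matrix.y))
        if rmse < best_rmse:
            best, best_rmse = m, rmse
    return int(best)


def permutation_importance(
    model: RandomForestRegressor,
    matrix: CovariateMatrix,
    repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """%IncMSE permutation importance on out-of-bag predictions.

    For each covariate, its column is shuffled and the OOB MSE
    recomputed; the importance is ``100 * (permuted - baseline) /
    baseline`` averaged over ``repeats`` shuffles. Near-zero baseline
    (constant response) yields zero importance for every covariate.
    """
    X, y = matrix.X, matrix.y
    base = _oob_mse(model, X, y)
    rng = np.random.default_rng(seed)
    rows = []
    scale = float(np.var(y)) if np.var(y) > 0 else 1.0
    for j, name in enumerate(matrix.columns):
        increases = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            increases.append(_oob_mse(model, Xp, y) - base)
        if base <= 1e-12 * scale:
            pct = 0.0
        else:
            pct = 100.0 * float(np.mean(increases)) / base
        rows.append({"covariate": name, "pct_inc_mse": pct})
    table = pd.DataFrame(rows).set_index("covariate")
    return table


def partial_dependence(
    model: RandomForestRegressor,
    matrix: CovariateMatrix,
    covariate: str,
    grid_points: int = 25,
) -> pd.DataFrame:
    """Partial-dependence curve of the model on one covariate.

    For each of ``grid_points`` equally spaced values spanning the
    covariate's observed range, the covariate is set to that value in
    every training row and the model predictions averaged.
    """
    if covariate not in matrix.columns:
        raise GridError(f"covariate {covariate!r} is not in the model matrix")
    j = matrix.columns.index(covariate)
    col = matrix.X[:, j]
    grid = np.linspace(col.min(), col.max(), grid_points)
    X = matrix.X.copy()
    means = []
    for v in grid:
        X[:, j] = v
        means.append(float(model.predict(X).mean()))
    return pd.DataFrame({"value": grid, "prediction": means})


def fit_ensemble_predict(
    matrix: CovariateMatrix,
    stack: GridStack,
    config: RFConfig,
    mask: np.ndarray | None = None,
    member_seeds: Sequence[int] | None = None,
) -> IsoscapeProduct:
    """Fit an ensemble of forests and predict over the grid.

    Each member trains on the identical matrix with a distinct derived
    seed (optionally a bootstrap resample), predicts every grid cell
    with complete covariates, and the per-cell mean, SD and CV (= SD /
    |mean|) across members form the isoscape product. Nodata in any
    covariate layer propagates; CV is nodata where the mean is zero.
    """
    missing = [c for c in matrix.columns if c not in stack]
    if missing:
        raise GridError(f"stack is missing covariate layer(s) {missing}")
    ref = stack.reference
    layers = np.stack([stack[c].values for c in matrix.columns])  # (p, r, c)
    valid = np.all(np.isfinite(layers), axis=0)
    if mask is not None:
        valid &= mask
    Xgrid = layers[:, valid].T

    if config.mtry == "auto":
        mtry = choose_mtry(matrix, n_trees=config.n_trees, seed=config.seed)
        config = RFConfig(
            mtry=mtry,
            n_trees=config.n_trees,
            seed=config.seed,
            n_ensemble=config.n_ensemble,
            bootstrap_members=config.bootstrap_members,
        )

    rng = np.random.default_rng(derive_seed(config.seed, "ensemble-bootstrap"))
    if member_seeds is None:
        seeds = [derive_seed(config.seed, f"ensemble-member-{i}") for i in range(config.n_ensemble)]
    else:
        if len(member_seeds) != config.n_ensemble:
            raise GridError("member_seeds length must equal n_ensemble")
        seeds = [int(s) for s in member_seeds]
    preds = np.empty((config.n_ensemble, Xgrid.shape[0]))
    for i, member_seed in enumerate(seeds):
        sub = matrix
        if config.bootstrap_members:
            idx = rng.integers(0, matrix.n_samples, matrix.n_samples)
            sub = CovariateMatrix(
                matrix.data.iloc[idx].reset_index(drop=True),
                matrix.response.iloc[idx].reset_index(drop=True),
            )
        member_cfg = RFConfig(
            mtry=config.mtry, n_trees=config.n_trees, seed=member_seed, n_ensemble=1
        )
        model = fit_rf(sub, member_cfg)
        preds[i] = model.predict(Xgrid)

    mean = np.full(ref.values.shape, np.nan)
    sd = np.full(ref.values.shape, np.nan)
    mean[valid] = preds.mean(axis=0)
    sd[valid] = preds.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / np.abs(mean)
    cv[np.isclose(mean, 0.0)] = np.nan

    return IsoscapeProduct(
        mean_grid=ref.with_values(mean),
        sd_grid=ref.with_values(sd),
        cv_grid=ref.with_values(cv),
        member_count=config.n_ensemble,
        seeds=seeds,
        covariates=matrix.columns,
        training_range=(float(matrix.y.min()), float(matrix.y.max())),
    )
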