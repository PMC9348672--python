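"""Recursive Feature Elimination by cross-validated forest RMSE.

Backward covariate selection: inside each outer cross-validation fold a
forest on all covariates ranks them by permutation importance, forests
on the top-s subsets are scored on the held-out fold for every
candidate size s, and the size with the lowest mean held-out RMSE wins.
The final variable set is the top-`chosen_size` covariates of a
full-data forest's ranking. Recomputing the ranking inside every fold
avoids selection bias; ranking ties break by column order, RMSE ties by
the smaller subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from ._seeds import derive_seed
from .ensemble import RFConfig, fit_rf, permutation_importance
from .grids import CovariateMatrix, GridError

__all__ = ["RFESpec", "RFEResult", "rfe_select"]


@dataclass
class RFESpec:
    """Settings for the covariate-elimination loop.

    ``subset_sizes`` defaults to every size 1..p. One outer repetition
    of plain k-fold cross-validation is the default; ``n_repeats``
    makes it repeated CV. Forest settings pass through; importance
    inside folds uses ``importance_repeats`` permutation shuffles.
    """

    k_folds: int = 10
    subset_sizes: Sequence[int] | None = None
    seed: int = 0
    n_trees: int = 300
    mtry: int | str = "auto"
    n_repeats: int = 1
    importance_repeats: int = 3

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")


@dataclass
class RFEResult:
    """Per-size CV error profile and the chosen covariate set."""

    rmse_by_size: pd.DataFrame  # columns: size, mean_rmse, sd_rmse
    chosen_size: int
    chosen_variables: list[str]
    full_ranking: list[str]


def _rank_covariates(matrix: CovariateMatrix, spec: RFESpec, seed: int) -> list[str]:
    """Covariates ordered by decreasing permutation importance (stable)."""
    cfg = _rf_config(spec, seed, matrix.n_covariates)
    model = fit_rf(matrix, cfg)
    imp = permutation_importance(
        model, matrix, repeats=spec.importance_repeats, seed=derive_seed(seed, "rfe-imp")
    )
    scores = imp["pct_inc_mse"].to_numpy()
    order = np.argsort(-scores, kind="stable")  # ties keep column order
    return [matrix.columns[i] for i in order]


def _rf_config(spec: RFESpec, seed: int, p: int) -> RFConfig:
    mtry = spec.mtry
    if mtry == "auto":
        # inside RFE use the reference default p/3 (>=2 when possible) rather
        # than a nested OOB search, which would be quadratic in forest fits
        mtry = max(2, p // 3) if p >= 2 else 1
    return RFConfig(mtry=min(int(mtry), max(p, 1)), n_trees=spec.n_trees, seed=seed, n_ensemble=1)


def rfe_select(matrix: CovariateMatrix, spec: RFESpec) -> RFEResult:
    """Run recursive feature elimination and return the chosen subset."""
    n, p = matrix.n_samples, matrix.n_covariates
    if p < 1:
        raise GridError("RFE needs at least one covariate")
    if n < spec.k_folds:
        raise GridError(
            f"n = {n} samples is smaller than k_folds = {spec.k_folds}; use a smaller k"
        )
    if np.ptp(matrix.y) == 0:
        raise GridError("constant response: covariate ranking is undefined")
    sizes = sorted(set(spec.subset_sizes)) if spec.subset_sizes else list(range(1, p + 1))
    if any(s < 1 or s > p for s in sizes):
        raise GridError(f"subset sizes must lie in 1..{p}, got {sizes}")

    fold_rmse: dict[int, list[float]] = {s: [] for s in sizes}
    for rep in range(spec.n_repeats):
        kf = KFold(
            n_splits=spec.k_folds,
            shuffle=True,
            random_state=derive_seed(spec.seed, f"rfe-fold-{rep}"),
        )
        for f, (tr, te) in enumerate(kf.split(matrix.X)):
            ids_tr = matrix.data.index[tr]
            ids_te = matrix.data.index[te]
            train = matrix.subset_rows(ids_tr)
            fold_seed = derive_seed(spec.seed, f"rfe-rep{rep}-fold{f}")
            ranking = _rank_covariates(train, spec, fold_seed)
            for s in sizes:
                top = ranking[:s]
                sub = train.subset_columns(top)
                model = fit_rf(sub, _rf_config(spec, derive_seed(fold_seed, f"size{s}"), s))
                Xte = matrix.data.loc[ids_te, top].to_numpy(dtype=float)
                pred = model.predict(Xte)
                resid = matrix.response.loc[ids_te].to_numpy() - pred
                fold_rmse[s].append(float(np.sqrt(np.mean(resid**2))))

    profile = pd.DataFrame(
        {
            "size": sizes,
            "mean_rmse": [float(np.mean(fold_rmse[s])) for s in sizes],
            "sd_rmse": [float(np.std(fold_rmse[s], ddof=1)) if len(fold_rmse[s]) > 1 else 0.0
                        for s in sizes],
        }
    )
    # lowest mean RMSE; ties to the smaller subset (sizes ascending, strict <)
    best_row = profile.loc[profile["mean_rmse"].idxmin()]
    chosen_size = int(best_row["size"])

    full_ranking = _rank_covariates(matrix, spec, derive_seed(spec.seed, "rfe-full"))
    chosen = full_ranking[:chosen_size]
    return RFEResult(
        rmse_by_size=profile,
        chosen_size=chosen_size,
        chosen_variables=chosen,
        full_ranking=full_ranking,
    )
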