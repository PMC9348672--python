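"""Replicated parameter-recovery experiments on the synthetic world.

These are the package's standing reproducibility checks: each function
generates data with known ground truth, runs the corresponding pipeline
stage, and reports how often (or how well) the truth is recovered. The
test suite and the acceptance script both call them, so the numbers
they print are always recomputed, never stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .ensemble import RFConfig, fit_rf
from .grids import CovariateMatrix
from .selection import RFESpec, rfe_select
from .synthetic import (
    SimConfig,
    climatology_from_stack,
    d2hp_monthly_from_stack,
    paperlike_config,
    simulate_samples,
    simulate_surfaces,
)
from .validation import compute_metrics, repeated_kfold_predictions, split_train_test
from .windows import scan_windows

__all__ = [
    "window_recovery",
    "rfe_recovery",
    "holdout_vs_cv",
    "noiseless_end_to_end_r2",
]


def window_recovery(n_replicates: int = 50, seed: int = 0,
                    n_sites: int = 200, noise_sd: float = 6.0) -> dict:
    """How often the month-window scan ranks the true window first.

    Feathers are generated from the February-April composite alone
    (plus intercept and noise), so the scan is asked exactly the
    question it answers: which window's composite drives the signal.
    Also reports how often the full-year baseline fit is beaten.
    """
    hits = 0
    annual_beaten = 0
    for rep in range(n_replicates):
        cfg = SimConfig(
            seed=derive_seed(seed, f"window-rep-{rep}"),
            n_sites=n_sites,
            noise_sd=noise_sd,
            coef={"intercept": -30.0, "d2hp_window": 1.0},
        )
        stack = simulate_surfaces(cfg)
        samples, _ = simulate_samples(stack, cfg)
        clim = climatology_from_stack(stack, cfg)
        res = scan_windows(samples, d2hp_monthly_from_stack(stack), clim.prec)
        best = (res.best_window.start_month, res.best_window.length)
        hits += best == (cfg.true_window.start_month, cfg.true_window.length)
        true_row = res.table[
            (res.table.start_month == cfg.true_window.start_month)
            & (res.table.length == cfg.true_window.length)
        ].iloc[0]
        annual_beaten += res.annual_r2 < true_row.r_squared
    return {
        "recovery_rate": hits / n_replicates,
        "annual_beaten_rate": annual_beaten / n_replicates,
        "n_replicates": n_replicates,
    }


def _known_truth_matrix(n: int, seed: int, n_informative: int = 3,
                        n_noise: int = 5, noise_sd: float = 0.3) -> CovariateMatrix:
    rng = np.random.default_rng(seed)
    betas = [2.0, -1.5, 1.0, 0.8, -0.6][:n_informative]
    cols = {f"sig{j}": rng.normal(size=n) for j in range(n_informative)}
    cols.update({f"junk{j}": rng.normal(size=n) for j in range(n_noise)})
    X = pd.DataFrame(cols, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))
    y = sum(b * X[f"sig{j}"] for j, b in enumerate(betas)) + rng.normal(0, noise_sd, n)
    return CovariateMatrix(X, pd.Series(np.asarray(y), index=X.index, name="d2h_f"))


def rfe_recovery(n_replicates: int = 20, seed: int = 0, n: int = 300,
                 n_trees: int = 100) -> dict:
    """How often RFE keeps every informative covariate.

    Three informative covariates against five independent-noise ones at
    low residual noise: the chosen subset should contain all three.
    """
    hits = 0
    for rep in range(n_replicates):
        m = _known_truth_matrix(n, derive_seed(seed, f"rfe-rep-{rep}"))
        res = rfe_select(
            m,
            RFESpec(
                k_folds=10,
                n_trees=n_trees,
                importance_repeats=2,
                seed=derive_seed(seed, f"rfe-spec-{rep}"),
            ),
        )
        hits += {"sig0", "sig1", "sig2"} <= set(res.chosen_variables)
    return {"containment_rate": hits / n_replicates, "n_replicates": n_replicates}


def holdout_vs_cv(seed: int = 0, n_trees: int = 150, n_ensemble: int = 20,
                  clustered: bool = True) -> dict:
    """Holdout-vs-pooled-CV comparison on the museum-like preset.

    Clustered duplicated localities with location-shared noise: the
    80/20 holdout is scored against the 20-member ensemble mean while
    the pooled repeated 10-fold CV uses single per-fold models, which
    is exactly how the two numbers are produced in practice. Reports
    both r-squared values.
    """
    sim = paperlike_config(seed)
    if not clustered:  # spatially independent sites, no duplicated localities
        sim.clustered = False
        sim.n_locations = None
    stack = simulate_surfaces(sim)
    samples, truth = simulate_samples(stack, sim)
    matrix = CovariateMatrix(
        truth.covariates,
        pd.Series(samples["d2h_f"].to_numpy(), index=truth.covariates.index, name="d2h_f"),
    )
    train_tbl, test_tbl = split_train_test(samples, 0.8, seed=derive_seed(seed, "split"))
    train = matrix.subset_rows(train_tbl["sample_id"].tolist())
    test = matrix.subset_rows(test_tbl["sample_id"].tolist())

    mtry = 3  # the pipeline default for a five-covariate model
    cv = repeated_kfold_predictions(
        train, RFConfig(mtry=mtry, n_trees=n_trees), k=10, repeats=5,
        seed=derive_seed(seed, "cv"),
    )
    cv_rep = compute_metrics(cv["observed"], cv["predicted"])

    member_preds = []
    for i in range(n_ensemble):
        model = fit_rf(
            train,
            RFConfig(mtry=mtry, n_trees=n_trees, seed=derive_seed(seed, f"member-{i}")),
        )
        member_preds.append(model.predict(test.X))
    ens = np.mean(member_preds, axis=0)
    hold_rep = compute_metrics(test.y, ens)
    return {
        "cv_r2": cv_rep.r_squared,
        "cv_rmse": cv_rep.rmse,
        "cv_pairs": cv_rep.n,
        "holdout_r2": hold_rep.r_squared,
        "holdout_rmse": hold_rep.rmse,
        "holdout_n": hold_rep.n,
    }


def noiseless_end_to_end_r2(seed: int = 0, n_sites: int = 600,
                            n_trees: int = 300) -> float:
    """Held-out r-squared when the transfer model is offered noise-free.

    With zero noise and the generating covariates available, the forest
    only has to approximate a smooth additive function; the held-out
    fit should be nearly perfect.
    """
    cfg = SimConfig(seed=derive_seed(seed, "e2e"), n_sites=n_sites,
                    noise_sd=0.0, site_sd=0.0)
    stack = simulate_surfaces(cfg)
    samples, truth = simulate_samples(stack, cfg)
    matrix = CovariateMatrix(
        truth.covariates,
        pd.Series(samples["d2h_f"].to_numpy(), index=truth.covariates.index, name="d2h_f"),
    )
    train_tbl, test_tbl = split_train_test(samples, 0.8, seed=derive_seed(seed, "e2e-split"))
    train = matrix.subset_rows(train_tbl["sample_id"].tolist())
    test = matrix.subset_rows(test_tbl["sample_id"].tolist())
    model = fit_rf(train, RFConfig(mtry=3, n_trees=n_trees, seed=derive_seed(seed, "e2e-rf")))
    rep = compute_metrics(test.y, model.predict(test.X))
    return rep.r_squared
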