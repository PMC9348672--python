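"""Train/test splitting, repeated k-fold CV and observed-vs-predicted metrics.

Two error conventions are reported side by side. ``mae`` is the true
mean absolute residual. ``mse_paper`` is the mean *squared* residual —
the quantity some isoscape studies print under the label "MAE", whose
square root is their RMSE (e.g. 231.21 -> 15.21); naming it
``mse_paper`` keeps the arithmetic honest while staying comparable.
Diagnostics come from the least-squares fit observed = a + b*predicted
with t-tests of the slope against 1 and the intercept against 0: a
well-calibrated predictor should not reject either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

from ._seeds import derive_seed
from .ensemble import RFConfig, fit_rf
from .grids import CovariateMatrix, GridError

__all__ = [
    "ValidationReport",
    "split_train_test",
    "repeated_kfold_predictions",
    "compute_metrics",
]


@dataclass
class ValidationReport:
    """Observed-vs-predicted metrics and regression diagnostics."""

    n: int
    mae: float
    mse_paper: float
    rmse: float
    r_squared: float
    slope: float
    intercept: float
    p_slope_vs_1: float
    p_intercept_vs_0: float
    f_stat: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def split_train_test(samples: pd.DataFrame, fraction: float = 0.8, seed: int = 0):
    """Random 80/20 split of a sample table, reproducible given the seed.

    The training size is ceil(fraction * n); 192 samples at 0.8 give a
    154/38 partition.
    """
    if not 0 < fraction < 1:
        raise GridError(f"fraction must lie strictly between 0 and 1, got {fraction}")
    n = len(samples)
    if n < 10:
        raise GridError(f"need at least 10 samples to split, got {n}")
    n_train = int(np.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = samples.iloc[np.sort(perm[:n_train])].copy()
    test = samples.iloc[np.sort(perm[n_train:])].copy()
    return train, test


def repeated_kfold_predictions(
    matrix: CovariateMatrix,
    rf_config: RFConfig | None = None,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled out-of-fold predictions from repeated k-fold CV.

    Every sample receives exactly ``repeats`` out-of-fold predictions
    (one per repetition), so the pooled table has n * repeats rows —
    156 training samples at k = 10, 5 repeats give 780 pairs. Columns:
    sample_id, repeat, fold, observed, predicted.
    """
    n = matrix.n_samples
    if k > n:
        raise GridError(f"k = {k} folds exceed n = {n} samples")
    if rf_config is None:
        rf_config = RFConfig()
    rows = []
    for rep in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=derive_seed(seed, f"cv-rep-{rep}"))
        for f, (tr, te) in enumerate(kf.split(matrix.X)):
            train = matrix.subset_rows(matrix.data.index[tr])
            cfg = RFConfig(
                mtry=rf_config.mtry,
                n_trees=rf_config.n_trees,
                seed=derive_seed(seed, f"cv-rep{rep}-fold{f}"),
                n_ensemble=1,
            )
            model = fit_rf(train, cfg)
            pred = model.predict(matrix.X[te])
            for i, p in zip(te, pred):
                rows.append(
                    {
                        "sample_id": matrix.data.index[i],
                        "repeat": rep,
                        "fold": f,
                        "observed": float(matrix.y[i]),
                        "predicted": float(p),
                    }
                )
    return pd.DataFrame(rows)


def compute_metrics(observed, predicted) -> ValidationReport:
    """Error metrics and calibration diagnostics for paired predictions."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise GridError("observed and predicted must have equal length")
    n = obs.size
    if n < 3:
        raise GridError(f"need at least 3 pairs, got {n}")
    resid = obs - pred
    mae = float(np.mean(np.abs(resid)))
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))

    if np.ptp(pred) == 0:
        return ValidationReport(
            n=n, mae=mae, mse_paper=mse, rmse=rmse,
            r_squared=np.nan, slope=np.nan, intercept=np.nan,
            p_slope_vs_1=np.nan, p_intercept_vs_0=np.nan, f_stat=np.nan,
            degenerate=True,
        )

    X = sm.add_constant(pred)
    fit = sm.OLS(obs, X).fit()
    intercept, slope = fit.params
    se_intercept, se_slope = fit.bse
    from scipy import stats as _st

    df = n - 2
    if se_slope > 0:
        t_slope = (slope - 1.0) / se_slope
    else:  # perfect fit: the slope is exactly its estimate
        t_slope = 0.0 if np.isclose(slope, 1.0) else np.inf
    if se_intercept > 0:
        t_inter = (intercept - 0.0) / se_intercept
    else:
        t_inter = 0.0 if np.isclose(intercept, 0.0) else np.inf
    p_slope = float(2 * _st.t.sf(abs(t_slope), df))
    p_inter = float(2 * _st.t.sf(abs(t_inter), df))
    return ValidationReport(
        n=n,
        mae=mae,
        mse_paper=mse,
        rmse=rmse,
        r_squared=float(fit.rsquared),
        slope=float(slope),
        intercept=float(intercept),
        p_slope_vs_1=p_slope,
        p_intercept_vs_0=p_inter,
        f_stat=float(fit.fvalue),
    )
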