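"""Forest fitting, OOB importance, partial dependence, ensemble surfaces."""

import numpy as np
import pandas as pd
import pytest

from plumascape import (
    CovariateMatrix,
    GeoGrid,
    GridStack,
    RFConfig,
    choose_mtry,
    fit_ensemble_predict,
    fit_rf,
    partial_dependence,
    permutation_importance,
)
from plumascape.grids import GridError


def _matrix(n, p, seed=0, response=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {f"x{j}": rng.normal(size=n) for j in range(p)},
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )
    if response is None:
        y = pd.Series(rng.normal(size=n), index=X.index, name="y")
    else:
        y = pd.Series(response(X, rng), index=X.index, name="y")
    return CovariateMatrix(X, y)


class TestMtry:
    def test_two_covariates_single_candidate(self):
        m = _matrix(60, 2, response=lambda X, r: X.x0 + r.normal(0, 0.1, len(X)))
        assert choose_mtry(m, candidates=[2], n_trees=60) == 2

    def test_single_covariate_rejected(self):
        m = _matrix(40, 1)
        with pytest.raises(GridError, match="at least 2"):
            choose_mtry(m)

    def test_candidates_outside_range_rejected(self):
        m = _matrix(40, 3)
        with pytest.raises(GridError, match="candidates"):
            choose_mtry(m, candidates=[1, 2])

    def test_reproducible_choice(self):
        m = _matrix(120, 5, seed=2,
                    response=lambda X, r: 3 * X.x0 + r.normal(0, 0.5, len(X)))
        a = choose_mtry(m, n_trees=80, seed=5)
        b = choose_mtry(m, n_trees=80, seed=5)
        assert a == b


class TestImportance:
    def test_constant_response_near_zero(self):
        m = _matrix(80, 3, response=lambda X, r: np.full(len(X), -40.0))
        model = fit_rf(m, RFConfig(mtry=2, n_trees=100))
        imp = permutation_importance(model, m, seed=0)
        assert (imp["pct_inc_mse"].abs() < 1.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_dominant_covariate_ranks_first(self, seed):
        m = _matrix(
            150, 4, seed=seed,
            response=lambda X, r: 5 * X.x1 + r.normal(0, 0.4, len(X)),
        )
        model = fit_rf(m, RFConfig(mtry=2, n_trees=150, seed=seed))
        imp = permutation_importance(model, m, seed=seed)
        assert imp["pct_inc_mse"].idxmax() == "x1"

    def test_mtry_one_with_multiple_covariates_rejected(self):
        m = _matrix(50, 3)
        with pytest.raises(GridError, match="mtry"):
            fit_rf(m, RFConfig(mtry=1, n_trees=60))

    def test_single_row_rejected(self):
        m = _matrix(1, 2)
        with pytest.raises(GridError, match="2 samples"):
            fit_rf(m, RFConfig(mtry=2, n_trees=60))


class TestPartialDependence:
    def test_linear_slope_recovery(self):
        m = _matrix(
            500, 2, seed=1,
            response=lambda X, r: 2.0 * X.x0 + r.normal(0, 0.3, len(X)),
        )
        model = fit_rf(m, RFConfig(mtry=2, n_trees=300, seed=1))
        pdp = partial_dependence(model, m, "x0")
        slope = np.polyfit(pdp["value"], pdp["prediction"], 1)[0]
        assert 1.6 <= slope <= 2.4

    def test_constant_response_flat_curve(self):
        m = _matrix(80, 2, response=lambda X, r: np.full(len(X), -60.0))
        model = fit_rf(m, RFConfig(mtry=2, n_trees=100))
        pdp = partial_dependence(model, m, "x0")
        assert np.ptp(pdp["prediction"]) < 1.0

    def test_monotone_decreasing_generator(self):
        m = _matrix(
            400, 2, seed=3,
            response=lambda X, r: -3.0 * X.x1 + r.normal(0, 0.3, len(X)),
        )
        model = fit_rf(m, RFConfig(mtry=2, n_trees=200, seed=3))
        pdp = partial_dependence(model, m, "x1")
        diffs = np.diff(pdp["prediction"])
        assert (diffs <= 1e-9).mean() >= 0.9

    def test_absent_covariate_rejected(self):
        m = _matrix(50, 2)
        model = fit_rf(m, RFConfig(mtry=2, n_trees=60))
        with pytest.raises(GridError, match="zz"):
            partial_dependence(model, m, "zz")


def _stack_for(matrix, shape=(8, 8), seed=0):
    rng = np.random.default_rng(seed)
    return GridStack(
        {
            c: GeoGrid(rng.normal(size=shape), 0.0, float(shape[0]), 1.0, 1.0)
            for c in matrix.columns
        }
    )


class TestEnsemble:
    def test_single_member_sd_zero(self):
        m = _matrix(60, 2, seed=4,
                    response=lambda X, r: X.x0 - X.x1 + r.normal(0, 0.2, len(X)))
        stack = _stack_for(m)
        prod = fit_ensemble_predict(m, stack, RFConfig(mtry=2, n_trees=60, n_ensemble=1))
        assert np.nanmax(prod.sd_grid.values) == 0.0

    def test_same_seed_members_sd_zero(self):
        m = _matrix(60, 2, seed=4,
                    response=lambda X, r: X.x0 - X.x1 + r.normal(0, 0.2, len(X)))
        stack = _stack_for(m)
        prod = fit_ensemble_predict(
            m, stack, RFConfig(mtry=2, n_trees=60, n_ensemble=3),
            member_seeds=[7, 7, 7],
        )
        # members are bit-identical; SD is zero up to mean-rounding noise
        assert np.nanmax(prod.sd_grid.values) < 1e-12

    def test_predictions_bounded_by_training_range(self):
        m = _matrix(80, 3, seed=5,
                    response=lambda X, r: -60 + 8 * X.x0 + r.normal(0, 2, len(X)))
        stack = _stack_for(m, seed=5)
        prod = fit_ensemble_predict(m, stack, RFConfig(mtry=2, n_trees=80, n_ensemble=4))
        lo, hi = prod.training_range
        assert np.nanmin(prod.mean_grid.values) >= lo - 1e-9
        assert np.nanmax(prod.mean_grid.values) <= hi + 1e-9

    def test_nodata_propagates_and_cv_definition(self):
        m = _matrix(60, 2, seed=6,
                    response=lambda X, r: 30 + X.x0 + r.normal(0, 0.2, len(X)))
        stack = _stack_for(m, seed=6)
        vals = stack["x0"].values.copy()
        vals[0, 0] = np.nan
        stack = GridStack({"x0": stack["x0"].with_values(vals), "x1": stack["x1"]})
        prod = fit_ensemble_predict(m, stack, RFConfig(mtry=2, n_trees=60, n_ensemble=3))
        assert np.isnan(prod.mean_grid.values[0, 0])
        assert np.isnan(prod.cv_grid.values[0, 0])
        ok = np.isfinite(prod.mean_grid.values)
        np.testing.assert_allclose(
            prod.cv_grid.values[ok],
            prod.sd_grid.values[ok] / np.abs(prod.mean_grid.values[ok]),
        )
        assert (prod.sd_grid.values[ok] >= 0).all()

    def test_missing_covariate_layer_named(self):
        m = _matrix(50, 2)
        stack = _stack_for(m).subset(["x0"])
        with pytest.raises(GridError, match="x1"):
            fit_ensemble_predict(m, stack, RFConfig(mtry=2, n_trees=60, n_ensemble=2))
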