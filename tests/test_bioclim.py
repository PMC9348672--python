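"""BIOCLIM variables against a brute-force quarter-enumeration oracle."""

import numpy as np
import pytest

from plumascape import GeoGrid, MonthlyClimatology, compute_biovars, period_climatology
from plumascape.grids import GridError


def _grid(val):
    return GeoGrid(np.atleast_2d(np.asarray(val, dtype=float)), 0.0, 1.0, 1.0, 1.0)


def make_clim(tmin, tmax, prec):
    """Single-cell climatology from 12-vectors."""
    return MonthlyClimatology(
        tmin=[_grid([[v]]) for v in tmin],
        tmax=[_grid([[v]]) for v in tmax],
        prec=[_grid([[v]]) for v in prec],
    )


def biovars_cell_oracle(tmin, tmax, prec):
    """Independent single-cell reference: pure-python quarter enumeration."""
    tavg = [(a + b) / 2.0 for a, b in zip(tmin, tmax)]
    quarters = [[(s + i) % 12 for i in range(3)] for s in range(12)]
    qprec = [sum(prec[m] for m in q) for q in quarters]
    qtavg = [sum(tavg[m] for m in q) / 3.0 for q in quarters]

    def first_argmax(xs):
        best = max(xs)
        return min(i for i, x in enumerate(xs) if x == best)

    def first_argmin(xs):
        best = min(xs)
        return min(i for i, x in enumerate(xs) if x == best)

    out = {}
    out["bio1"] = sum(tavg) / 12.0
    out["bio2"] = sum(b - a for a, b in zip(tmin, tmax)) / 12.0
    out["bio5"] = max(tmax)
    out["bio6"] = min(tmin)
    out["bio7"] = out["bio5"] - out["bio6"]
    out["bio3"] = 100.0 * out["bio2"] / out["bio7"] if out["bio7"] != 0 else None
    mean_t = out["bio1"]
    out["bio4"] = 100.0 * (sum((t - mean_t) ** 2 for t in tavg) / 12.0) ** 0.5
    wet, dry = first_argmax(qprec), first_argmin(qprec)
    warm, cold = first_argmax(qtavg), first_argmin(qtavg)
    out["bio8"], out["bio9"] = qtavg[wet], qtavg[dry]
    out["bio10"], out["bio11"] = qtavg[warm], qtavg[cold]
    out["bio12"] = sum(prec)
    out["bio13"], out["bio14"] = max(prec), min(prec)
    mean_p = out["bio12"] / 12.0
    sd_p = (sum((p - mean_p) ** 2 for p in prec) / 12.0) ** 0.5
    out["bio15"] = 100.0 * sd_p / (1.0 + mean_p)
    out["bio16"], out["bio17"] = qprec[wet], qprec[dry]
    out["bio18"], out["bio19"] = qprec[warm], qprec[cold]
    return out


class TestPeriodClimatology:
    def test_single_year_is_identity(self, rng):
        grids = {(2010, m): _grid([[rng.normal()]]) for m in range(1, 13)}
        clim = period_climatology(grids, grids, grids, (2010, 2010))
        for m in range(12):
            assert clim.tmin[m].values[0, 0] == grids[(2010, m + 1)].values[0, 0]

    def test_two_year_mean(self):
        a = {(2010, m): _grid([[10.0]]) for m in range(1, 13)}
        b = {(2011, m): _grid([[20.0]]) for m in range(1, 13)}
        clim = period_climatology({**a, **b}, {**a, **b}, {**a, **b}, (2010, 2011))
        assert all(clim.prec[m].values[0, 0] == 15.0 for m in range(12))

    def test_three_year_stack_matches_direct_mean(self, rng):
        vals = rng.normal(size=(3, 12, 2, 2))
        grids = {
            (2000 + y, m + 1): GeoGrid(vals[y, m], 0.0, 2.0, 1.0, 1.0)
            for y in range(3)
            for m in range(12)
        }
        clim = period_climatology(grids, grids, grids, (2000, 2002))
        for m in range(12):
            np.testing.assert_allclose(clim.tmax[m].values, vals[:, m].mean(axis=0))

    def test_missing_layer_named(self):
        grids = {(2010, m): _grid([[1.0]]) for m in range(1, 12)}  # month 12 absent
        with pytest.raises(GridError, match="month 12"):
            period_climatology(grids, grids, grids, (2010, 2010))


class TestBiovars:
    def test_constant_climate(self):
        clim = make_clim([20.0] * 12, [30.0] * 12, [100.0] * 12)
        bio = compute_biovars(clim)
        expected = {
            "bio5": 30.0, "bio6": 20.0, "bio7": 10.0, "bio12": 1200.0,
            "bio4": 0.0, "bio13": 100.0, "bio14": 100.0,
            "bio16": 300.0, "bio17": 300.0, "bio18": 300.0, "bio19": 300.0,
        }
        for name, val in expected.items():
            assert bio[name].values[0, 0] == pytest.approx(val)

    def test_zero_precipitation(self):
        clim = make_clim(list(range(12)), [t + 5 for t in range(12)], [0.0] * 12)
        bio = compute_biovars(clim)
        assert bio["bio12"].values[0, 0] == 0.0
        assert bio["bio15"].values[0, 0] == 0.0

    def test_seasonal_cell_warmest_quarter(self):
        # temperature peaks months 6-8 (indices 5-7), rain peaks months 1-3
        tavg_peak = [0, 0, 0, 0, 5, 20, 25, 20, 5, 0, 0, 0]
        prec = [90, 95, 80, 10, 5, 5, 2, 2, 5, 10, 20, 50]
        clim = make_clim(tavg_peak, [t + 10 for t in tavg_peak], prec)
        bio = compute_biovars(clim)
        oracle = biovars_cell_oracle(
            tavg_peak, [t + 10 for t in tavg_peak], prec
        )
        assert bio["bio18"].values[0, 0] == pytest.approx(oracle["bio18"])
        assert oracle["bio18"] == sum(prec[5:8])

    def test_tie_earliest_quarter_wins(self):
        # all quarters equally wet: the January-start quarter is reported
        prec = [10.0] * 12
        tavg = list(range(12))
        clim = make_clim(tavg, [t + 8 for t in tavg], prec)
        bio = compute_biovars(clim)
        jan_quarter_tavg = (sum(tavg[:3]) / 3.0) + 4.0  # tavg = tmin + 4
        assert bio["bio8"].values[0, 0] == pytest.approx(jan_quarter_tavg)

    def test_zero_range_cell_gets_nodata_bio3(self):
        clim = make_clim([10.0] * 12, [10.0] * 12, [5.0] * 12)
        with pytest.warns(UserWarning, match="bio3"):
            bio = compute_biovars(clim)
        assert np.isnan(bio["bio3"].values[0, 0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tmin = rng.uniform(-5, 20, 12)
        tmax = tmin + rng.uniform(0.5, 15, 12)
        prec = rng.uniform(0, 400, 12)
        bio = compute_biovars(make_clim(tmin, tmax, prec))
        oracle = biovars_cell_oracle(list(tmin), list(tmax), list(prec))
        for name, val in oracle.items():
            assert bio[name].values[0, 0] == pytest.approx(val, abs=1e-9), name

    def test_structural_invariants_random(self, rng):
        for _ in range(10):
            tmin = rng.uniform(-10, 25, 12)
            tmax = tmin + rng.uniform(0.1, 12, 12)
            prec = rng.uniform(0, 500, 12)
            bio = compute_biovars(make_clim(tmin, tmax, prec))

            def v(name):
                return bio[name].values[0, 0]

            assert v("bio7") >= 0
            assert v("bio5") >= v("bio6")
            assert v("bio13") >= v("bio14")
            assert v("bio16") >= v("bio17")
            assert v("bio12") == pytest.approx(prec.sum())
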