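"""The 19 BIOCLIM variables from monthly climatologies over any year range.

bio1   annual mean temperature                 (mean of monthly tavg)
bio2   mean diurnal range                      (mean of tmax - tmin)
bio3   isothermality                           (100 * bio2 / bio7)
bio4   temperature seasonality                 (100 * sd of monthly tavg)
bio5   max temperature of warmest month
bio6   min temperature of coldest month
bio7   annual temperature range                (bio5 - bio6)
bio8   mean temperature of wettest quarter
bio9   mean temperature of driest quarter
bio10  mean temperature of warmest quarter
bio11  mean temperature of coldest quarter
bio12  annual precipitation
bio13  precipitation of wettest month
bio14  precipitation of driest month
bio15  precipitation seasonality               (100 * sd / (1 + bio12/12))
bio16  precipitation of wettest quarter
bio17  precipitation of driest quarter
bio18  precipitation of warmest quarter
bio19  precipitation of coldest quarter

Quarters are every window of three consecutive calendar months, with
wraparound across the year boundary (Nov-Dec-Jan and Dec-Jan-Feb
included). When two quarters tie, the earliest in January-start order
wins. Standard deviations are population SDs (divide by 12).
Temperatures are degrees C, precipitation mm; no x10 integer scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grids import GeoGrid, GridError, GridStack

__all__ = ["MonthlyClimatology", "period_climatology", "compute_biovars", "BIOVAR_NAMES"]

BIOVAR_NAMES = tuple(f"bio{i}" for i in range(1, 20))


@dataclass
class MonthlyClimatology:
    """Twelve monthly mean grids per variable, averaged over a year range."""

    tmin: Sequence[GeoGrid]
    tmax: Sequence[GeoGrid]
    prec: Sequence[GeoGrid]
    year_range: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        for name, grids in (("tmin", self.tmin), ("tmax", self.tmax), ("prec", self.prec)):
            if len(grids) != 12:
                raise GridError(f"{name} must have 12 monthly layers, got {len(grids)}")
        ref = self.tmin[0]
        for grids in (self.tmin, self.tmax, self.prec):
            for g in grids:
                if not ref.same_geometry(g):
                    raise GridError("climatology layers are not on a common grid")

    @property
    def reference(self) -> GeoGrid:
        return self.tmin[0]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(12, rows, cols) arrays for tmin, tmax, prec."""
        return (
            np.stack([g.values for g in self.tmin]),
            np.stack([g.values for g in self.tmax]),
            np.stack([g.values for g in self.prec]),
        )


def period_climatology(
    tmin: Mapping[tuple[int, int], GeoGrid],
    tmax: Mapping[tuple[int, int], GeoGrid],
    prec: Mapping[tuple[int, int], GeoGrid],
    year_range: tuple[int, int],
) -> MonthlyClimatology:
    """Average per-year monthly grids into a monthly climatology.

    Each mapping is keyed by ``(year, month)``; every year of
    ``year_range`` (inclusive) must supply all 12 months, otherwise an
    error names the missing layer.
    """
    first, last = year_range
    if last < first:
        raise GridError(f"invalid year range {year_range}")
    years = range(first, last + 1)

    def monthly_mean(grids: Mapping[tuple[int, int], GeoGrid], label: str) -> list[GeoGrid]:
        out = []
        for month in range(1, 13):
            stack = []
            for year in years:
                key = (year, month)
                if key not in grids:
                    raise GridError(f"missing {label} layer for year {year}, month {month}")
                stack.append(grids[key].values)
            out.append(grids[(first, month)].with_values(np.mean(stack, axis=0)))
        return out

    return MonthlyClimatology(
        tmin=monthly_mean(tmin, "tmin"),
        tmax=monthly_mean(tmax, "tmax"),
        prec=monthly_mean(prec, "prec"),
        year_range=(first, last),
    )


def _quarter_sums(monthly: np.ndarray) -> np.ndarray:
    """(12, ...) rolling 3-month sums with wraparound, start month first."""
    ext = np.concatenate([monthly, monthly[:2]], axis=0)
    return np.stack([ext[s : s + 3].sum(axis=0) for s in range(12)])


def compute_biovars(clim: MonthlyClimatology) -> GridStack:
    """Compute bio1..bio19 grids from a monthly climatology.

    Cells where the annual temperature range (bio7) is zero have an
    undefined isothermality; bio3 is nodata there and a warning reports
    the count.
    """
    tmin, tmax, prec = clim.arrays()
    tavg = (tmax + tmin) / 2.0

    bio = {}
    bio["bio1"] = tavg.mean(axis=0)
    bio["bio2"] = (tmax - tmin).mean(axis=0)
    bio["bio4"] = 100.0 * tavg.std(axis=0)
    bio["bio5"] = tmax.max(axis=0)
    bio["bio6"] = tmin.min(axis=0)
    bio["bio7"] = bio["bio5"] - bio["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio3 = 100.0 * bio["bio2"] / bio["bio7"]
    degenerate = np.isclose(bio["bio7"], 0.0) & np.isfinite(bio["bio7"])
    if degenerate.any():
        warnings.warn(
            f"bio3 undefined (zero annual temperature range) at {int(degenerate.sum())} cell(s)",
            stacklevel=2,
        )
        bio3 = np.where(degenerate, np.nan, bio3)
    bio["bio3"] = bio3

    bio["bio12"] = prec.sum(axis=0)
    bio["bio13"] = prec.max(axis=0)
    bio["bio14"] = prec.min(axis=0)
    bio["bio15"] = 100.0 * prec.std(axis=0) / (1.0 + bio["bio12"] / 12.0)

    q_prec = _quarter_sums(prec)            # quarter precipitation totals
    q_tavg = _quarter_sums(tavg) / 3.0      # quarter mean temperatures

    # argmax/argmin return the first extreme: earliest January-start quarter wins
    # ties; NaN inputs propagate to NaN outputs through the picked value
    wettest = np.argmax(q_prec, axis=0)
    driest = np.argmin(q_prec, axis=0)
    warmest = np.argmax(q_tavg, axis=0)
    coldest = np.argmin(q_tavg, axis=0)

    def pick(stack: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(stack, idx[None, ...], axis=0)[0]

    bio["bio8"] = pick(q_tavg, wettest)
    bio["bio9"] = pick(q_tavg, driest)
    bio["bio10"] = pick(q_tavg, warmest)
    bio["bio11"] = pick(q_tavg, coldest)
    bio["bio16"] = pick(q_prec, wettest)
    bio["bio17"] = pick(q_prec, driest)
    bio["bio18"] = pick(q_prec, warmest)
    bio["bio19"] = pick(q_prec, coldest)

    ref = clim.reference
    return GridStack({name: ref.with_values(bio[name]) for name in BIOVAR_NAMES})
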