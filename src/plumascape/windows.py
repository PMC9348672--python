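"""Amount-weighted precipitation-d2H compositing and month-window selection.

A tissue like a feather integrates precipitation hydrogen over the
months feeding the food web during growth. The composite for a window
of consecutive months is the precipitation-amount-weighted mean of the
monthly precipitation d2H grids,

    delta_w = sum_m P_m * delta_m / sum_m P_m,   m in window,

and the window scan regresses observed feather d2H on the composite
extracted at the sample sites for every candidate window, keeping the
window with the highest r-squared. Months wrap across the year
boundary. Weights come from the monthly precipitation climatology, the
same one the BIOCLIM stage uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import GeoGrid, GridError, GridStack, extract_at_points

__all__ = ["WindowSpec", "WindowScanResult", "amount_weighted_composite", "scan_windows"]


@dataclass(frozen=True)
class WindowSpec:
    """A contiguous window of calendar months (with wraparound).

    ``WindowSpec(2, 3)`` is February-April, the window selected for
    Brazilian feathers.
    """

    start_month: int
    length: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= 12:
            raise ValueError(f"start_month must be 1-12, got {self.start_month}")
        if not 1 <= self.length <= 12:
            raise ValueError(f"length must be 1-12, got {self.length}")

    @property
    def months(self) -> tuple[int, ...]:
        return tuple((self.start_month - 1 + i) % 12 + 1 for i in range(self.length))

    @property
    def wraps(self) -> bool:
        return self.start_month + self.length - 1 > 12

    def __str__(self) -> str:
        return f"months {self.start_month}..{self.months[-1]} (len {self.length})"


@dataclass
class WindowScanResult:
    """Per-window regression fits plus the winning window.

    ``table`` has one row per candidate window with columns
    start_month, length, r_squared, slope, intercept, n_used.
    ``annual_r2`` is the full-year amount-weighted baseline fit.
    """

    table: pd.DataFrame
    best_window: WindowSpec
    annual_r2: float


def _check_monthly(delta_monthly: Sequence[GeoGrid], prec_monthly: Sequence[GeoGrid]) -> None:
    if len(delta_monthly) != 12 or len(prec_monthly) != 12:
        raise GridError("need 12 monthly delta grids and 12 monthly precipitation grids")
    ref = delta_monthly[0]
    for g in list(delta_monthly) + list(prec_monthly):
        if not ref.same_geometry(g):
            raise GridError("monthly delta/precipitation stacks are misaligned")


def amount_weighted_composite(
    delta_monthly: Sequence[GeoGrid],
    prec_monthly: Sequence[GeoGrid],
    window: WindowSpec,
) -> GeoGrid:
    """Precipitation-amount-weighted mean of monthly d2H over a window.

    Cells whose window precipitation sums to zero (no water to weight
    by) become nodata, as do cells missing in any window month.
    """
    _check_monthly(delta_monthly, prec_monthly)
    num = np.zeros_like(delta_monthly[0].values)
    den = np.zeros_like(num)
    for m in window.months:
        p = prec_monthly[m - 1].values
        d = delta_monthly[m - 1].values
        num = num + p * d
        den = den + p
    with np.errstate(divide="ignore", invalid="ignore"):
        comp = num / den
    comp[den == 0] = np.nan
    return delta_monthly[0].with_values(comp)


def scan_windows(
    samples: pd.DataFrame,
    delta_monthly: Sequence[GeoGrid],
    prec_monthly: Sequence[GeoGrid],
    lengths: Sequence[int] = (3,),
) -> WindowScanResult:
    """Regress feather d2H on the window composite for every candidate window.

    Candidates are all 12 start months crossed with ``lengths``;
    windows covering an identical month set (every start at length 12)
    are evaluated once. The best window maximizes r-squared, ties
    resolved to the earliest start month then the shortest length. The
    full-year amount-weighted baseline is always reported.
    """
    _check_monthly(delta_monthly, prec_monthly)
    candidates: list[WindowSpec] = []
    seen: set[frozenset] = set()
    for length in lengths:
        for start in range(1, 13):
            w = WindowSpec(start, length)
            key = frozenset(w.months)
            if key not in seen:
                seen.add(key)
                candidates.append(w)
    candidates.sort(key=lambda w: (w.start_month, w.length))

    def fit_window(w: WindowSpec) -> dict:
        comp = amount_weighted_composite(delta_monthly, prec_monthly, w)
        matrix = extract_at_points(GridStack({"composite": comp}), samples)
        x = matrix.data["composite"].to_numpy()
        y = matrix.y
        row = {
            "start_month": w.start_month,
            "length": w.length,
            "n_used": int(len(x)),
            "r_squared": np.nan,
            "slope": np.nan,
            "intercept": np.nan,
        }
        if len(x) >= 3 and np.ptp(x) > 0:
            res = stats.linregress(x, y)
            row.update(
                r_squared=float(res.rvalue**2),
                slope=float(res.slope),
                intercept=float(res.intercept),
            )
        return row

    rows = [fit_window(w) for w in candidates]
    table = pd.DataFrame(rows)

    valid = table[np.isfinite(table["r_squared"])]
    if valid.empty:
        raise GridError("no window produced at least 3 usable samples")
    # candidates are already in (start, length) order: first strict max wins
    best_idx = int(valid["r_squared"].idxmax())
    best = WindowSpec(int(table.loc[best_idx, "start_month"]), int(table.loc[best_idx, "length"]))

    annual = fit_window(WindowSpec(1, 12))
    return WindowScanResult(table=table, best_window=best, annual_r2=float(annual["r_squared"]))
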