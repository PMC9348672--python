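"""Assembly of the modelling covariate pool onto one grid stack."""

from __future__ import annotations

from typing import Sequence

from .bioclim import MonthlyClimatology, compute_biovars
from .grids import GeoGrid, GridStack
from .windows import WindowSpec, amount_weighted_composite

__all__ = ["build_covariate_stack"]


def build_covariate_stack(
    clim: MonthlyClimatology,
    d2hp_monthly: Sequence[GeoGrid],
    static: GridStack | None,
    window: WindowSpec,
    include: Sequence[str] | None = None,
) -> GridStack:
    """All candidate covariate layers on the climatology grid.

    Layers: the amount-weighted precipitation-d2H composite for
    ``window`` (named ``d2hp_window``), the 19 BIOCLIM variables, and
    any static layers (solar radiation, wind speed, vapor pressure,
    altitude, ...). ``include`` restricts the result to a named subset.
    """
    stack = GridStack()
    stack.add(
        "d2hp_window",
        amount_weighted_composite(d2hp_monthly, clim.prec, window),
    )
    for name, grid in compute_biovars(clim):
        stack.add(name, grid)
    if static is not None:
        for name, grid in static:
            stack.add(name, grid)
    if include is not None:
        stack = stack.subset(include)
    return stack
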