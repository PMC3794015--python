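"""Temporally continuous paleoclimate interpolation between two end-member
grids, indexed by the isotope-proxy global MAT curve.

Each 4-ky slice is a per-cell, per-variable linear blend of the modern
(interglacial) and full-glacial end-members:

    X_t = alpha * X_modern + (1 - alpha) * X_glacial,
    alpha = (MAT(t) - MAT_glacial) / (MAT_modern - MAT_glacial).

alpha may exceed 1, linearly extrapolating into interglacials warmer than
present (the last interglacial).  Non-analogue climate is detected with
rectilinear MESS scores against a reference grid's per-variable bounds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .grids import ClimateGrid, IsotopeSeries
from .mess import mess_grid_from_bounds


class EmptyReferenceError(ValueError):
    """Reference cell set or vector set is empty."""


def blend_weight(isotope: IsotopeSeries, t_ka: float) -> float:
    """The modern-end-member weight alpha at slice time t."""
    return isotope.alpha(t_ka)


def interpolate_slice(modern: ClimateGrid, glacial: ClimateGrid,
                      isotope: IsotopeSeries, t_ka: float) -> ClimateGrid:
    """Interpolated climate grid at slice time ``t_ka`` (ka BP).

    Raises
    ------
    NoSuchSliceError
        If ``t_ka`` is not exactly one of the series' slice times.
    IncompatibleGridsError
        If the end-members do not share a lattice.
    """
    modern.require_same_lattice(glacial)
    if modern.var_names != glacial.var_names:
        raise ValueError("end-member grids must carry the same variables")
    a = isotope.alpha(t_ka)
    values = a * modern.values + (1.0 - a) * glacial.values
    return replace(modern, values=values, time_ka=float(t_ka))


def interpolate_series(modern: ClimateGrid, glacial: ClimateGrid,
                       isotope: IsotopeSeries) -> list:
    """All slices of the series, oldest last (ordered as ``times_ka``)."""
    return [interpolate_slice(modern, glacial, isotope, t)
            for t in isotope.times_ka]


def reference_bounds(reference: ClimateGrid, variables,
                     cells: np.ndarray | None = None) -> tuple:
    """Per-variable (lower, upper) min-max bounds of a reference grid,
    optionally restricted to a cell subset (e.g. a species' basins)."""
    if cells is not None:
        cells = np.asarray(cells, dtype=int)
        if cells.size == 0:
            raise EmptyReferenceError("empty reference cell set")
    lowers, uppers = [], []
    for v in variables:
        col = reference.var(v)
        if cells is not None:
            col = col[cells]
        if col.size == 0:
            raise EmptyReferenceError("empty reference grid")
        lowers.append(col.min())
        uppers.append(col.max())
    return np.asarray(lowers), np.asarray(uppers)


def nonanalogue_map(paleo: ClimateGrid, reference: ClimateGrid,
                    variables=None) -> np.ndarray:
    """Combined MESS score per cell of ``paleo`` against the reference
    grid's per-variable min-max bounds.

    Cells scoring negative hold non-analogue climate relative to the
    reference period: they fall outside the reference's available climate
    space on at least one variable.
    """
    variables = tuple(variables) if variables is not None else paleo.var_names
    lower, upper = reference_bounds(reference, variables)
    query = paleo.subset(variables).values
    return mess_grid_from_bounds(lower, upper, query, mode="combined")
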