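"""Rectilinear multivariate environmental similarity (MESS) scores and the
SIM5 minimal-refugium selection.

A MESS score locates a point in climate space relative to a rectilinear
reference interval on each variable.  Inside the interval the score runs
from 0 (on a boundary) to +100 (exactly at the interval midpoint):

    score = 100 * (1 - 2*|value - mid| / width).

Outside, it is the distance to the nearest boundary as a (negative)
percentage of the interval width:

    score = -100 * dist(value, nearest bound) / width,

so a point lying one full interval-width beyond a boundary scores exactly
-100.  The combined multivariate score is the minimum across variables:
one incompatible variable makes the climate non-analogue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import BIOCLIM_VARS


class DegenerateReferenceError(ValueError):
    """Zero-width reference interval queried off its single point."""


class MissingReferenceError(KeyError):
    """A query variable has no reference interval."""


@dataclass
class MessResult:
    """Per-variable and combined MESS scores for one query vector."""

    var_names: tuple
    scores: np.ndarray           # per-variable, same order as var_names
    combined: float              # minimum across variables
    limiting_variable: str       # arg-min, ties broken by canonical order
    reference: str = ""          # free-text description of the reference

    def score(self, name: str) -> float:
        return float(self.scores[self.var_names.index(name)])


def _canonical_rank(name: str) -> int:
    try:
        return BIOCLIM_VARS.index(name)
    except ValueError:
        return len(BIOCLIM_VARS)


def mess_univariate(ref_lower: float, ref_upper: float, value: float) -> float:
    """Score of a single value against one reference interval."""
    if ref_lower > ref_upper:
        raise ValueError("ref_lower must be <= ref_upper")
    width = ref_upper - ref_lower
    if width == 0.0:
        if value == ref_lower:
            return 0.0
        raise DegenerateReferenceError(
            "zero-width reference interval with off-point query")
    if ref_lower <= value <= ref_upper:
        mid = 0.5 * (ref_lower + ref_upper)
        return 100.0 * (1.0 - 2.0 * abs(value - mid) / width)
    dist = (ref_lower - value) if value < ref_lower else (value - ref_upper)
    return -100.0 * dist / width


def _mess_columns(lower: np.ndarray, upper: np.ndarray,
                  values: np.ndarray) -> np.ndarray:
    """Vectorized per-variable scores; values is (n, d)."""
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    values = np.atleast_2d(np.asarray(values, float))
    width = upper - lower
    if np.any(width == 0):
        # fall back to the scalar path for exactness of its error contract
        out = np.empty_like(values)
        for j in range(values.shape[1]):
            for i in range(values.shape[0]):
                out[i, j] = mess_univariate(lower[j], upper[j], values[i, j])
        return out
    mid = 0.5 * (lower + upper)
    inside = (values >= lower) & (values <= upper)
    s_in = 100.0 * (1.0 - 2.0 * np.abs(values - mid) / width)
    dist = np.where(values < lower, lower - values, values - upper)
    s_out = -100.0 * dist / width
    return np.where(inside, s_in, s_out)


def mess_combined(bounds: dict, vector: dict, reference: str = "") -> MessResult:
    """Multivariate score of one query vector.

    Parameters
    ----------
    bounds : mapping variable -> (lower, upper)
    vector : mapping variable -> value; every variable must have bounds.
    """
    names = sorted(vector, key=_canonical_rank)
    missing = [v for v in names if v not in bounds]
    if missing:
        raise MissingReferenceError(f"no reference interval for {missing}")
    scores = np.array([mess_univariate(bounds[v][0], bounds[v][1], vector[v])
                       for v in names])
    k = int(np.argmin(scores))  # first minimum == canonical-order tie-break
    return MessResult(var_names=tuple(names), scores=scores,
                      combined=float(scores[k]), limiting_variable=names[k],
                      reference=reference)


def mess_grid_from_bounds(lower: np.ndarray, upper: np.ndarray,
                          values: np.ndarray, mode: str = "combined"):
    """Scores for many query vectors against explicit per-variable bounds.

    Returns a (n,) combined array, or the full (n, d) per-variable array.
    """
    per_var = _mess_columns(lower, upper, values)
    if mode == "combined":
        return per_var.min(axis=1)
    if mode == "per-variable":
        return per_var
    raise ValueError("mode must be 'combined' or 'per-variable'")


def mess_grid(reference, grid, mode: str = "combined",
              variables=None, reference_cells=None):
    """Score every cell of ``grid`` against a reference.

    ``reference`` is either a niche envelope (per-variable bounds, map kind
    (a): position relative to a species' potential niche) or a
    :class:`~paleoniche.grids.ClimateGrid` whose min-max bounds over
    ``reference_cells`` define available climate space (map kind (b)).
    """
    from .grids import ClimateGrid
    from .niche import NicheEnvelope

    if isinstance(reference, NicheEnvelope):
        variables = tuple(variables) if variables else reference.var_names
        lower = np.array([reference.bound(v)[0] for v in variables])
        upper = np.array([reference.bound(v)[1] for v in variables])
    elif isinstance(reference, ClimateGrid):
        from .climate import reference_bounds
        variables = tuple(variables) if variables else grid.var_names
        lower, upper = reference_bounds(reference, variables,
                                        cells=reference_cells)
    else:
        raise TypeError("reference must be a NicheEnvelope or ClimateGrid")
    return mess_grid_from_bounds(lower, upper,
                                 grid.subset(variables).values, mode=mode)


def sim5(scores: np.ndarray, cells: np.ndarray | None = None, k: int = 5):
    """The k accessible cells with the least-negative combined MESS scores.

    Used as a minimal hypothesized refugium when a projected range is
    empty: the species is arbitrarily assigned the k equal-area cells whose
    climate is closest to its potential niche.  Ties at the cutoff are
    broken by ascending cell id; the result is deterministic.

    Parameters
    ----------
    scores : per-cell combined MESS scores over the accessible cells.
    cells : cell ids aligned with ``scores`` (default 0..n-1).

    Returns
    -------
    ndarray of selected cell ids, sorted ascending, with
    ``len == min(k, n accessible)``.
    """
    scores = np.asarray(scores, dtype=float)
    cells = (np.arange(scores.size) if cells is None
             else np.asarray(cells, dtype=int))
    if cells.size != scores.size:
        raise ValueError("scores and cell ids must align")
    if scores.size <= k:
        if scores.size < k:
            import warnings
            warnings.warn(f"fewer than {k} accessible cells; returning all")
        return np.sort(cells)
    # sort by (-score, cell id): best scores first, low ids first on ties
    order = np.lexsort((cells, -scores))
    return np.sort(cells[order[:k]])
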