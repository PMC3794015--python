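"""Occurrence preparation and rectilinear (BIOCLIM) niche envelopes.

A potential niche is estimated as a rectilinear envelope around a species'
occurrence points in climate space: independent per-variable bounds, either
the full data range (trim 0) or a 90% envelope that drops the outlying 10%
of points per variable (5th/95th percentiles).  Rectilinear envelopes
depend only on the per-variable marginals, so they are unbiased by
correlations between climate variables — which need not be the same in the
past as today.  Realized-niche membership is the stricter test: a point
must lie inside the convex hull of the occurrence vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .grids import ClimateGrid


class CannotFitError(ValueError):
    """Envelope requested on an empty vector set."""


class OutOfDomainError(ValueError):
    """One or more points fall outside the grid's cell lattice."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"points outside grid domain at indices {self.indices}")


@dataclass
class OccurrenceSet:
    """Thinned occurrence points for one species, with extracted climate."""

    species: str
    points: np.ndarray                      # (n, 2) projected km
    thinning_resolution: float | None = None
    climate: pd.DataFrame | None = None     # per-point bioclim vectors

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class NicheEnvelope:
    """Per-variable [lower, upper] bounds in climate space."""

    var_names: tuple
    lower: np.ndarray
    upper: np.ndarray
    trim_fraction: float = 0.0
    provenance: str = "modern-tip"

    def __post_init__(self):
        self.var_names = tuple(self.var_names)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("envelope lower bound exceeds upper bound")

    def bound(self, name: str) -> tuple:
        i = self.var_names.index(name)
        return (float(self.lower[i]), float(self.upper[i]))

    def bounds_dict(self) -> dict:
        return {v: (float(self.lower[i]), float(self.upper[i]))
                for i, v in enumerate(self.var_names)}

    def contains(self, vector, atol: float = 0.0) -> bool | np.ndarray:
        """Membership test: inside on *every* variable.

        ``vector`` may be a mapping, a 1-D array aligned with
        ``var_names``, or a 2-D (n, d) array (returns a boolean array).
        """
        if isinstance(vector, dict):
            vector = np.array([vector[v] for v in self.var_names])
        v = np.asarray(vector, dtype=float)
        ok = (v >= self.lower - atol) & (v <= self.upper + atol)
        return ok.all(axis=-1)

    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# trim_fraction={self.trim_fraction}\n")
            fh.write(f"# provenance={self.provenance}\n")
            pd.DataFrame({"variable": list(self.var_names),
                          "lower": self.lower,
                          "upper": self.upper}).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "NicheEnvelope":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if line.startswith("#"):
                body_start += 1
                k, _, v = line.lstrip("# ").strip().partition("=")
                meta[k] = v
            else:
                break
        from io import StringIO
        df = pd.read_csv(StringIO("".join(lines[body_start:])))
        return cls(var_names=tuple(df["variable"]),
                   lower=df["lower"].to_numpy(),
                   upper=df["upper"].to_numpy(),
                   trim_fraction=float(meta.get("trim_fraction", 0.0)),
                   provenance=meta.get("provenance", "modern-tip"))


def thin_occurrences(points, resolution: float,
                     species: str = "") -> OccurrenceSet:
    """Spatially thin points to at most one per ``resolution`` grid cell.

    Retention is deterministic: the first point in input order wins within
    each thinning cell.  Mirrors resampling raw records on a coarse grid to
    remove uneven sampling effort.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        warnings.warn(f"no occurrence points to thin for {species!r}")
        return OccurrenceSet(species=species,
                             points=np.empty((0, 2)),
                             thinning_resolution=resolution)
    cells = np.floor(pts / resolution).astype(int)
    seen = set()
    keep = []
    for i, key in enumerate(map(tuple, cells)):
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return OccurrenceSet(species=species, points=pts[keep],
                         thinning_resolution=resolution)


def extract_climate(points, grid: ClimateGrid) -> pd.DataFrame:
    """Climate vector of the cell containing each point.

    Cells are squares around the stored centers; the half-open convention
    is left/bottom inclusive, so a point exactly on a shared edge belongs
    to the cell on its right/top side's left/bottom neighbour.  Points
    outside the lattice raise :class:`OutOfDomainError` listing them.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = cell_index(pts, grid)
    bad = np.flatnonzero(idx < 0)
    if bad.size:
        raise OutOfDomainError(bad)
    df = pd.DataFrame(grid.values[idx], columns=list(grid.var_names))
    df.insert(0, "cell_id", idx)
    return df


def cell_index(points, grid: ClimateGrid) -> np.ndarray:
    """Containing-cell id per point; -1 where outside the domain."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if grid.n_rows is None or grid.n_cols is None:
        # irregular cell list: nearest center, no outside detection beyond
        # half the max nearest-neighbour spacing is attempted
        from scipy.spatial import cKDTree
        tree = cKDTree(np.column_stack([grid.x, grid.y]))
        _, idx = tree.query(pts)
        return idx.astype(int)
    dx = float(np.sqrt(grid.cell_area))
    x0, y0 = grid.x.min(), grid.y.min()
    col = np.floor((pts[:, 0] - (x0 - dx / 2)) / dx).astype(int)
    row = np.floor((pts[:, 1] - (y0 - dx / 2)) / dx).astype(int)
    ok = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    idx = row * grid.n_cols + col
    return np.where(ok, idx, -1)


def fit_envelope(vectors, variables=None, trim_fraction: float = 0.0,
                 provenance: str = "modern-tip") -> NicheEnvelope:
    """Rectilinear envelope around occurrence vectors in climate space.

    trim 0 keeps the full per-variable data range (min/max); trim 0.10
    uses the 5th/95th percentiles (linear-interpolation convention),
    excluding the outlying 10% of points on each variable.
    """
    if trim_fraction not in (0.0, 0.10):
        raise ValueError("trim_fraction must be 0 or 0.10")
    if isinstance(vectors, pd.DataFrame):
        variables = tuple(variables) if variables else tuple(
            c for c in vectors.columns if c.startswith("BIO"))
        data = vectors[list(variables)].to_numpy(dtype=float)
    else:
        data = np.atleast_2d(np.asarray(vectors, dtype=float))
        if variables is None:
            raise ValueError("variables required with array input")
        variables = tuple(variables)
    if data.shape[0] == 0:
        raise CannotFitError("cannot fit an envelope to zero vectors")
    if trim_fraction == 0.10 and data.shape[0] < 10:
        warnings.warn("fewer than 10 vectors: 10% trim poorly defined, "
                      "falling back to min/max bounds")
        trim_fraction = 0.0
        provenance = provenance + " (trim fallback: min/max)"
    if trim_fraction == 0.0:
        lower, upper = data.min(axis=0), data.max(axis=0)
    else:
        lower = np.percentile(data, 5, axis=0)
        upper = np.percentile(data, 95, axis=0)
    return NicheEnvelope(var_names=variables, lower=lower, upper=upper,
                         trim_fraction=trim_fraction, provenance=provenance)


def realized_membership(reference_vectors, query, tol: float = 1e-9) -> bool:
    """Convex-hull membership of ``query`` among the reference vectors.

    True iff the query can be written as a convex combination of the
    reference vectors (linear-programming feasibility with tolerance
    ``tol`` on the constraint residuals).  Strictly tighter than the
    rectilinear envelope fitted on the same vectors.  Degenerate reference
    sets (fewer than d+1 points, or affinely dependent ones that the LP
    still resolves) fall back to bounding-box membership with a warning.
    """
    refs = np.atleast_2d(np.asarray(reference_vectors, dtype=float))
    if isinstance(query, dict):
        raise TypeError("pass query as an array aligned with the references")
    q = np.asarray(query, dtype=float).ravel()
    n, d = refs.shape
    if n < d + 1:
        warnings.warn("degenerate reference set (n <= dim): falling back to "
                      "bounding-box membership")
        return bool(np.all(q >= refs.min(axis=0) - tol)
                    & np.all(q <= refs.max(axis=0) + tol))
    # scale columns to unit width for a well-conditioned LP
    scale = np.ptp(refs, axis=0)
    scale[scale == 0] = 1.0
    A_eq = np.vstack([refs.T / scale[:, None], np.ones(n)])
    b_eq = np.concatenate([q / scale, [1.0]])
    res = linprog(c=np.zeros(n), A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * n, method="highs")
    if res.status == 2:      # infeasible
        return False
    if not res.success:
        warnings.warn("LP solver did not converge; using bounding box")
        return bool(np.all(q >= refs.min(axis=0) - tol)
                    & np.all(q <= refs.max(axis=0) + tol))
    resid = np.abs(A_eq @ res.x - b_eq).max()
    return bool(resid <= max(tol, 1e-7))


def read_occurrences_csv(path) -> pd.DataFrame:
    """Occurrence table with columns species and x,y (projected km) or
    lon,lat (renamed to x,y unchanged; projection is the caller's job)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        xc, yc = cols["x"], cols["y"]
    elif "lon" in cols and "lat" in cols:
        xc, yc = cols["lon"], cols["lat"]
    else:
        raise ValueError("need x/y or lon/lat columns")
    out = df.rename(columns={cols["species"]: "species", xc: "x", yc: "y"})
    return out[["species", "x", "y"]]
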