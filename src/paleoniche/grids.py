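"""Core spatial containers: bioclimatic grids, the isotope proxy series, and
watershed (drainage-basin) membership maps.

All grids live on a single equal-area lattice of square cells.  Cell centers
are in projected kilometres; every cell has the same area (default 50 km^2,
the resolution that avoids latitudinal bias on an equal-area projection).
Temperature variables are plain degrees Celsius, precipitation in mm; any
x10 integer-encoded input (the WorldClim convention) must be converted at
the reader boundary before constructing a :class:`ClimateGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The 19 standard bioclimatic variables, in canonical order.
BIOCLIM_VARS = tuple(f"BIO{i}" for i in range(1, 20))

#: Temperature-type variables (degrees C); the rest are precipitation (mm),
#: except BIO3 (ratio, %) and BIO4 (seasonality) which behave like
#: temperature under a uniform-offset glacial perturbation only through BIO1.
TEMPERATURE_VARS = ("BIO1", "BIO2", "BIO4", "BIO5", "BIO6", "BIO7",
                    "BIO8", "BIO9", "BIO10", "BIO11")

#: Default subset of moderately uncorrelated variables used for niche
#: modeling: diurnal range, warm-month maximum, wettest/warmest quarter
#: temperatures, and four quarterly precipitation totals.  (The warm-month
#: extreme is exposed here under its conventional BIO5 coding; see
#: docs/methods.md for the naming caveat.)
MODELING_VARS = ("BIO2", "BIO5", "BIO8", "BIO10",
                 "BIO16", "BIO17", "BIO18", "BIO19")


class IncompatibleGridsError(ValueError):
    """Two grids do not share the same cell lattice."""


class NoSuchSliceError(KeyError):
    """Requested time is not one of the series' slice times."""


@dataclass
class ClimateGrid:
    """An equal-area lattice carrying one bioclimatic vector per cell.

    Parameters
    ----------
    var_names : tuple of str
        Variable names, e.g. ``("BIO1", ..., "BIO19")`` or a subset.
    values : ndarray, shape (n_cells, n_vars)
        Per-cell variable values.
    x, y : ndarray, shape (n_cells,)
        Cell-center coordinates in projected km.
    cell_area : float
        Area of every cell in km^2 (uniform; default 50).
    time_ka : float or None
        Age of the slice in ka BP; ``None`` for timeless grids.
    n_rows, n_cols : int or None
        Lattice shape when the grid is a full rectangle (synthetic grids
        always are); kept for reshaping into images.
    """

    var_names: tuple
    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cell_area: float = 50.0
    time_ka: float | None = None
    n_rows: int | None = None
    n_cols: int | None = None

    def __post_init__(self):
        self.var_names = tuple(self.var_names)
        self.values = np.asarray(self.values, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.x.size:
            raise ValueError("values must be (n_cells, n_vars) aligned with x/y")
        if self.values.shape[1] != len(self.var_names):
            raise ValueError("values second dimension must match var_names")
        if np.isnan(self.values).any():
            raise ValueError("missing values inside the modeled domain")
        if "BIO5" in self.var_names and "BIO6" in self.var_names:
            b5 = self.var("BIO5")
            b6 = self.var("BIO6")
            if np.any(b5 < b6 - 1e-9):
                raise ValueError("BIO5 (warm-month max) must be >= BIO6 "
                                 "(cold-month min) in every cell")

    @property
    def n_cells(self) -> int:
        return self.x.size

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def var_index(self, name: str) -> int:
        try:
            return self.var_names.index(name)
        except ValueError:
            raise KeyError(f"variable {name!r} not in grid") from None

    def var(self, name: str) -> np.ndarray:
        """Values of a single variable over all cells."""
        return self.values[:, self.var_index(name)]

    def subset(self, variables) -> "ClimateGrid":
        """A view of the grid restricted to ``variables`` (order preserved)."""
        idx = [self.var_index(v) for v in variables]
        return replace(self, var_names=tuple(variables),
                       values=self.values[:, idx])

    def same_lattice(self, other: "ClimateGrid") -> bool:
        return (self.n_cells == other.n_cells
                and np.array_equal(self.x, other.x)
                and np.array_equal(self.y, other.y)
                and self.cell_area == other.cell_area)

    def require_same_lattice(self, other: "ClimateGrid") -> None:
        if not self.same_lattice(other):
            raise IncompatibleGridsError("grids do not share a cell lattice")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.var_names))
        df.insert(0, "cell_id", self.cell_ids)
        df.insert(1, "x", self.x)
        df.insert(2, "y", self.y)
        return df

    # --- I/O -------------------------------------------------------------

    def to_netcdf(self, path) -> None:
        """Write as a NetCDF3 stack (one data variable per bioclim variable)."""
        import xarray as xr

        ds = xr.Dataset(
            {v: ("cell", self.var(v)) for v in self.var_names},
            coords={"cell": self.cell_ids, "x": ("cell", self.x),
                    "y": ("cell", self.y)},
            attrs={"cell_area_km2": self.cell_area,
                   "time_ka": -999.0 if self.time_ka is None else self.time_ka,
                   "n_rows": -1 if self.n_rows is None else self.n_rows,
                   "n_cols": -1 if self.n_cols is None else self.n_cols},
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "ClimateGrid":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            ds.load()
        var_names = tuple(ds.data_vars)
        values = np.column_stack([ds[v].values for v in var_names])
        t = float(ds.attrs["time_ka"])
        nr = int(ds.attrs.get("n_rows", -1))
        nc = int(ds.attrs.get("n_cols", -1))
        return cls(var_names=var_names, values=values,
                   x=ds["x"].values, y=ds["y"].values,
                   cell_area=float(ds.attrs["cell_area_km2"]),
                   time_ka=None if t == -999.0 else t,
                   n_rows=None if nr < 0 else nr,
                   n_cols=None if nc < 0 else nc)


@dataclass
class IsotopeSeries:
    """Global mean-annual-temperature proxy at uniform time steps.

    Emulates a deep-sea-core oxygen-isotope curve rescaled to degrees C,
    anchored at a modern (interglacial) and a glacial end-member MAT.
    """

    times_ka: np.ndarray
    mat_c: np.ndarray
    mat_modern: float
    mat_glacial: float

    def __post_init__(self):
        self.times_ka = np.asarray(self.times_ka, dtype=float)
        self.mat_c = np.asarray(self.mat_c, dtype=float)
        if self.times_ka.size != self.mat_c.size:
            raise ValueError("times and MAT values must align")
        d = np.diff(self.times_ka)
        if self.times_ka.size >= 2 and not (np.all(d > 0)
                                            and np.allclose(d, d[0])):
            raise ValueError("slice times must be strictly increasing with "
                             "uniform step")
        if not self.mat_modern > self.mat_glacial:
            raise ValueError("mat_modern must exceed mat_glacial")

    @property
    def n_slices(self) -> int:
        return self.times_ka.size

    @property
    def step_ky(self) -> float:
        return float(self.times_ka[1] - self.times_ka[0])

    def slice_index(self, t_ka: float) -> int:
        """Index of an exact slice time.  No nearest-slice snapping."""
        hits = np.flatnonzero(np.isclose(self.times_ka, t_ka, atol=1e-9))
        if hits.size == 0:
            raise NoSuchSliceError(f"{t_ka} ka is not a slice time")
        return int(hits[0])

    def mat_at(self, t_ka: float) -> float:
        return float(self.mat_c[self.slice_index(t_ka)])

    def alpha(self, t_ka: float) -> float:
        """Blend weight toward the modern end-member at time t.

        alpha = (MAT(t) - MAT_glacial) / (MAT_modern - MAT_glacial);
        1 at modern conditions, 0 at full-glacial, and may exceed 1 during
        interglacials warmer than present.
        """
        return ((self.mat_at(t_ka) - self.mat_glacial)
                / (self.mat_modern - self.mat_glacial))

    def bracketing_slices(self, age_ka: float) -> tuple:
        """Slice times bracketing an arbitrary age (helper; projection code
        itself only accepts exact slice times)."""
        t = self.times_ka
        if age_ka < t[0] or age_ka > t[-1]:
            raise NoSuchSliceError(f"{age_ka} ka outside modeled window")
        i = int(np.searchsorted(t, age_ka))
        if np.isclose(t[min(i, t.size - 1)], age_ka) or i == 0:
            j = min(i, t.size - 1)
            return (float(t[j]), float(t[j]))
        return (float(t[i - 1]), float(t[i]))

    def window_slices(self, age_min_ka: float, age_max_ka: float) -> np.ndarray:
        """All slice times inside [age_min, age_max] (inclusive); if the
        window falls between slices, the bracketing pair."""
        if age_min_ka > age_max_ka:
            raise ValueError("age_min must be <= age_max")
        if age_max_ka < self.times_ka[0] or age_min_ka > self.times_ka[-1]:
            raise NoSuchSliceError("age window outside the modeled slices")
        m = ((self.times_ka >= age_min_ka - 1e-9)
             & (self.times_ka <= age_max_ka + 1e-9))
        if m.any():
            return self.times_ka[m].copy()
        lo, hi = self.bracketing_slices(age_min_ka)
        return np.array([lo, hi]) if lo != hi else np.array([lo])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ka": self.times_ka, "mat_c": self.mat_c}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, mat_modern=None, mat_glacial=None) -> "IsotopeSeries":
        df = pd.read_csv(path)
        mat = df["mat_c"].to_numpy()
        return cls(times_ka=df["time_ka"].to_numpy(), mat_c=mat,
                   mat_modern=float(mat[0]) if mat_modern is None else mat_modern,
                   mat_glacial=float(mat.min()) if mat_glacial is None else mat_glacial)


@dataclass
class WatershedMap:
    """Per-cell nested drainage-basin labels (Pfafstetter-style levels).

    Level-2 basins must nest inside exactly one Level-1 basin; Level-1
    basins act as dispersal-accessibility masks, Level-2 basins define the
    available climate space for model training and reference bounds.
    """

    level1: np.ndarray
    level2: np.ndarray

    def __post_init__(self):
        self.level1 = np.asarray(self.level1, dtype=int)
        self.level2 = np.asarray(self.level2, dtype=int)
        if self.level1.shape != self.level2.shape:
            raise ValueError("level1/level2 labels must align")
        df = pd.DataFrame({"l1": self.level1, "l2": self.level2})
        bad = df.groupby("l2")["l1"].nunique()
        if (bad > 1).any():
            raise ValueError("a Level-2 basin spans multiple Level-1 basins")

    @property
    def n_cells(self) -> int:
        return self.level1.size

    def labels(self, level: int) -> np.ndarray:
        if level == 1:
            return self.level1
        if level == 2:
            return self.level2
        raise ValueError("level must be 1 or 2")

    def basin_cells(self, level: int, basin_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels(level) == basin_id)

    def to_csv(self, path) -> None:
        pd.DataFrame({"cell_id": np.arange(self.n_cells),
                      "level1": self.level1,
                      "level2": self.level2}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WatershedMap":
        df = pd.read_csv(path).sort_values("cell_id")
        return cls(level1=df["level1"].to_numpy(),
                   level2=df["level2"].to_numpy())
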