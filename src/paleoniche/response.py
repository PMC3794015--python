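"""Range-response rates: pairwise changes in temperature, range area and
range centroid, regression of geographic response on temperature change,
and partitioning into climate-tracking vs adaptive (phylogenetic)
components.

For each species and slice pair, three changes are recorded: PC_MAT, the
change in mean annual temperature (degrees C, by default the range-local
mean BIO1 over the species' accessibility mask); PC_RS, the signed change
in range area (km^2); and PC_GC, the displacement of the range centroid
(km, non-negative).  Subtracting the uncorrected from the corrected record
field-wise isolates the phylogenetic (adaptive) component; its residual —
the uncorrected record itself — is the purely geographic, climate-tracking
component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedFitError(ValueError):
    """Regression undefined (too few records or zero predictor variance)."""


class AlignmentError(ValueError):
    """Corrected and uncorrected records do not align on species/slices."""


@dataclass
class RegressionFit:
    """Ordinary-least-squares summary for a response-vs-PC_MAT fit."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self):
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("R^2 out of [0, 1]")

    def equation(self, response: str = "y") -> str:
        return (f"{response} = {self.intercept:.2f} + "
                f"{self.slope:.2f}*PC_MAT  (R^2 = {self.r_squared:.3f}, "
                f"p = {self.p_value:.3g}, n = {self.n})")


def pairwise_changes(series, mat_per_slice, mode: str = "consecutive",
                     component: str = "uncorrected") -> pd.DataFrame:
    """Change records from one species' slice series.

    Parameters
    ----------
    series : list of RangeProjection, one per slice (aligned with
        ``mat_per_slice``).
    mat_per_slice : MAT (degrees C) per slice.
    mode : ``"consecutive"`` (adjacent slices) or ``"all-pairs"``
        (every unordered slice pair).

    Empty slices contribute area 0 and no centroid; records whose PC_GC is
    undefined carry NaN there and a ``gc_defined=False`` flag, and are
    excluded from centroid regressions.
    """
    mat = np.asarray(mat_per_slice, dtype=float)
    if len(series) != mat.size:
        raise ValueError("series and MAT list must align on slices")
    if mode == "consecutive":
        pairs = [(i, i + 1) for i in range(len(series) - 1)]
    elif mode == "all-pairs":
        pairs = [(i, j) for i in range(len(series))
                 for j in range(i + 1, len(series))]
    else:
        raise ValueError("mode must be 'consecutive' or 'all-pairs'")
    rows = []
    for i, j in pairs:
        a, b = series[i], series[j]
        gc_ok = a.centroid is not None and b.centroid is not None
        if gc_ok:
            dx = b.centroid[0] - a.centroid[0]
            dy = b.centroid[1] - a.centroid[1]
            pc_gc = float(np.hypot(dx, dy))
        else:
            pc_gc = np.nan
        rows.append({
            "species": a.species, "t1_ka": a.time_ka, "t2_ka": b.time_ka,
            "pc_mat": float(mat[j] - mat[i]),
            "pc_rs": b.area_km2 - a.area_km2,
            "pc_gc": pc_gc, "gc_defined": gc_ok,
            "component": component})
    return pd.DataFrame(rows)


def fit_response(records: pd.DataFrame, response: str = "pc_rs",
                 signed: bool = False) -> RegressionFit:
    """OLS of a geographic response on temperature change.

    By default both sides enter as magnitudes (|response| on |PC_MAT|):
    the response rate per degree of warming *or* cooling.  ``signed=True``
    regresses the raw signed changes instead.
    """
    if response not in ("pc_rs", "pc_gc"):
        raise ValueError("response must be 'pc_rs' or 'pc_gc'")
    df = records
    if response == "pc_gc":
        df = df[df["gc_defined"]]
    df = df.dropna(subset=["pc_mat", response])
    if len(df) < 3:
        raise UndefinedFitError("need >= 3 usable records")
    x = df["pc_mat"].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    if not signed:
        x, y = np.abs(x), np.abs(y)
    if np.ptp(x) == 0.0:
        raise UndefinedFitError("zero variance in PC_MAT")
    if np.ptp(y) == 0.0:
        # constant response: flat line fits exactly but explains nothing
        return RegressionFit(slope=0.0, intercept=float(y[0]),
                             r_squared=0.0, p_value=1.0, n=len(df))
    fit = stats.linregress(x, y)
    return RegressionFit(slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue ** 2),
                         p_value=float(fit.pvalue), n=len(df))


def partition(corrected: pd.DataFrame,
              uncorrected: pd.DataFrame) -> pd.DataFrame:
    """Phylogenetic (adaptive) component records: corrected - uncorrected.

    PC_RS and PC_GC are differenced field-wise per (species, slice pair);
    PC_MAT is shared between the two and carried through unchanged.
    """
    keys = ["species", "t1_ka", "t2_ka"]
    c = corrected.set_index(keys)
    u = uncorrected.set_index(keys)
    missing = c.index.symmetric_difference(u.index)
    if len(missing):
        raise AlignmentError(f"records misaligned on {list(missing)[:10]}")
    u = u.loc[c.index]
    if not np.allclose(c["pc_mat"], u["pc_mat"], equal_nan=True):
        raise AlignmentError("PC_MAT differs between corrected and "
                             "uncorrected records")
    out = pd.DataFrame({
        "pc_mat": c["pc_mat"],
        "pc_rs": c["pc_rs"] - u["pc_rs"],
        "pc_gc": c["pc_gc"] - u["pc_gc"],
        "gc_defined": c["gc_defined"] & u["gc_defined"],
    }, index=c.index).reset_index()
    out["component"] = "phylogenetic"
    return out


def density_histogram(records: pd.DataFrame, response: str = "pc_rs",
                      bins: int = 50) -> pd.DataFrame:
    """2-D histogram counts of (|PC_MAT|, |response|) for density-style
    panels; tidy long format (x_mid, y_mid, count)."""
    df = records.dropna(subset=["pc_mat", response])
    H, xe, ye = np.histogram2d(np.abs(df["pc_mat"]), np.abs(df[response]),
                               bins=bins)
    xm = 0.5 * (xe[:-1] + xe[1:])
    ym = 0.5 * (ye[:-1] + ye[1:])
    xx, yy = np.meshgrid(xm, ym, indexing="ij")
    return pd.DataFrame({"x_mid": xx.ravel(), "y_mid": yy.ravel(),
                         "count": H.ravel().astype(int)})
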