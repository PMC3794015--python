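"""Range hindcasting: project niche envelopes onto interpolated climate
slices under watershed accessibility masks.

For every species and 4-ky slice two ranges are built: the *corrected*
range from the time-adjusted (Brownian-reconstructed) envelope, and the
*uncorrected* range from the fixed modern envelope.  Ranges are masked to
the Level-1 drainage basins containing the species' modern occurrences —
climate beyond those basins is treated as geographically inaccessible.
Corrected slices that contract to nothing receive a SIM5 substitute range
(the five accessible cells with least-negative MESS) recorded as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ClimateGrid, WatershedMap
from .mess import mess_grid_from_bounds, sim5
from .niche import NicheEnvelope, OccurrenceSet, cell_index


class InvalidMaskError(ValueError):
    """Empty accessibility mask."""


class UnassignedPointError(ValueError):
    """An occurrence point falls outside every basin."""


@dataclass
class RangeProjection:
    """One species' presence mask at one time slice."""

    species: str
    time_ka: float
    presence: np.ndarray          # sorted cell ids
    cell_area: float
    centroid: tuple | None        # (x, y) km, None when empty
    empty: bool                   # empty before any SIM5 substitution
    sim5_substituted: bool = False
    provenance: str = "uncorrected"
    n_fragments: int = 0

    @property
    def area_km2(self) -> float:
        return float(self.presence.size * self.cell_area)


def accessible_mask(occurrences: OccurrenceSet | np.ndarray,
                    watersheds: WatershedMap, grid: ClimateGrid,
                    level: int = 1) -> np.ndarray:
    """Cells of every basin (at the requested level) holding >= 1
    occurrence point."""
    if isinstance(occurrences, OccurrenceSet):
        pts = occurrences.points
    else:
        pts = np.atleast_2d(np.asarray(occurrences, dtype=float))
    if pts.shape[0] == 0:
        raise InvalidMaskError("no occurrences to build a mask from")
    idx = cell_index(pts, grid)
    if np.any(idx < 0):
        raise UnassignedPointError(
            f"occurrences outside every basin at rows "
            f"{np.flatnonzero(idx < 0).tolist()}")
    labels = watersheds.labels(level)
    basins = np.unique(labels[idx])
    return np.flatnonzero(np.isin(labels, basins))


def count_fragments(cells: np.ndarray, grid: ClimateGrid) -> int:
    """Connected components of a presence mask under 4-connectivity."""
    if cells.size == 0 or grid.n_rows is None:
        return 0 if cells.size == 0 else 1
    from scipy.ndimage import label
    img = np.zeros(grid.n_rows * grid.n_cols, dtype=bool)
    img[cells] = True
    n = label(img.reshape(grid.n_rows, grid.n_cols),
              structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))[1]
    return int(n)


def project_slice(envelope: NicheEnvelope, climate: ClimateGrid,
                  mask: np.ndarray, species: str = "",
                  provenance: str = "uncorrected",
                  with_fragments: bool = False) -> RangeProjection:
    """Presence = cells in the mask whose climate lies inside the envelope."""
    mask = np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise InvalidMaskError("empty accessibility mask")
    sub = climate.subset(envelope.var_names).values[mask]
    inside = envelope.contains(sub)
    presence = np.sort(mask[inside])
    if presence.size:
        centroid = (float(climate.x[presence].mean()),
                    float(climate.y[presence].mean()))
    else:
        centroid = None
    return RangeProjection(
        species=species,
        time_ka=float(climate.time_ka if climate.time_ka is not None else 0.0),
        presence=presence, cell_area=climate.cell_area, centroid=centroid,
        empty=presence.size == 0, provenance=provenance,
        n_fragments=count_fragments(presence, climate) if with_fragments else 0)


def _sim5_substitute(proj: RangeProjection, envelope: NicheEnvelope,
                     climate: ClimateGrid, mask: np.ndarray,
                     k: int = 5) -> RangeProjection:
    """Replace an empty projection by its SIM5 minimal refugium."""
    sub = climate.subset(envelope.var_names).values[mask]
    scores = mess_grid_from_bounds(envelope.lower, envelope.upper, sub,
                                   mode="combined")
    cells = sim5(scores, cells=mask, k=k)
    proj.presence = cells
    proj.sim5_substituted = True
    proj.centroid = (float(climate.x[cells].mean()),
                     float(climate.y[cells].mean()))
    return proj


@dataclass
class SeriesResult:
    """Per-species slice series plus the empty-slice census."""

    projections: dict               # (species, provenance) -> [RangeProjection]
    census: pd.DataFrame            # per-species empty-slice counts
    mat_local: pd.DataFrame         # per-species mean BIO1 over mask per slice
    masks: dict                     # species -> accessible cell ids
    failures: dict = field(default_factory=dict)

    def series(self, species: str, provenance: str = "corrected"):
        return self.projections[(species, provenance)]

    def table(self) -> pd.DataFrame:
        rows = []
        for (sp, prov), projs in self.projections.items():
            for p in projs:
                rows.append({
                    "species": sp, "provenance": prov, "time_ka": p.time_ka,
                    "area_km2": p.area_km2,
                    "centroid_x": np.nan if p.centroid is None else p.centroid[0],
                    "centroid_y": np.nan if p.centroid is None else p.centroid[1],
                    "n_fragments": p.n_fragments,
                    "empty": p.empty, "sim5": p.sim5_substituted})
        return pd.DataFrame(rows)

    def census_summary(self) -> dict:
        """Min/max/median empty slices among species with >= 2 empty
        slices, and how many species have two or more empty slices."""
        c = self.census["n_empty_corrected"]
        multi = c[c >= 2]
        return {"n_species_with_2plus_empty": int((c >= 2).sum()),
                "min_empty": int(multi.min()) if multi.size else 0,
                "max_empty": int(multi.max()) if multi.size else 0,
                "median_empty": float(multi.median()) if multi.size else 0.0}


def run_series(envelopes: dict, reconstruction, occurrences: dict,
               modern: ClimateGrid, glacial: ClimateGrid, isotope,
               watersheds: WatershedMap, mask_level: int = 1,
               sim5_k: int = 5, with_fragments: bool = True) -> SeriesResult:
    """Project every species across all slices, corrected and uncorrected.

    Parameters
    ----------
    envelopes : species -> modern NicheEnvelope (the uncorrected model).
    reconstruction : fitted NicheReconstruction serving time-adjusted
        envelopes (the corrected model), or None to skip correction.
    occurrences : species -> OccurrenceSet (defines accessibility masks).

    Single-species failures are recorded in ``failures`` and the run
    continues (partial-results contract).
    """
    from .climate import interpolate_slice

    slices = [interpolate_slice(modern, glacial, isotope, t)
              for t in isotope.times_ka]
    projections, masks, failures = {}, {}, {}
    mat_rows = []
    census_rows = []
    for sp, env in envelopes.items():
        try:
            mask = accessible_mask(occurrences[sp], watersheds, modern,
                                   level=mask_level)
            masks[sp] = mask
            for grid in slices:
                mat_rows.append({"species": sp, "time_ka": grid.time_ka,
                                 "mat_c": float(grid.var("BIO1")[mask].mean())
                                 if "BIO1" in grid.var_names else np.nan})
            corr_envs = None
            if reconstruction is not None:
                corr_envs = [reconstruction.envelope_at_time(sp, t)
                             for t in isotope.times_ka]
            for prov in ("uncorrected", "corrected"):
                if prov == "corrected" and corr_envs is None:
                    continue
                series = []
                n_empty = 0
                for i, grid in enumerate(slices):
                    e = env if prov == "uncorrected" else corr_envs[i]
                    p = project_slice(e, grid, mask, species=sp,
                                      provenance=prov,
                                      with_fragments=with_fragments)
                    if p.empty:
                        n_empty += 1
                        if prov == "corrected":
                            p = _sim5_substitute(p, e, grid, mask, k=sim5_k)
                    series.append(p)
                projections[(sp, prov)] = series
                if prov == "corrected":
                    census_rows.append({"species": sp,
                                        "n_empty_corrected": n_empty})
                else:
                    census_rows.append({"species": sp,
                                        "n_empty_uncorrected": n_empty})
        except Exception as exc:   # noqa: BLE001 - partial-results contract
            failures[sp] = repr(exc)
            warnings.warn(f"species {sp!r} failed: {exc!r}; continuing")
    census = (pd.DataFrame(census_rows)
              .groupby("species").first().reset_index()
              if census_rows else
              pd.DataFrame(columns=["species", "n_empty_corrected",
                                    "n_empty_uncorrected"]))
    if "n_empty_corrected" not in census.columns and len(census):
        census["n_empty_corrected"] = census["n_empty_uncorrected"]
    mat_local = pd.DataFrame(mat_rows)
    return SeriesResult(projections=projections, census=census,
                        mat_local=mat_local, masks=masks, failures=failures)


def richness(projections: list, n_cells: int,
             include_sim5: bool = False) -> np.ndarray:
    """Per-cell species count from one slice's projections."""
    counts = np.zeros(n_cells, dtype=int)
    times = {p.time_ka for p in projections}
    if len(times) > 1:
        raise ValueError("projections must all be from one slice")
    for p in projections:
        if p.sim5_substituted and not include_sim5:
            continue
        if p.presence.size and p.presence.max() >= n_cells:
            from .grids import IncompatibleGridsError
            raise IncompatibleGridsError("projection lattice exceeds grid")
        counts[p.presence] += 1
    return counts
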