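"""Model/Results facade over the hindcasting pipeline.

:class:`PPGM` bundles the inputs of a paleophylogeographic range model —
occurrences, a time-calibrated tree, the two end-member climate grids, the
isotope-proxy MAT series and watershed maps.  ``fit()`` thins the
occurrences, extracts climate, fits per-species rectilinear envelopes,
and reconstructs ancestral envelope bounds by Brownian-motion GLS on the
tree; the returned :class:`PPGMResults` carries the fitted envelopes,
node estimates, per-trait Brownian rates, and methods that project the
ranges through time, regress the range responses on temperature change,
partition them into tracking vs adaptation, and evaluate fossils.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .fossils import FossilRecord, classify_fossil, summarize
from .grids import MODELING_VARS, ClimateGrid, IsotopeSeries, WatershedMap
from .niche import fit_envelope, extract_climate, thin_occurrences
from .phylo import NicheReconstruction, PhyloTree, envelopes_to_traits
from .projection import run_series
from .response import fit_response, pairwise_changes, partition


class PPGM:
    """A paleophylogeographic range model specification.

    Parameters
    ----------
    occurrences : DataFrame with columns species, x, y (projected km).
    tree : PhyloTree whose tip labels match the species.
    modern, glacial : end-member ClimateGrids on one lattice.
    isotope : IsotopeSeries indexing the interpolation.
    watersheds : WatershedMap for accessibility masking.
    variables : modeling-variable subset (default: the eight moderately
        uncorrelated bioclim variables).
    trim_fraction : 0 for the full envelope, 0.10 for the 90% envelope.
    thinning_resolution : spatial thinning grid spacing in km (default:
        one occurrence per climate cell).
    """

    def __init__(self, occurrences: pd.DataFrame, tree: PhyloTree,
                 modern: ClimateGrid, glacial: ClimateGrid,
                 isotope: IsotopeSeries, watersheds: WatershedMap,
                 variables=MODELING_VARS, trim_fraction: float = 0.0,
                 thinning_resolution: float | None = None):
        self.occurrences = occurrences
        self.tree = tree
        self.modern = modern
        self.glacial = glacial
        self.isotope = isotope
        self.watersheds = watersheds
        self.variables = tuple(variables)
        self.trim_fraction = trim_fraction
        self.thinning_resolution = (np.sqrt(modern.cell_area)
                                    if thinning_resolution is None
                                    else thinning_resolution)
        window_ka = float(isotope.times_ka[-1])
        tree.validate_window(window_ka)

    @classmethod
    def from_world(cls, world, **kwargs) -> "PPGM":
        """Build from a :class:`~paleoniche.synthetic.SyntheticWorld`."""
        return cls(occurrences=world.occurrence_frame(), tree=world.tree,
                   modern=world.modern_grid, glacial=world.glacial_grid,
                   isotope=world.isotope, watersheds=world.watersheds,
                   variables=world.variables, **kwargs)

    def fit(self) -> "PPGMResults":
        """Fit envelopes and the Brownian ancestral reconstruction."""
        occ_sets, envelopes, reference_vectors = {}, {}, {}
        species = [sp for sp in self.tree.tip_labels]
        for sp in species:
            pts = self.occurrences.loc[self.occurrences["species"] == sp,
                                       ["x", "y"]].to_numpy(dtype=float)
            occ = thin_occurrences(pts, self.thinning_resolution, species=sp)
            if occ.n_points == 0:
                warnings.warn(f"no occurrences for {sp!r}; species skipped")
                continue
            clim = extract_climate(occ.points, self.modern)
            occ.climate = clim
            occ_sets[sp] = occ
            envelopes[sp] = fit_envelope(
                clim, variables=self.variables,
                trim_fraction=self.trim_fraction,
                provenance=f"modern-tip {sp}")
            reference_vectors[sp] = clim[list(self.variables)].to_numpy()
        traits = envelopes_to_traits(envelopes)
        reconstruction = NicheReconstruction(self.tree, traits)
        return PPGMResults(self, occ_sets, envelopes, reference_vectors,
                           reconstruction)


class PPGMResults:
    """Fitted envelopes, ancestral reconstruction, and derived analyses."""

    def __init__(self, model: PPGM, occ_sets, envelopes, reference_vectors,
                 reconstruction: NicheReconstruction):
        self.model = model
        self.occ_sets = occ_sets
        self.envelopes = envelopes
        self.reference_vectors = reference_vectors
        self.reconstruction = reconstruction
        self.node_estimates = reconstruction.node_estimates
        self._series = None

    def bm_rates(self) -> pd.Series:
        """ML Brownian rate per envelope-bound trait (variance per My)."""
        return self.reconstruction.rates()

    def project(self, mask_level: int = 1, sim5_k: int = 5):
        """Run the full corrected + uncorrected slice series (cached)."""
        if self._series is None:
            self._series = run_series(
                self.envelopes, self.reconstruction, self.occ_sets,
                self.model.modern, self.model.glacial, self.model.isotope,
                self.model.watersheds, mask_level=mask_level, sim5_k=sim5_k)
        return self._series

    def change_records(self, mode: str = "consecutive",
                       mat_source: str = "local") -> dict:
        """Pairwise change records pooled over species, per component.

        ``mat_source``: ``"local"`` uses the per-species mean BIO1 over
        the accessibility mask; ``"global"`` uses the isotope-proxy MAT.
        """
        sr = self.project()
        records = {}
        for prov in ("uncorrected", "corrected"):
            frames = []
            for sp in self.envelopes:
                if (sp, prov) not in sr.projections:
                    continue
                if mat_source == "local":
                    m = sr.mat_local[sr.mat_local["species"] == sp]
                    mat = m.sort_values("time_ka")["mat_c"].to_numpy()
                else:
                    mat = self.model.isotope.mat_c
                frames.append(pairwise_changes(
                    sr.projections[(sp, prov)], mat, mode=mode,
                    component=prov))
            records[prov] = pd.concat(frames, ignore_index=True)
        records["phylogenetic"] = partition(records["corrected"],
                                            records["uncorrected"])
        return records

    def response_fits(self, mode: str = "consecutive",
                      signed: bool = False) -> pd.DataFrame:
        """OLS response-rate fits per component and response variable."""
        records = self.change_records(mode=mode)
        rows = []
        for comp, recs in records.items():
            for resp in ("pc_rs", "pc_gc"):
                from .response import UndefinedFitError
                try:
                    f = fit_response(recs, response=resp, signed=signed)
                    rows.append({"component": comp, "response": resp,
                                 "slope": f.slope, "intercept": f.intercept,
                                 "r_squared": f.r_squared,
                                 "p_value": f.p_value, "n": f.n})
                except UndefinedFitError as exc:
                    rows.append({"component": comp, "response": resp,
                                 "slope": np.nan, "intercept": np.nan,
                                 "r_squared": np.nan, "p_value": np.nan,
                                 "n": 0, "note": str(exc)})
        return pd.DataFrame(rows)

    def evaluate_fossils(self, fossils: list) -> dict:
        """Classify fossils against the fitted niches and summarize."""
        m = self.model
        classified = []
        for f in fossils:
            if isinstance(f, dict):
                f = FossilRecord(species=f["species"], x=f["x"], y=f["y"],
                                 age_min_ka=f["age_min_ka"],
                                 age_max_ka=f["age_max_ka"])
            if f.species not in self.envelopes:
                warnings.warn(f"no fitted niche for {f.species!r}; skipped")
                continue
            classify_fossil(f, self.reference_vectors[f.species],
                            self.envelopes[f.species], m.modern, m.glacial,
                            m.isotope)
            classified.append(f)
        out = summarize(classified)
        out["records"] = classified
        return out

    def summary(self) -> str:
        """Plain-text model summary table."""
        lines = ["Paleophylogeographic range model",
                 "=" * 48,
                 f"species fitted:        {len(self.envelopes)}",
                 f"modeling variables:    {', '.join(self.model.variables)}",
                 f"trim fraction:         {self.model.trim_fraction}",
                 f"slices:                {self.model.isotope.n_slices} x "
                 f"{self.model.isotope.step_ky:g} ky",
                 f"grid cells:            {self.model.modern.n_cells} x "
                 f"{self.model.modern.cell_area:g} km^2",
                 "",
                 "Brownian rates (per-trait ML, variance/My):"]
        rates = self.bm_rates()
        lines.append(f"  min {rates.min():.4g}  median {rates.median():.4g}"
                     f"  max {rates.max():.4g}")
        if self._series is not None:
            cs = self._series.census_summary()
            lines += ["", "Empty-slice census (corrected projections):",
                      f"  species with >=2 empty slices: "
                      f"{cs['n_species_with_2plus_empty']}",
                      f"  min/median/max empty: {cs['min_empty']}/"
                      f"{cs['median_empty']:g}/{cs['max_empty']}"]
        return "\n".join(lines)
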