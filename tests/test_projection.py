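"""Watershed accessibility masks, range projection onto climate slices,
the corrected/uncorrected slice series, and richness maps."""

import numpy as np
import pytest

import paleoniche as pn
from paleoniche.grids import IncompatibleGridsError
from paleoniche.projection import (InvalidMaskError, UnassignedPointError,
                                   count_fragments)
from paleoniche.synthetic import make_endmember_grids


@pytest.fixture(scope="module")
def setting():
    modern, glacial, ws = make_endmember_grids(10, 10, seed=9)
    return modern, glacial, ws


class TestAccessibleMask:
    def test_single_basin_occurrences(self, setting):
        modern, _, ws = setting
        basin = int(ws.level1[0])
        cells = ws.basin_cells(1, basin)
        pts = np.column_stack([modern.x[cells[:3]], modern.y[cells[:3]]])
        mask = pn.accessible_mask(pts, ws, modern, level=1)
        np.testing.assert_array_equal(np.sort(mask), np.sort(cells))

    def test_two_basins_union(self, setting):
        modern, _, ws = setting
        b1, b2 = np.unique(ws.level1)[:2]
        c1 = ws.basin_cells(1, int(b1))[0]
        c2 = ws.basin_cells(1, int(b2))[0]
        pts = np.column_stack([modern.x[[c1, c2]], modern.y[[c1, c2]]])
        mask = pn.accessible_mask(pts, ws, modern, level=1)
        expect = np.sort(np.concatenate([ws.basin_cells(1, int(b1)),
                                         ws.basin_cells(1, int(b2))]))
        np.testing.assert_array_equal(np.sort(mask), expect)

    def test_matches_per_cell_membership_oracle(self, setting, rng):
        modern, _, ws = setting
        cells = rng.choice(modern.n_cells, size=8, replace=False)
        pts = np.column_stack([modern.x[cells], modern.y[cells]])
        for level in (1, 2):
            mask = pn.accessible_mask(pts, ws, modern, level=level)
            labels = ws.labels(level)
            hit_basins = {labels[c] for c in cells}
            expect = [i for i in range(modern.n_cells)
                      if labels[i] in hit_basins]
            np.testing.assert_array_equal(np.sort(mask), expect)

    def test_point_outside_any_basin_rejected(self, setting):
        modern, _, ws = setting
        with pytest.raises(UnassignedPointError):
            pn.accessible_mask(np.array([[-1e5, -1e5]]), ws, modern)

    def test_empty_occurrences_rejected(self, setting):
        modern, _, ws = setting
        with pytest.raises(InvalidMaskError):
            pn.accessible_mask(np.empty((0, 2)), ws, modern)


class TestProjectSlice:
    def test_all_permissive_envelope_fills_mask(self, setting):
        modern, _, _ = setting
        env = pn.NicheEnvelope(modern.var_names,
                               modern.values.min(0), modern.values.max(0))
        mask = np.arange(0, 40)
        p = pn.project_slice(env, modern, mask)
        np.testing.assert_array_equal(p.presence, mask)
        assert p.area_km2 == 40 * modern.cell_area
        assert not p.empty

    def test_disjoint_envelope_flags_empty(self, setting):
        modern, _, _ = setting
        env = pn.NicheEnvelope(("BIO1",), [1e5], [1e6])
        p = pn.project_slice(env, modern, np.arange(modern.n_cells))
        assert p.empty and p.presence.size == 0 and p.centroid is None

    def test_matches_cellwise_membership_oracle(self, setting):
        modern, _, _ = setting
        q = np.percentile(modern.var("BIO1"), [30, 70])
        env = pn.NicheEnvelope(("BIO1",), [q[0]], [q[1]])
        mask = np.arange(modern.n_cells)
        p = pn.project_slice(env, modern, mask)
        expect = [c for c in mask
                  if q[0] <= modern.var("BIO1")[c] <= q[1]]
        np.testing.assert_array_equal(p.presence, expect)
        # centroid = mean of presence-cell centers on the equal-area grid
        assert p.centroid[0] == pytest.approx(modern.x[expect].mean())
        assert p.centroid[1] == pytest.approx(modern.y[expect].mean())

    def test_area_is_cellcount_times_cellarea(self, setting):
        modern, _, _ = setting
        env = pn.NicheEnvelope(modern.var_names,
                               modern.values.min(0), modern.values.max(0))
        p = pn.project_slice(env, modern, np.arange(17))
        assert p.area_km2 == 17 * modern.cell_area

    def test_tightening_bounds_shrinks_range(self, setting):
        modern, _, _ = setting
        lo, hi = np.percentile(modern.var("BIO10"), [10, 90])
        mask = np.arange(modern.n_cells)
        wide = pn.project_slice(pn.NicheEnvelope(("BIO10",), [lo], [hi]),
                                modern, mask)
        tight = pn.project_slice(
            pn.NicheEnvelope(("BIO10",), [lo + 1], [hi - 1]), modern, mask)
        assert set(tight.presence) <= set(wide.presence)

    def test_empty_mask_rejected(self, setting):
        modern, _, _ = setting
        env = pn.NicheEnvelope(("BIO1",), [0.0], [1.0])
        with pytest.raises(InvalidMaskError):
            pn.project_slice(env, modern, np.array([], dtype=int))


class TestRunSeries:
    def test_zero_evolution_corrected_equals_uncorrected(self, small_results):
        sr = small_results.project()
        for sp in small_results.envelopes:
            for pc, pu in zip(sr.series(sp, "corrected"),
                              sr.series(sp, "uncorrected")):
                np.testing.assert_array_equal(pc.presence, pu.presence)
                assert pc.empty == pu.empty

    def test_empty_slices_match_analytic_blend_threshold(self):
        """A species whose lower bound excludes glacial climate empties
        exactly at slices whose blend weight alpha falls below the
        critical value alpha* = (L - x_gla) / (x_mod - x_gla)."""
        grid = pn.ClimateGrid(("BIO1",), np.array([[10.0]]),
                              x=np.array([5.0]), y=np.array([5.0]),
                              cell_area=100.0, n_rows=1, n_cols=1)
        gla = pn.ClimateGrid(("BIO1",), np.array([[0.0]]),
                             x=np.array([5.0]), y=np.array([5.0]),
                             cell_area=100.0, n_rows=1, n_cols=1)
        mats = np.array([15., 13., 11., 9.5, 9., 10., 12., 14.])
        iso = pn.IsotopeSeries(np.arange(8) * 4.0, mats, 15.0, 9.0)
        env = pn.NicheEnvelope(("BIO1",), [4.0], [20.0])  # alpha* = 0.4
        mask = np.array([0])
        empties = []
        for t in iso.times_ka:
            g = pn.interpolate_slice(grid, gla, iso, t)
            empties.append(pn.project_slice(env, g, mask).empty)
        alphas = (mats - 9.0) / 6.0
        np.testing.assert_array_equal(empties, alphas < 0.4)

    def test_census_counts_and_sim5_substitution(self, small_results):
        sr = small_results.project()
        assert set(sr.census["species"]) == set(small_results.envelopes)
        for sp in small_results.envelopes:
            n_empty = sum(p.empty for p in sr.series(sp, "corrected"))
            row = sr.census[sr.census["species"] == sp]
            assert int(row["n_empty_corrected"].iloc[0]) == n_empty
            for p in sr.series(sp, "corrected"):
                if p.empty:
                    assert p.sim5_substituted and p.presence.size == 5
                    assert set(p.presence) <= set(sr.masks[sp])
                else:
                    assert not p.sim5_substituted

    def test_never_empty_species_contributes_zero(self, small_results):
        sr = small_results.project()
        never = sr.census[sr.census["n_empty_corrected"] == 0]
        for sp in never["species"]:
            assert not any(p.empty for p in sr.series(sp, "corrected"))

    def test_presence_within_accessibility_mask(self, small_results):
        sr = small_results.project()
        for (sp, _), series in sr.projections.items():
            allowed = set(sr.masks[sp])
            for p in series:
                assert set(p.presence) <= allowed

    def test_projection_deterministic(self, small_world):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = pn.PPGM.from_world(small_world).fit().project()
            b = pn.PPGM.from_world(small_world).fit().project()
        for key in a.projections:
            for pa, pb in zip(a.projections[key], b.projections[key]):
                np.testing.assert_array_equal(pa.presence, pb.presence)


class TestRichness:
    def _proj(self, cells, t=0.0, sim5=False):
        return pn.RangeProjection("s", t, np.asarray(cells, int), 50.0,
                                  (0.0, 0.0), empty=len(cells) == 0,
                                  sim5_substituted=sim5)

    def test_single_species_is_presence_mask(self):
        r = pn.richness([self._proj([1, 3, 5])], n_cells=8)
        np.testing.assert_array_equal(r, [0, 1, 0, 1, 0, 1, 0, 0])

    def test_disjoint_species_max_one(self):
        r = pn.richness([self._proj([0, 1]), self._proj([2, 3])], n_cells=5)
        assert r.max() == 1

    def test_matches_per_cell_sum_oracle(self, rng):
        projs = [self._proj(np.flatnonzero(rng.random(30) < 0.4))
                 for _ in range(5)]
        r = pn.richness(projs, n_cells=30)
        expect = np.zeros(30, int)
        for p in projs:
            expect[p.presence] += 1
        np.testing.assert_array_equal(r, expect)

    def test_sim5_cells_excluded_by_default(self):
        projs = [self._proj([0, 1]), self._proj([2, 3], sim5=True)]
        np.testing.assert_array_equal(pn.richness(projs, 4), [1, 1, 0, 0])
        np.testing.assert_array_equal(
            pn.richness(projs, 4, include_sim5=True), [1, 1, 1, 1])

    def test_mixed_slices_rejected(self):
        with pytest.raises(ValueError):
            pn.richness([self._proj([0]), self._proj([1], t=4.0)], 4)

    def test_lattice_mismatch_rejected(self):
        with pytest.raises(IncompatibleGridsError):
            pn.richness([self._proj([10])], n_cells=5)


def test_fragment_counting_4_connectivity():
    grid = pn.ClimateGrid(("BIO1",), np.zeros((16, 1)),
                          x=np.tile(np.arange(4.) * 7 + 3.5, 4),
                          y=np.repeat(np.arange(4.) * 7 + 3.5, 4),
                          cell_area=49.0, n_rows=4, n_cols=4)
    # two diagonal cells are separate fragments under 4-connectivity
    assert count_fragments(np.array([0, 5]), grid) == 2
    assert count_fragments(np.array([0, 1, 5]), grid) == 1
    assert count_fragments(np.array([], dtype=int), grid) == 0
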