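"""Synthetic study-system generator.

Builds every input the hindcasting pipeline consumes — glacial/interglacial
end-member climate grids, a quasi-periodic isotope-proxy MAT curve, blocky
nested watershed maps, a Yule tree whose tip niche envelopes evolved by
Brownian motion, occurrence points sampled inside the tip envelopes, and
dated fossils planted in past projected ranges with ground-truth labels —
so every downstream stage is testable without external geodata.

Spatial fields are sums of low-frequency smooth gradients plus seeded,
smoothed noise: cheap, controllable spatial autocorrelation with no
attempt to mimic real geography or the real covariance structure of
observed bioclim layers.  Ages are in ka BP, tree depths in My; this
module owns the 1 My = 1000 ky conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import (BIOCLIM_VARS, MODELING_VARS, TEMPERATURE_VARS,
                    ClimateGrid, IsotopeSeries, WatershedMap)
from .niche import NicheEnvelope
from .phylo import KY_PER_MY, PhyloTree

#: Default glacial cooling of every temperature variable (degrees C); the
#: glacial-interglacial global MAT contrast of the late Quaternary is of
#: order 5-10 degrees.
GLACIAL_OFFSET_C = 6.0
#: Default glacial precipitation scaling (glacial climates are drier).
GLACIAL_PRECIP_FACTOR = 0.7


@dataclass
class SyntheticWorld:
    """A complete synthetic study system with ground truth attached."""

    modern_grid: ClimateGrid
    glacial_grid: ClimateGrid
    isotope: IsotopeSeries
    watersheds: WatershedMap
    tree: PhyloTree
    tip_envelopes: dict                 # latent BM truth, per species
    occ_envelopes: dict                 # envelope of sampled occurrence climates
    occurrences: dict                   # species -> (n, 2) points (km)
    fossils: list                       # FossilRecord-like dicts with truth
    seed: int
    variables: tuple = MODELING_VARS

    @property
    def species(self) -> list:
        return list(self.tree.tip_labels)

    def occurrence_frame(self) -> pd.DataFrame:
        rows = [{"species": sp, "x": p[0], "y": p[1]}
                for sp, pts in self.occurrences.items() for p in pts]
        return pd.DataFrame(rows)

    def fossil_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fossils)


def _smooth_field(rng, n_rows, n_cols, roughness, sigma=4.0):
    """Zero-mean smooth random field with unit-ish amplitude * roughness."""
    if roughness == 0:
        return np.zeros((n_rows, n_cols))
    noise = rng.standard_normal((n_rows, n_cols))
    sm = gaussian_filter(noise, sigma=sigma, mode="nearest")
    s = sm.std()
    if s > 0:
        sm = sm / s
    return roughness * sm


def make_endmember_grids(n_rows: int, n_cols: int, cell_area: float = 50.0,
                         n_vars: int = 19, roughness: float = 1.0,
                         seed: int = 0,
                         glacial_offset_c: float = GLACIAL_OFFSET_C,
                         glacial_precip_factor: float = GLACIAL_PRECIP_FACTOR,
                         n_basins_l1: tuple = (2, 2)):
    """Modern and glacial end-member grids plus a nested watershed map.

    The glacial grid is the modern grid uniformly colder by
    ``glacial_offset_c`` on every temperature variable (plus smooth noise
    scaled by ``roughness``) and drier by ``glacial_precip_factor`` on
    precipitation variables.  ``roughness=0`` makes the glacial grid an
    exact constant-offset copy.  Watersheds partition the lattice into
    contiguous Level-1 blocks, each subdivided into 2x2 Level-2 blocks.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2x2")
    if n_vars not in (8, 19):
        raise ValueError("n_vars must be 8 or 19")
    rng = np.random.default_rng(seed)
    dx = float(np.sqrt(cell_area))
    xs = (np.arange(n_cols) + 0.5) * dx
    ys = (np.arange(n_rows) + 0.5) * dx
    X, Y = np.meshgrid(xs, ys)            # (n_rows, n_cols)
    lat = (Y - ys.min()) / max(ys.max() - ys.min(), 1e-9)   # 0 south, 1 north

    # latent structure: MAT gradient south->north, seasonal spread,
    # moisture gradient west->east
    mat = 24.0 - 20.0 * lat + _smooth_field(rng, n_rows, n_cols, 1.5 * roughness)
    spread = 8.0 + 4.0 * lat + np.abs(
        _smooth_field(rng, n_rows, n_cols, roughness))
    lon = (X - xs.min()) / max(xs.max() - xs.min(), 1e-9)
    wet = 1200.0 - 900.0 * lon + 100.0 * _smooth_field(
        rng, n_rows, n_cols, roughness)
    wet = np.clip(wet, 50.0, None)

    fields = {
        "BIO1": mat,
        "BIO2": 0.45 * spread,
        "BIO3": np.clip(100.0 * 0.45 * spread / (2 * spread), 5.0, 95.0),
        "BIO4": 100.0 * 0.8 * spread,
        "BIO5": mat + spread,
        "BIO6": mat - spread,
        "BIO7": 2.0 * spread,
        "BIO8": mat + 0.3 * spread + _smooth_field(rng, n_rows, n_cols,
                                                   0.5 * roughness),
        "BIO9": mat - 0.3 * spread + _smooth_field(rng, n_rows, n_cols,
                                                   0.5 * roughness),
        "BIO10": mat + 0.6 * spread,
        "BIO11": mat - 0.6 * spread,
        "BIO12": wet,
        "BIO13": 0.18 * wet,
        "BIO14": 0.03 * wet,
        "BIO15": np.clip(40.0 + 30.0 * lon + 10.0 * _smooth_field(
            rng, n_rows, n_cols, roughness), 5.0, 150.0),
        "BIO16": 0.45 * wet,
        "BIO17": 0.10 * wet,
        "BIO18": 0.30 * wet + 10.0 * np.abs(_smooth_field(
            rng, n_rows, n_cols, roughness)),
        "BIO19": 0.15 * wet + 10.0 * np.abs(_smooth_field(
            rng, n_rows, n_cols, roughness)),
    }
    var_names = BIOCLIM_VARS if n_vars == 19 else MODELING_VARS
    modern_vals = np.column_stack([fields[v].ravel() for v in var_names])
    glacial_cols = []
    for v in var_names:
        col = fields[v].ravel().copy()
        if v in TEMPERATURE_VARS and v not in ("BIO2", "BIO4", "BIO7"):
            col = (col - glacial_offset_c
                   + _smooth_field(rng, n_rows, n_cols,
                                   0.3 * roughness).ravel())
        elif v.startswith("BIO1") and v not in ("BIO1", "BIO10", "BIO11",
                                                "BIO15"):
            col = np.clip(col * glacial_precip_factor
                          + 5.0 * _smooth_field(rng, n_rows, n_cols,
                                                roughness).ravel(),
                          0.0, None)
        glacial_cols.append(col)
    glacial_vals = np.column_stack(glacial_cols)

    common = dict(var_names=var_names, x=X.ravel(), y=Y.ravel(),
                  cell_area=cell_area, n_rows=n_rows, n_cols=n_cols)
    modern = ClimateGrid(values=modern_vals, time_ka=0.0, **common)
    glacial = ClimateGrid(values=glacial_vals, time_ka=21.0, **common)

    # blocky nested basins: Level-1 = coarse blocks, Level-2 = quadrants
    br, bc = n_basins_l1
    row_blk = np.minimum((np.arange(n_rows) * br) // n_rows, br - 1)
    col_blk = np.minimum((np.arange(n_cols) * bc) // n_cols, bc - 1)
    l1 = (row_blk[:, None] * bc + col_blk[None, :] + 1)
    sub_r = np.minimum((np.arange(n_rows) * 2 * br) // n_rows, 2 * br - 1) % 2
    sub_c = np.minimum((np.arange(n_cols) * 2 * bc) // n_cols, 2 * bc - 1) % 2
    l2 = l1 * 10 + (sub_r[:, None] * 2 + sub_c[None, :] + 1)
    watersheds = WatershedMap(level1=l1.ravel(), level2=l2.ravel())
    return modern, glacial, watersheds


def make_isotope_series(n_slices: int = 80, step_ky: float = 4.0,
                        period_ky: float = 100.0, mat_modern: float = 15.0,
                        mat_glacial: float = 9.0, amplitude: float | None = None,
                        overshoot_c: float = 1.0, noise_c: float = 0.0,
                        seed: int = 0) -> IsotopeSeries:
    """Quasi-sinusoidal global-MAT proxy over ``n_slices`` uniform steps.

    MAT(0) = ``mat_modern``; troughs reach ``mat_modern - amplitude``
    (default amplitude spans down to ``mat_glacial``); an interglacial
    ``overshoot_c`` above present peaks at t = ``period_ky`` (the last
    interglacial being warmer than today).  Optional seeded noise of sd
    ``noise_c`` is added away from t=0.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    if not mat_modern > mat_glacial:
        raise ValueError("mat_modern must exceed mat_glacial")
    if amplitude is None:
        amplitude = mat_modern - mat_glacial
    t = np.arange(n_slices) * step_ky
    w = 0.5 - 0.5 * np.cos(2 * np.pi * t / period_ky)      # 0 at t=0, 1 at trough
    g = (1.0 - w) * np.sin(np.pi * t / (2 * period_ky)) ** 2
    mat = mat_modern - amplitude * w + overshoot_c * g
    if noise_c > 0:
        rng = np.random.default_rng(seed)
        eps = noise_c * rng.standard_normal(n_slices)
        eps[0] = 0.0
        mat = np.clip(mat + eps, mat_glacial, None)
    return IsotopeSeries(times_ka=t, mat_c=mat, mat_modern=mat_modern,
                         mat_glacial=mat_glacial)


def simulate_yule_tree(n_species: int, birth_rate: float, rng,
                       min_terminal_my: float = 0.4) -> PhyloTree:
    """Yule (pure-birth) tree conditioned on ``n_species`` extant tips.

    Speciation intervals are exponential with rate k*lambda while k
    lineages exist; the final interval (last split to present) is floored
    at ``min_terminal_my`` so that the 320-ka modeling window fits inside
    every terminal branch.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    active = [tree.seed_node]
    tree.seed_node.edge.length = 0.0
    elapsed = [0.0]          # birth time (depth) per active lineage start
    birth_time = {tree.seed_node: 0.0}
    now = 0.0
    while len(active) < n_species:
        k = len(active)
        now += rng.exponential(1.0 / (birth_rate * k))
        i = rng.integers(k)
        parent = active.pop(i)
        parent.edge.length = now - birth_time[parent]
        c1, c2 = dendropy.Node(), dendropy.Node()
        parent.add_child(c1)
        parent.add_child(c2)
        birth_time[c1] = birth_time[c2] = now
        active.extend([c1, c2])
    tail = max(rng.exponential(1.0 / (birth_rate * n_species)),
               min_terminal_my)
    present = now + tail
    for j, leaf in enumerate(active):
        leaf.edge.length = present - birth_time[leaf]
        leaf.taxon = taxon_namespace.new_taxon(label=f"sp{j + 1:02d}")
    tree.seed_node.edge.length = None
    return PhyloTree(tree)


def _simulate_bm_on_tree(ptree: PhyloTree, root_value: float, rate: float,
                         rng) -> dict:
    """Brownian tip values: independent Gaussian increments per branch."""
    vals = {}
    for nd in ptree.tree.preorder_node_iter():
        if nd.parent_node is None:
            vals[nd] = root_value
        else:
            ln = nd.edge.length or 0.0
            vals[nd] = vals[nd.parent_node] + rng.standard_normal() * np.sqrt(
                rate * ln)
    return {t.taxon.label: vals[t] for t in ptree.tips}


def simulate_clade(n_species: int, birth_rate: float, bm_rate: float,
                   root_envelope: NicheEnvelope, seed: int = 0,
                   bm_rate_logwidth: float | None = None,
                   min_terminal_my: float = 0.4):
    """Yule tree plus Brownian-evolving tip envelopes.

    Envelope midpoints evolve by Brownian motion with variance ``bm_rate``
    per My; log-widths evolve with variance ``bm_rate_logwidth`` (defaults
    to ``bm_rate`` scaled to a gentle 0.01 when ``bm_rate`` > 0), keeping
    widths positive.  ``bm_rate=0`` returns the root envelope at every tip.

    Returns (PhyloTree, trait matrix DataFrame of tip envelope bounds).
    """
    if bm_rate < 0:
        raise ValueError("bm_rate must be >= 0")
    rng = np.random.default_rng(seed)
    ptree = simulate_yule_tree(n_species, birth_rate, rng,
                               min_terminal_my=min_terminal_my)
    if bm_rate_logwidth is None:
        bm_rate_logwidth = 0.01 if bm_rate > 0 else 0.0
    cols = {}
    for i, v in enumerate(root_envelope.var_names):
        lo, up = root_envelope.lower[i], root_envelope.upper[i]
        mid0, w0 = 0.5 * (lo + up), max(up - lo, 1e-9)
        scale = w0    # midpoint steps scale with envelope width
        mids = _simulate_bm_on_tree(ptree, 0.0, bm_rate, rng)
        logws = _simulate_bm_on_tree(ptree, 0.0, bm_rate_logwidth, rng)
        lo_col, up_col = {}, {}
        for sp in ptree.tip_labels:
            mid = mid0 + scale * 0.1 * mids[sp]
            w = w0 * np.exp(logws[sp])
            lo_col[sp] = mid - w / 2
            up_col[sp] = mid + w / 2
        cols[f"{v}_lower"] = lo_col
        cols[f"{v}_upper"] = up_col
    traits = pd.DataFrame(cols).loc[ptree.tip_labels]
    return ptree, traits


def default_root_envelope(modern: ClimateGrid,
                          variables=MODELING_VARS,
                          q_low: float = 25.0,
                          q_high: float = 75.0) -> NicheEnvelope:
    """A mid-sized root niche: the interquartile climate of the modern
    grid, guaranteeing plenty of suitable cells for the root species."""
    lower = [np.percentile(modern.var(v), q_low) for v in variables]
    upper = [np.percentile(modern.var(v), q_high) for v in variables]
    return NicheEnvelope(var_names=tuple(variables), lower=np.array(lower),
                         upper=np.array(upper), provenance="synthetic-root")


def traits_to_envelopes(traits: pd.DataFrame, variables,
                        provenance: str = "modern-tip") -> dict:
    envs = {}
    for sp, row in traits.iterrows():
        lower = np.array([row[f"{v}_lower"] for v in variables])
        upper = np.array([row[f"{v}_upper"] for v in variables])
        envs[sp] = NicheEnvelope(var_names=tuple(variables), lower=lower,
                                 upper=upper, provenance=provenance)
    return envs


def sample_occurrences_and_fossils(modern: ClimateGrid, glacial: ClimateGrid,
                                   isotope: IsotopeSeries,
                                   watersheds: WatershedMap,
                                   tip_envelopes: dict,
                                   n_occ: int = 100, n_fossils: int = 50,
                                   occupancy: float = 1.0,
                                   age_blur_ky: float = 0.0,
                                   p_inside: float = 0.87,
                                   seed: int = 0,
                                   variables=MODELING_VARS,
                                   home_basins_l1: int | None = None):
    """Occurrence points and planted fossils with ground-truth labels.

    Occurrences are cell centers drawn (without replacement) from the
    cells whose modern climate lies inside the species' latent tip
    envelope, each suitable cell included with probability ``occupancy``.
    Fossils are planted at random past slices within the species'
    accessible (occurrence-bearing Level-1 basin) cells; with probability
    ``p_inside`` the planting cell/slice is chosen so its paleoclimate
    lies inside the species' occurrence-derived envelope (the range the
    pipeline projects), otherwise outside it.  The truth label records
    that membership; the reported age window is the true slice time +/-
    ``age_blur_ky``, clipped to the modeled span.  Truth labels are a
    test-only channel, never read by the analysis modules.

    ``home_basins_l1`` imposes dispersal limitation: each species is
    confined to that many randomly chosen Level-1 drainage basins (among
    those holding suitable cells), emulating basin-bound ranges whose
    accessible climate can vanish entirely during glacial slices.  The
    default (None) leaves ranges unrestricted.
    """
    from .climate import interpolate_slice
    from .niche import fit_envelope

    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    rng = np.random.default_rng(seed)
    variables = tuple(variables)
    sub_modern = modern.subset(variables)

    occurrences, occ_envelopes = {}, {}
    for sp, env in tip_envelopes.items():
        inside = env.contains(sub_modern.values)
        cells = np.flatnonzero(inside)
        if cells.size == 0:
            warnings.warn(f"species {sp!r} has zero suitable cells; "
                          "no occurrences emitted")
            occurrences[sp] = np.empty((0, 2))
            continue
        if home_basins_l1 is not None:
            suitable_basins = np.unique(watersheds.level1[cells])
            k = min(home_basins_l1, suitable_basins.size)
            chosen_basins = rng.choice(suitable_basins, size=k,
                                       replace=False)
            cells = cells[np.isin(watersheds.level1[cells], chosen_basins)]
        if occupancy < 1.0:
            cells = cells[rng.random(cells.size) < occupancy]
            if cells.size == 0:
                cells = np.array([rng.choice(np.flatnonzero(inside))])
        take = min(n_occ, cells.size)
        chosen = np.sort(rng.choice(cells, size=take, replace=False))
        occurrences[sp] = np.column_stack([modern.x[chosen],
                                           modern.y[chosen]])
        occ_envelopes[sp] = fit_envelope(
            sub_modern.values[chosen], variables=variables,
            provenance="synthetic-occurrence-envelope")

    # paleoclimate per slice, restricted to modeling variables
    slice_cache = {}

    def slice_values(t):
        if t not in slice_cache:
            g = interpolate_slice(modern, glacial, isotope, t)
            slice_cache[t] = g.subset(variables).values
        return slice_cache[t]

    species_with_occ = [sp for sp in tip_envelopes if sp in occ_envelopes]
    fossils = []
    t_max = isotope.times_ka[-1]
    past = isotope.times_ka[1:]
    attempts = 0
    while len(fossils) < n_fossils and attempts < 50 * n_fossils:
        attempts += 1
        sp = species_with_occ[rng.integers(len(species_with_occ))]
        env = occ_envelopes[sp]
        # accessibility: Level-1 basins holding the species' occurrences
        from .projection import accessible_mask
        mask = accessible_mask(occurrences[sp], watersheds, modern, level=1)
        t = float(past[rng.integers(past.size)])
        vals = slice_values(t)[mask]
        inside = env.contains(vals)
        want_inside = bool(rng.random() < p_inside)
        pool = mask[inside] if want_inside else mask[~inside]
        if pool.size == 0:
            continue
        cell = int(pool[rng.integers(pool.size)])
        truth_inside = bool(env.contains(
            slice_values(t)[cell]))
        fossils.append({
            "species": sp,
            "x": float(modern.x[cell]), "y": float(modern.y[cell]),
            "cell_id": cell,
            "true_slice_ka": t,
            "age_min_ka": max(0.0, t - age_blur_ky),
            "age_max_ka": min(float(t_max), t + age_blur_ky),
            "truth_inside_envelope": truth_inside,
        })
    if len(fossils) < n_fossils:
        warnings.warn(f"planted only {len(fossils)} of {n_fossils} fossils")
    return occurrences, occ_envelopes, fossils


def make_world(n_species: int = 10, n_rows: int = 50, n_cols: int = 50,
               n_slices: int = 80, step_ky: float = 4.0,
               cell_area: float = 50.0, birth_rate: float = 0.3,
               bm_rate: float = 0.0, roughness: float = 1.0,
               n_occ: int = 100, n_fossils: int = 50,
               occupancy: float = 1.0, age_blur_ky: float = 0.0,
               p_inside: float = 0.87, seed: int = 0,
               variables=MODELING_VARS, home_basins_l1: int | None = None,
               **iso_kwargs) -> SyntheticWorld:
    """One-call construction of a full synthetic study system.

    Derived sub-seeds are split deterministically from ``seed``; the same
    seed reproduces every field bit-identically.
    """
    ss = np.random.SeedSequence(seed)
    s_grid, s_iso, s_clade, s_sample = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4)]
    modern, glacial, watersheds = make_endmember_grids(
        n_rows, n_cols, cell_area=cell_area, roughness=roughness,
        seed=s_grid)
    isotope = make_isotope_series(n_slices=n_slices, step_ky=step_ky,
                                  seed=s_iso, **iso_kwargs)
    root_env = default_root_envelope(modern, variables=variables)
    tree, traits = simulate_clade(n_species, birth_rate, bm_rate, root_env,
                                  seed=s_clade,
                                  min_terminal_my=(n_slices * step_ky)
                                  / KY_PER_MY * 1.25)
    tip_envelopes = traits_to_envelopes(traits, variables,
                                        provenance="synthetic-tip-truth")
    occurrences, occ_envelopes, fossils = sample_occurrences_and_fossils(
        modern, glacial, isotope, watersheds, tip_envelopes,
        n_occ=n_occ, n_fossils=n_fossils, occupancy=occupancy,
        age_blur_ky=age_blur_ky, p_inside=p_inside, seed=s_sample,
        variables=variables, home_basins_l1=home_basins_l1)
    return SyntheticWorld(modern_grid=modern, glacial_grid=glacial,
                          isotope=isotope, watersheds=watersheds,
                          tree=tree, tip_envelopes=tip_envelopes,
                          occ_envelopes=occ_envelopes,
                          occurrences=occurrences, fossils=fossils,
                          seed=seed, variables=tuple(variables))


def write_world(world: SyntheticWorld, out_dir) -> None:
    """Serialize a world: CSV occurrences/fossils/watersheds/isotope,
    NetCDF end-member grids, Newick tree."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.modern_grid.to_netcdf(out / "modern_grid.nc")
    world.glacial_grid.to_netcdf(out / "glacial_grid.nc")
    world.isotope.to_csv(out / "isotope.csv")
    world.watersheds.to_csv(out / "watersheds.csv")
    (out / "tree.nwk").write_text(world.tree.to_newick() + "\n")
    world.occurrence_frame().to_csv(out / "occurrences.csv", index=False)
    world.fossil_frame().to_csv(out / "fossils.csv", index=False)
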