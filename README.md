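# paleoniche

Paleophylogeographic range modeling for Quaternary glacial–interglacial
cycles: hindcast where species could have lived over the last ~320 ky,
test the hindcasts against fossils, and ask whether species responded to
climate change by *tracking* suitable climate across geography or by
*adapting* their climatic niche.

The package was built around the study system where this approach matured
— Nearctic turtles, ectotherms whose ranges are bounded by drainage basins
and whose niches are strongly climate-controlled — but every stage works
on synthetic data generated by the package itself, so the full pipeline is
testable without any external geodata.

## The model

**Niche envelopes.** A species' potential niche is a rectilinear BIOCLIM
envelope: independent per-variable bounds `[lᵥ, uᵥ]` over a subset of the
19 standard bioclimatic variables, fitted as the min/max (100% envelope)
or 5th/95th percentiles (90% envelope) of the climate extracted at its
thinned occurrence points. Rectilinear envelopes depend only on marginals,
so they are unbiased by inter-variable correlations — which need not be
the same in past climates. The realized niche is operationalized as the
convex hull of the occurrence climates (always nested in the envelope).

**Continuous paleoclimate.** Two end-member grids — modern (interglacial)
and full-glacial — are blended per cell and variable,

    X_t = α·X_modern + (1−α)·X_glacial,
    α = (MAT(t) − MAT_glacial) / (MAT_modern − MAT_glacial),

where MAT(t) is an isotope-proxy global mean-annual-temperature curve at
4-ky steps; α > 1 extrapolates into interglacials warmer than present.

**Phylogenetic correction.** Envelope bounds are treated as continuous
characters evolving by Brownian motion on a time-calibrated tree.
Ancestral bounds at internal nodes are GLS (joint-ML) estimates under the
Brownian covariance; the envelope of a species at time *t* on its terminal
branch interpolates linearly between its modern bounds and its parent
node's estimate. Projecting the time-adjusted (corrected) and fixed-modern
(uncorrected) envelopes onto each climate slice — masked to the Level-1
drainage basins holding the species' occurrences — yields per-slice range
masks, areas and centroids. Subtracting uncorrected from corrected changes
isolates the adaptive (phylogenetic) component of the range response.

**MESS and SIM5.** A point's multivariate environmental similarity score
is, per variable, `100·(1 − 2|x−mid|/width)` inside the reference interval
and `−100·dist/width` outside, combined as the minimum over variables.
Negative scores flag non-analogue climate; fossils are dated to the slice
maximizing their score and classified against the realized/potential
niches. When a projected range contracts to nothing, the five accessible
cells with least-negative MESS (SIM5) stand in as a minimal refugium.

## Worked example

```python
import paleoniche as pn

world = pn.make_world(n_species=10, n_rows=50, n_cols=50, n_slices=80,
                      n_occ=4000, n_fossils=60, home_basins_l1=1, seed=2013)
results = pn.PPGM.from_world(world).fit()
series = results.project()
print(results.summary())
```

prints

```
Paleophylogeographic range model
================================================
species fitted:        10
modeling variables:    BIO2, BIO5, BIO8, BIO10, BIO16, BIO17, BIO18, BIO19
trim fraction:         0.0
slices:                80 x 4 ky
grid cells:            2500 x 50 km^2

Brownian rates (per-trait ML, variance/My):
  min 0.000812  median 21.9  max 5610

Empty-slice census (corrected projections):
  species with >=2 empty slices: 7
  min/median/max empty: 12/33/33
```

Seven of the ten dispersal-limited species lose *all* suitable climate in
their home basins for 12–33 of the 80 glacial-cycle slices — the modeled
analogue of glacial range collapse into refugia. (The Brownian rates are
estimated from the *fitted* envelopes, which differ across species because
each species samples climate from its own home basin, even though the
generating tip envelopes did not evolve here.) Fossil evaluation and the
tracking-vs-adaptation regression then follow from the same object:

```python
fossil_report = results.evaluate_fossils(world.fossils)
print(fossil_report["total"])
# {'n_fossils': 60, 'pct_within_realized': 0.0, 'pct_within_potential': 81.7}
print(results.response_fits().to_string(index=False))
#    component response      slope  intercept  r_squared      p_value   n
#  uncorrected    pc_rs 914.742945  53.841150   0.271237 3.931147e-56 790
#  uncorrected    pc_gc  17.866969  -1.334567   0.401006 1.118190e-68 601
#    corrected    pc_rs 901.094323  -5.404068   0.260134 1.551054e-53 790
#    corrected    pc_gc  16.722587  -2.027616   0.298285 1.265315e-62 790
# phylogenetic    pc_rs 169.735450  76.263052   0.024942 8.197351e-06 790
# phylogenetic    pc_gc   3.151862   0.398017   0.043663 2.351763e-07 601
```

`pct_within_potential` is the share of fossils whose paleoclimate at
their best-dated slice lies inside the species' modern envelope (81.7%
here: fossils were planted inside with probability 0.87). The
within-realized share is 0% in this synthetic world — an 8-dimensional
convex hull is thin relative to its bounding box, so even slightly
shifted paleoclimates fall outside it, unlike the lower-dimensional
structure of real climate data. The response-fit table gives the OLS
slope, intercept, R² and p of |ΔRS| and |ΔGC| on |ΔMAT| per component;
note the phylogenetic component explains almost nothing (R² ≈ 0.02–0.04)
— climate tracking, not adaptation, drives the modeled responses.

A thin CLI wraps the same pipeline:

```sh
paleoniche synthesize --seed 3 --n-species 10 --out-dir world/
paleoniche run --config config.yaml
```

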