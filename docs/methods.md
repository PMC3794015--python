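# Methods

This note records the model assumptions, the defaults that matter, what
the synthetic generator does and does not emulate, and the design choices
made where the design was genuinely open.

## Paleoclimate interpolation

The continuous climate series is a per-cell, per-variable linear blend of
two end-member grids indexed by the isotope-proxy global MAT curve:
`X_t = α·X_modern + (1−α)·X_glacial` with
`α = (MAT(t) − MAT_gla)/(MAT_mod − MAT_gla)`. Linear blending is the
minimal model consistent with scaling every variable to the global MAT
record; α is allowed to exceed 1 so that interglacials warmer than
present extrapolate linearly rather than saturating. Consequences worth
knowing: the blend is exact at both end-members (α = 1 and α = 0 return
the respective grids bit-identically), any cell/variable is monotone in
MAT(t), and under a fixed envelope the suitability of a cell is an
*interval in α* — which is what makes the empty-slice census analytically
checkable (the α-interval oracle used by the test suite).

Slice lookup is strict: a time must be exactly one of the series' slice
times, with no nearest-slice snapping. A separate helper maps arbitrary
age windows to the bracketing/contained slices; fossil age resolution goes
through that helper only.

Temperatures are plain °C internally; any ×10 integer-encoded raster
input must be rescaled at the reader boundary. Grid I/O uses NetCDF
(scipy backend) and CSV rather than GeoTIFF; coordinates are projected
kilometres on an equal-area lattice (default cell area 50 km², chosen to
avoid latitudinal bias in sampling density), so no projection machinery
is needed at runtime.

## Envelopes and realized membership

The 100% envelope is the per-variable min/max of the training climates;
the 90% envelope uses 5th/95th percentiles with the linear-interpolation
convention. "Excluding the outlying 10% of points" is ambiguous between a
multivariate and a per-variable reading; the per-variable symmetric trim
was chosen because it is deterministic, standard for BIOCLIM-style
envelopes, and matches the rectilinear framing. With fewer than 10
training vectors the trim is statistically meaningless and falls back to
min/max with a provenance note.

Realized-niche membership is convex-hull membership of the occurrence
climates (LP feasibility, residual tolerance 1e-9, columns rescaled to
unit width for conditioning). The hull is strictly nested in the trim-0
envelope fitted on the same vectors, which guarantees the
within-realized ≤ within-potential ordering in every fossil summary. The
hull test is parameter-free but *dimension-sensitive*: in the 8-variable
modeling space a hull occupies a small fraction of its bounding box, so
synthetic fossils rarely test as within-realized even when their climate
is barely shifted; percentages from this test should be compared only
across runs with the same variable set.

Occurrence thinning keeps the first point in input order per thinning
cell (determinism without a seed); the default thinning resolution equals
the climate cell size. Point-to-cell assignment uses a half-open cell
convention, left/bottom inclusive.

The default modeling subset is BIO2, BIO5, BIO8, BIO10, BIO16, BIO17,
BIO18, BIO19 — a standard moderately uncorrelated set. One naming caveat:
source materials for this variable set sometimes label the warm-month
maximum "BIO6"; conventionally BIO5 is the warm-month maximum and BIO6
the cold-month minimum, and this package uses the conventional coding
throughout. The subset is configuration, not hard-coded.

## Brownian ancestral reconstruction

Each envelope bound (lower and upper per variable) is an independent
continuous character. Ancestral states are joint-ML estimates under
Brownian motion, computed by solving the weighted-Laplacian system with
edge weights 1/branch-length; this is algebraically identical to GLS
conditional means under the shared-path-length covariance (the test suite
checks the equivalence against an explicit covariance-matrix oracle to
1e-8, and against an independent R implementation). The root estimate is
the GLS grand mean. The ML rate estimator carries the usual (n−1)/n
downward bias, which the parameter-recovery tests account for.

Along-branch values interpolate linearly in time between the tip (t = 0)
and the parent-node estimate (at the node's age), with a single
reconstruction per trait rather than a re-fit per slice — the cheaper of
the two readings, and exact at both endpoints. Because every node
estimate is a positively-weighted average of valid tip envelopes applied
columnwise, lower ≤ upper is preserved along branches; the
midpoint-collapse repair exists only as a guard for externally supplied
or corrupted reconstruction tables, and logs a warning when triggered.
The 320-ka modeling window must lie within every terminal branch, checked
at model construction; My↔ky conversion is fixed at 1000 and owned by the
phylogenetics module.

## MESS, SIM5, masking

The rectilinear MESS formula is implemented literally: inside a reference
interval the score falls linearly from +100 at the midpoint to 0 at a
boundary; outside it is −100 × (distance to nearest boundary)/(interval
width). The combined score is the minimum over variables (one
incompatible variable suffices for non-analogue status), with arg-min
ties broken by canonical BIO ordering. The score is invariant under
positive affine maps of a variable, so unit choices cannot change it.

SIM5 selects the five accessible cells with least-negative combined MESS
when a projected range is empty, ties broken by ascending cell id.
Candidates are restricted to the species' Level-1 accessibility mask — a
refugium a species cannot reach is not a refugium. Level-1 basins mask
projections; Level-2 basins define available climate space for reference
bounds. SIM5-substituted slices are flagged and excluded from richness
maps by default.

## Response partitioning

Change records are built per species between slices (consecutive by
default; all-pairs available — the choice is a config field because the
pairing convention is not uniquely determined by the framing). PC_MAT
defaults to the range-local mean BIO1 over the species' accessibility
mask (per-species responses are range-relevant); a global-MAT mode
exists. Regressions default to magnitudes (|response| on |ΔMAT|): the
positive intercepts and slopes of the published full-scale fits are most
consistent with magnitude-on-magnitude, and a signed mode is available.
Empty slices contribute area 0 and no centroid; records with undefined
centroid displacement are flagged and excluded from centroid regressions.
A constant response (e.g. the phylogenetic component under zero niche
evolution) returns slope 0, R² 0, p 1 rather than an error, so component
regressions remain well-defined in the degenerate limit.

The partition is exact by construction: corrected = uncorrected +
phylogenetic component, field-wise per (species, slice pair).

## Fossil evaluation

A fossil's age window resolves to the modeled slice(s) within it that
maximize the combined MESS of its cell against the species' potential
niche — the conservative choice that minimizes ad hoc niche-change
assumptions; exact ties keep all tied slices, and the most favorable
slice supplies the headline classification. Paleoclimate is read from the
single containing cell (no neighborhood averaging), matching the per-cell
arithmetic elsewhere. Classification against the *resolved-slice*
paleoclimate (rather than the modern climate at the site) is a recorded
choice, consistent with treating fossils as tests of past potential
ranges. Percentages are aggregated unrounded and rounded once to one
decimal for tables.

Physiological congruence: CT_max is congruent iff it is ≥ the highest
BIO5 upper bound across slices; CT_min iff ≤ the lowest BIO6 lower bound;
the incubation interval iff it overlaps the BIO10 envelope interval in
every slice. Missing fields are skipped with a note.

Two small published reference tables (per-species fossil classification
percentages and per-variable MESS deviation summaries for Nearctic
turtles) are bundled for the aggregation arithmetic worked examples; they
are inputs, not outputs, of this package.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not real geography. Climate fields are low-frequency latitudinal/
longitudinal gradients plus seeded Gaussian-smoothed noise; internal
consistency is enforced where the analysis relies on it (BIO5 ≥ BIO6,
non-negative precipitation) but the full covariance structure of observed
bioclim layers is not reproduced. The glacial end-member is uniformly
colder by 6 °C on temperature variables (the order of the late-Quaternary
glacial–interglacial MAT contrast) and drier by a factor 0.7 on
precipitation totals, plus smooth noise. The MAT curve is quasi-sinusoidal
with a 100-ky period (the dominant late-Pleistocene cyclicity), anchored
at 15 °C modern and 9 °C glacial, with a 1 °C interglacial overshoot so
the warmest slice is warmer than present. Watersheds are blocky nested
partitions (2×2 Level-1 quadrants, each split into 2×2 Level-2 blocks).

The clade is a Yule tree conditioned on the tip count, with the final
interval floored so the 320-ka window fits inside every terminal branch
(a conditioning of the simulation, required for along-branch
interpolation to be defined for all slices). Envelope midpoints evolve by
Brownian motion; log-widths evolve by Brownian motion so widths stay
positive.

Occurrences are cell centers drawn from cells suitable under the latent
tip envelope; the optional `home_basins_l1` setting confines each species
to randomly chosen Level-1 basins, emulating dispersal-limited,
basin-bound ranges — the condition under which glacial slices can empty a
species' accessible climate entirely. Fossils are planted at past slices
inside (probability 0.87, matching the empirically typical share of
fossils compatible with modern niches) or outside the species'
*occurrence-derived* envelope. Truth labels record membership in that
envelope rather than the latent tip envelope, because only the occurrence
envelope is exactly recoverable downstream; with zero age blur the
pipeline must — and does — reproduce every label exactly. Truth labels
are a test-only channel, never read by analysis code.

What passing tests therefore show: the pipeline's algebra (blending,
membership, reconstruction, partitioning, scoring) is exact and
self-consistent at study scale. What they do not show: that real climate
fields, real occurrence biases, or real fossil taphonomy behave like the
generator — full-scale regression coefficients and census figures from
the real continental dataset are not reproducible from synthetic data and
are treated as report schemas, not target values.

## Problem sizes and numerics

Default test/demo scale is 10 species on a 2,500-cell grid over 80
slices, which exercises every code path in seconds. Envelope membership,
blending and MESS are vectorized; the ancestral solve is one dense linear
system per trait (n_nodes × n_nodes). LP hull membership is the only
superlinear step and is per-fossil. Determinism: all stochastic stages
take explicit seeds, sub-seeds are spawned from a single master seed, and
projection/scoring contain no randomness at all.
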