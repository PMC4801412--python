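# Methods

This note records the models, conventions and design decisions behind
`betascape`, in the spirit of a statistical methods appendix: what is
computed, under which assumptions, and where the genuinely open choices
were made.

## Grid and rasterization

The analysis frame is a rectangular lat/lon lattice with a boolean land
mask. Cells are half-open boxes `[lon, lon+s) × (lat−s, lat]`, row 0 is
northernmost, and land cells are indexed row-major; every module shares
this single convention.

A species is present in a cell when its range polygon covers at least
half the cell's area (`coverage_threshold = 0.5`, inclusive). Coverage is
an exact polygon–rectangle intersection computed in planar degree
coordinates. No spherical-area correction is applied: on a half-degree
grid the relative distortion of the coverage *fraction* within one cell
is negligible compared to range-map digitization error, and the planar
rule matches what a GIS overlay on a degree grid does. Species whose
polygons clear no cell are kept as all-false columns and reported, so
species bookkeeping is auditable. The restricted-range subset takes the
`⌈q·S⌉` species with the smallest occupied-cell counts (`q = 0.25`),
breaking ties deterministically by species id so the subset size is
exact.

## Beta diversity and neighborhood fields

Pairwise dissimilarity uses the Baselga decomposition: with `a` shared
species, `b` exclusive to the focal cell and `c` to the neighbor,
`βsim = min(b,c)/(a+min(b,c))`, `βsor = (b+c)/(2a+b+c)`,
`βsne = βsor − βsim`. When `a + min(b,c) = 0` (an empty community) the
statistic is undefined and the functions return `None`, never a number.

Neighborhood turnover is the mean βsim between a cell and its
queen-adjacent land cells. Design choices the literature leaves open:

* **Edge cells** average over the 1–8 neighbors that exist; the neighbor
  count is stored on the field so analysts can filter if desired.
* **Undefined pairs are skipped**; cells with no defined pair are
  missing, and cells with zero richness therefore drop out of all
  regressions.
* **`.dif` uses mean absolute differences.** Signed differences cancel
  on monotone gradients and would erase exactly the relief signal the
  turnover analysis is after; a `signed` mode exists for sensitivity
  checks only.
* Turnover fields are square-root transformed before regression to
  symmetrize their skew.

## Spatial statistics

Moran's I follows the standard double-sum form with binary queen weights
for contiguity diagnostics and binary distance-class weights for
correlograms. Correlogram classes are equal-width bins partitioning
`(0, d_max]`, so every pair is assessed exactly once. Significance is a
two-sided permutation test, `p = min(1, 2·min(p_lo, p_hi))` with the
observed statistic counted in both tails; its type-I error at α = 0.05 is
verified to sit in [0.03, 0.07] by simulation (500 white-noise fields,
999 permutations each).

PCNM filters: inter-cell great-circle distances (spherical Earth,
R = 6371 km; planar degrees available, and the metric is recorded on the
filter set so the truncation distance and matrix can never mix units) are
truncated at the longest minimum-spanning-tree edge — the smallest
threshold that keeps the graph connected — with beyond-truncation entries
replaced by `4t`, the classical constant. The truncated matrix is
Gower-centered and eigen-decomposed; eigenvectors with eigenvalues above
`1e-9 ×` the largest are retained, unit-normalized, in descending
eigenvalue order (broad scales first). The implementation agrees with
`vegan::pcnm` to seven digits on transect benchmarks. A caveat worth
recording: on a 50-cell regular transect the leading eigenvector is a
half-cosine-like arch whose correlation with the pure half-period cosine
is 0.868 (identically in vegan); only an *untruncated* PCoA score reaches
0.99. Claims that truncated PCNM reproduces the pure cosine overstate the
resemblance.

**Filter selection** operationalizes "minimize residual Moran's I" as
greedy forward selection: at each step add the eigenvector that most
reduces the absolute Moran's I of the least-squares residuals; stop when
the residual autocorrelation is no longer significant (seeded permutation
test), when no candidate improves |I| by at least 5% (relative), or at a
configurable cap. Two choices deserve emphasis:

* **Selection target.** By default filters are selected against the
  residuals of the environmental model, not the raw response. Selecting
  on the raw response lets broad eigenvectors absorb the variance that
  space and environment share — a montane clade's richness *is* a broad
  spatial pattern — which collapses semipartial R² of the very predictors
  the analysis is estimating and can invert predictor rankings. Residual
  selection targets the spatial structure the environment cannot explain,
  which is what the filters are for. `select_on="response"` restores the
  naive behavior.
* **Improvement floor.** Broad-scale filters each remove only ~1–2% of
  queen-scale residual autocorrelation generated by contiguous ranges; an
  unbounded greedy search therefore accumulates filters that fix little
  autocorrelation while degrading the conditioned environmental terms.
  The 5% relative floor is a parsimony guard; genuinely broad-scale
  signal (e.g. a planted eigenvector) still clears it easily.

## Regression layer

The analysis cell set is fixed per comparison — land cells with richness
≥ 1 and all predictors defined — because AICc values are only comparable
at a single n. Semipartial R² of predictor j is `R²(full) − R²(full−j)`
with parametric extra-sum-of-squares F tests (permutation F is out of
scope). Both the raw global R² and the filter-partialled fraction are
reported, since published "global model" values are ambiguous between the
two readings. Model selection enumerates all nonempty predictor subsets
(guarded at p ≤ 15) with filters always included;
`AICc = n·ln(RSS/n) + 2K + 2K(K+1)/(n−K−1)` with K counting intercept,
filters and predictors, constant likelihood terms dropped consistently.
Coefficients are standardized by z-scoring response and predictors;
filters enter unstandardized (they are unit-norm by construction).
Latitude enters Pearson correlations as signed degrees.

## The synthetic continent generator

The generator is a stand-in, not a fitted model: no suitable range-map
data are redistributable, so the study conditions are emulated by
construction and every dataset ships ground truth (niche weights, optima,
realized range sizes, truncation flags) for parameter-recovery tests.

**Environment.** Elevation is a Gaussian ridge near the western margin
(4000 m × exp-profile, sd 4 columns) whose crest meanders (sd 2 columns)
and whose height varies along the ridge (cv 0.3), plus fine-scale relief
noise (sd 700 m, correlation length ~1 cell) concentrated in high terrain
— mountains are rough, lowlands smooth. Temperature is
`27 − 0.55·|lat| − 6.5·z̃/1000 + ε` °C where `z̃` is elevation smoothed
over ~4 cells: climate surfaces are interpolated between stations and
miss fine relief, and this smoothing is what keeps `temperature.dif` from
being a perfect proxy of `elevation.dif` (their raw correlation is 0.99
if the lapse acts on raw terrain, which makes semipartial attribution
meaningless). Precipitation declines and seasonality rises away from the
equator, each with small smoothed noise. Elevation is *not* clipped at
0 m: clipping ties lowland suitabilities exactly and the deterministic
tie-break would grow every range toward the northwest corner, imprinting
a spurious latitudinal richness gradient.

**Species.** Each species draws a seed cell with probability
`∝ exp(w·z / breadth)` — the clade's habitat preference on z-scored
environmental axes — and takes its optimum from the environment there.
This biased seeding is the mechanism that couples clade richness to its
driving axis: with uniform seeding, expected richness is spatially
uniform regardless of how individual ranges compress, because each
species contributes its range size somewhere. The range then grows from
the seed by greedy most-suitable-neighbor accretion (suitability = a
Gaussian kernel of |w|-weighted z-distance from the optimum; ties broken
by row-major order) to a log-normal target size (median 250 cells,
log-sd 0.75, ≥ 1, rounded up). Because greedy growth depends only on the
suitability *ranking*, `niche_breadth` cannot shape range boundaries; it
acts through the seeding concentration instead. Ranges trapped on
landmasses smaller than their target are truncated and flagged. All
randomness is seeded, with per-species generators derived from the clade
seed by counter so adding species never perturbs earlier ones.

**What passing recovery tests do and do not show.** On 40×60-cell
continents with a 150-species elevation-driven clade and a 150-species
temperature-driven clade, the full pipeline recovers the planted drivers
(top standardized coefficient per clade; `elevation.dif` top semipartial
for turnover) in ≥ 90% of seeded replicates. This demonstrates internal
consistency — the statistics can see structure the generator planted —
not that real faunas behave this way. The generator omits dispersal
barriers, biotic interactions, historical contingency, range
fragmentation, sampling error in range maps, and non-equilibrium
dynamics; with drivers as collinear as real Andean temperature and
topography, attribution would be harder than in these simulations.

## Problem sizes and defaults

Recovery experiments use 20 replicates of a 40×60 grid (2400 cells,
300 species), PCNM computed once per geometry, 30 leading filter
candidates, ≤ 8 filters, 99-permutation stopping tests; the correlogram
calibration uses a 7×7 grid, 500 replicates and 999 permutations. These
sizes give stable rates while keeping a full run in tens of seconds on
one core. Pipeline defaults (queen adjacency, absolute `.dif`, sqrt
turnover, great-circle distances, α = 0.05) are all exposed in
`PipelineConfig`, which rejects unknown keys and round-trips through
YAML; every run writes a manifest with the config hash, seed, cell
counts, filter counts and stage timings.

## Known limitations

* Rasterization is exact but O(cells × polygons); very large multi-part
  polygons should be simplified upstream.
* Correlograms build dense distance matrices; they are meant for
  diagnostic use at ≤ a few thousand cells.
* The all-subsets model selector is deliberately capped at 15 predictors.
* GeoTIFF and shapefile IO are not provided; gridded CSV and GeoJSON are
  the interchange formats.
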