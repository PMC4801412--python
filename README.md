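# betascape

Grid-based macroecology of species richness and turnover: rasterize
species range maps onto a latitude/longitude grid, map richness and
Simpson-turnover fields, and ask which environmental gradients drive them
while controlling for spatial autocorrelation with PCNM spatial filters.

The package is aimed at biogeographers working with range maps (or
presence/absence matrices) and gridded environmental layers — the classic
setting of continental diversity analyses, where a fauna's richness
hotspots hug a mountain cordillera, a second hotspot sits in coastal
forest, and the question is whether elevation, temperature, precipitation
or seasonality best explains richness and compositional turnover.

## What it computes

**Presence/absence matrix.** Each species is present in a cell when its
range polygon covers at least 50% of the cell (exact polygon–rectangle
clipping; the inclusive threshold is configurable). Richness is the cell's
column sum; the "restricted-range" subset is the quartile of species with
the smallest occupied-cell counts.

**Turnover fields.** For a focal cell and one adjacent cell with `a`
shared species, `b` exclusive to the focal and `c` exclusive to the
neighbor, the Baselga decomposition of Sørensen dissimilarity is

    βsim = min(b,c) / (a + min(b,c))          (Simpson turnover)
    βsor = (b + c) / (2a + b + c)             (total dissimilarity)
    βsne = βsor − βsim                        (nestedness-resultant)

βsim is insensitive to richness differences: nested pairs score 0. The
*neighborhood turnover* of a cell is the mean βsim against its eight
queen-adjacent land cells (fewer at coasts/edges), square-root transformed
to symmetrize its skew. Environmental predictors get the matching `.dif`
treatment: the mean absolute difference between a cell and its neighbors.

**Spatial filtering.** Moran's I and distance-class correlograms
(permutation-tested) diagnose autocorrelation. PCNM spatial filters are
built by truncating the inter-cell great-circle distance matrix at the
longest minimum-spanning-tree edge (beyond-truncation distances set to
4t), double-centering, and eigen-decomposing; eigenvectors are selected
greedily to minimize the absolute Moran's I of model residuals.

**Inference.** Filter-conditioned semipartial regression (each predictor's
independent R² and extra-sum-of-squares F), all-subsets AICc model
selection with Akaike weights and standardized coefficients, VIF
collinearity diagnostics, and Pearson correlations with latitude and
longitude.

**Synthetic continents.** Because digitized range maps are rarely
redistributable, `betascape.synth` generates virtual continents — a high
meandering ridge along one margin, latitudinal climate gradients, and
clades of species grown from niche suitability with known ground truth —
so the full pipeline is testable end to end and its power to recover
planted drivers is measurable.

## Worked example

Simulate a continent with a montane (elevation-driven) and a lowland
(temperature-driven) clade, then ask the statistics which axis drives
each pattern:

```python
import numpy as np
import betascape as bs

grid, env = bs.make_continent(bs.ContinentSpec(seed=42))
ra, _ = bs.simulate_ranges(grid, env, bs.CladeSpec(
    clade_id="montane", n_species=150, niche_axis_weights=(1, 0, 0, 0), seed=1))
rb, _ = bs.simulate_ranges(grid, env, bs.CladeSpec(
    clade_id="lowland", n_species=150, niche_axis_weights=(0, 1, 0, 0), seed=2))
pam = bs.build_pam(ra + rb, grid)

rich = bs.richness(bs.clade_subset(pam, "montane"))
print(bs.pearson(rich, env.elevation))          # 0.95

turn = bs.sqrt_transform(bs.neighborhood_turnover(pam))
difs = [bs.neighborhood_env_diff(l) for l in env.layers()]
mask = (bs.richness(pam).values >= 1) & ~turn.missing
for d in difs:
    mask &= ~d.missing
res = bs.partial_regression(turn.values[mask], bs.PredictorSet(
    names=[d.name for d in difs],
    values=np.column_stack([d.values[mask] for d in difs])))
print({k: round(v, 3) for k, v in res.semipartial_r2.items()})
# {'elevation.dif': 0.094, 'temperature.dif': 0.0,
#  'precipitation.dif': 0.009, 'seasonality.dif': 0.008}
```

Montane richness correlates with elevation at r = 0.95, and relief
(`elevation.dif`) carries an order of magnitude more independent turnover
signal than any climatic `.dif` — the planted structure, recovered. AICc
model selection on the same response ranks elevation first by
standardized coefficient (0.69 vs −0.33 for temperature, model weight
0.97).

The same analyses run from the shell:

```bash
betascape simulate --n-species 150 --seed 42 --out-dir world/
betascape rasterize --ranges world/ranges.geojson --grid world/grid.json --out pam.csv
betascape turnover --pam pam.csv --grid world/grid.json --sqrt --out turnover.csv
betascape run --config analysis.yaml   # full pipeline with manifest
```

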