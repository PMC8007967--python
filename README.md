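# fruitscape

Spatial macroecology of fruit-type composition: where on a landscape are
fleshy-fruited plant species (berries, drupes, pomes, …) concentrated
relative to dry-fruited ones (capsules, achenes, nuts, …), and what drives
that pattern — climate, ecosystem productivity, vegetation height, or the
evolutionary age of the local flora?

The package is aimed at trait biogeographers who hold species occurrence
records at the level of administrative polygons (counties, districts) rather
than points, and who need the full inferential chain that this kind of data
demands:

1. **Rasterization with an area-coverage presence rule.** Polygon-level
   occurrences are intersected with an equal-area square grid (50 km or
   100 km). A species is scored present in a cell when the summed area of
   the cell's intersections with its occupied counties strictly exceeds a
   threshold (default 1,106.66 km²). Cells with less than half their area on
   land, or with five or fewer species of the analysis group, are excluded.
2. **Per-cell trait composition.** For each retained cell: the proportion of
   fleshy-fruited species (overall and separately for trees, shrubs and
   herbs), the arithmetic mean of the maximum mature heights of its species
   (climbers, scandent shrubs and epiphytes excluded), the mean stem age of
   the set of genera present, and environmental means (MAT, MTCQ, MPWQ, AI,
   TSN, PSN, AET).
3. **Binomial GLMs.** The response is the pair (fleshy count, richness) per
   cell, fitted with a logit link by IRLS; goodness of fit is McFadden's
   R² = 1 − ℓ(model)/ℓ(null). Mean height enters as log₁₀, all predictors
   are z-scored.
4. **Spatially corrected inference.** Moran's *I*, distance-class
   correlograms, and the modified *t*-test (Dutilleul/Clifford): the
   correlation test between two spatially autocorrelated variables uses an
   effective sample size M̂ = 1 + n²/tr(B R̂ₓ B R̂ᵧ) instead of n, so
   significance is not inflated by autocorrelation.
5. **Model selection and attribution.** One predictor per environmental
   category (temperature / precipitation / seasonality / productivity) is
   prescreened from univariate fits; exhaustive BIC-based Bayesian model
   averaging ranks all predictor subsets by posterior probability; the top
   three models and their union are reported; hierarchical partitioning
   (Chevan–Sutherland) splits the combined model's goodness of fit into
   independent and joint contributions per predictor.
6. **SAR error models.** y = Xβ + u, u = λWu + ε, fitted by maximum
   likelihood with the neighborhood distance set where the response
   correlogram crosses zero; residual Moran's *I* is reported before and
   after.

Because real national-scale floras are not redistributable, the package
ships a first-class synthetic-data generator (`fruitscape.synthdata`) that
produces a planar landscape with climate/productivity surfaces, a county
tessellation with heterogeneous areas, a species pool whose fruit types
follow a known logistic model of height and productivity preference, gamma
genus stem ages, and environmentally filtered ranges — so every stage of the
chain can be validated against known generative truth.

## Worked example

```bash
fruitscape all --seed 1
```

runs the full chain on the default synthetic system (800 species, 400
counties on a 1,000 × 1,000 km landscape, 50-km grid → 400 cells) and
prints, per group (abbreviated):

```json
{
  "dataset": {
    "n_species": 800,
    "fleshy_percent": 21.875,
    "fleshy_percent_tree": 53.9,
    "fleshy_percent_shrub": 20.3,
    "fleshy_percent_herb": 11.5
  },
  "all": {
    "retained_cells": 400,
    "candidates": ["AET", "height", "age"],
    "top_model": "AET + height",
    "top_posterior": 0.904,
    "combined_r2": 0.467,
    "sar_lambda": 0.967
  }
}
```

Read this as: ~22% of the generated pool is fleshy-fruited, most prevalent
among trees and least among herbs; after prescreening, productivity (AET),
mean height and genus age are the candidate drivers; the highest-posterior
model for all species combined contains AET and height (posterior 0.90);
the combined model explains ~47% (McFadden) of the variation; and the SAR
error coefficient 0.97 reflects the strong residual spatial structure of a
smooth environmental gradient. Genus age — generated independently of fruit
type — correctly receives a small independent contribution in the
hierarchical partitioning.

The same analysis is available programmatically:

```python
from fruitscape import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
report.groups["all"].univariate       # slopes, McFadden R², corrected p
report.groups["all"].bma.top3         # top models with posteriors
report.groups["all"].hierpart.table   # independent / joint contributions
report.groups["all"].sar              # lambda, coefficients, residual Moran
```

With `--out DIR` the run also writes every table (CSV/GeoJSON/JSON) plus a
SHA-256 manifest; identical config + seed reproduce identical manifests.

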