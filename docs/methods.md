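# Methods

This note documents the statistical procedures, the synthetic study system,
the numerical choices, and the places where the design was genuinely open.

## The analysis chain

### Gridding and the presence rule

Occurrences are recorded per administrative polygon (county). For a square
grid cell c and species s, coverage(s, c) = Σ over counties occupied by s of
area(county ∩ c). Presence is declared when coverage **strictly exceeds**
the threshold (default 1,106.66 km², the area of the smallest administrative
unit in the motivating data set); the strict inequality follows the
"more than" wording of the source data protocol and is config-overridable.
The threshold is kept constant across grid resolutions by default (a knob
exists to scale it with cell area). Coverage values are retained alongside
the presence bit so every presence decision is auditable.

Cell filters, both strict: land_area ≥ 0.5 × cell area (1,250 km² at 50 km,
5,000 km² at 100 km) and group richness > 5 (sensitivity variant: > 10).
Counties larger than a configurable `max_county_km2` are guillotine-split
into ≤ 4 quadrant parts before intersection; since no occurrence downscaling
is attempted, the split provably leaves summed coverages unchanged (tested),
and exists for geometry-refinement parity with protocols that subdivide
oversized desert counties.

### Per-cell metrics

* prop_fleshy_g = fleshy_g / richness_g per group g ∈ {all, herb, shrub,
  tree}. Growth-form mapping: tree→tree; shrub, woody liana, scandent
  shrub→shrub; herb, herbaceous liana, subshrub, climber, epiphyte→herb.
  The last three labels are additionally flagged height-excluded. The core
  six-label mapping follows the field convention (woody lianas with shrubs,
  herbaceous lianas and subshrubs with herbs); climbers and epiphytes lack
  self-supporting stature, so pooling them with herbs is this package's
  choice — they carry no height signal anyway because they are excluded
  from the height means.
* mean_height_m: arithmetic mean of maximum mature heights of the present,
  height-eligible species. The log₁₀ transform is applied to the per-cell
  mean at the modelling stage, not to per-species heights (base 10 chosen,
  config-overridable; the convention in the trait literature is a log
  transform without a stated base).
* mean_genus_age_Ma: mean stem age over the **set** of genera present —
  each genus counts once regardless of its species number in the cell.
  Genera without ages are omitted (not imputed) and counted in the log.
* Environmental means: average of the environmental-raster cells whose
  centres fall inside the grid cell.
* Standardization (z-scores) is computed per analysis group over that
  group's retained cells, because each group's model uses its own cell set;
  means/sds are stored for back-transformation.

### Binomial GLMs

Response per cell: (fleshy count k, richness n), binomial with logit link,
fitted by IRLS to max|Δβ| < 1e-8 (≤ 100 iterations). Cells are thereby
weighted by their richness, which is what modelling "percentages of
species" with a binomial likelihood implies; unweighted proportions were
rejected. The log-likelihood includes the binomial normalizing constant so
AIC/BIC are comparable across models. McFadden R² = 1 − ℓ/ℓ₀ with ℓ₀ the
intercept-only likelihood on the same cells. Guards: rank-deficiency error
naming suspect columns; a separation error when fitted proportions reach
1e-12 / 1−1e-12 (divergent coefficients are never returned). No
quasi-binomial overdispersion correction is applied — a known limitation;
per-cell species counts are treated as independent Bernoulli draws.

### Spatial statistics

* **Moran's I** with expectation −1/(n−1), randomization variance
  (Cliff–Ord S₀/S₁/S₂ with the kurtosis term), two-sided normal p.
* **Correlogram**: equal-width distance classes up to half the maximum
  pairwise distance, default 13 classes; Moran coefficient per class with
  class-membership binary weights. The zero crossing is linearly
  interpolated between the last positive and first non-positive class; if
  the first non-empty class is already non-positive the first midpoint is
  returned (flagged); if the coefficient never crosses, the maximum
  considered distance is returned (flagged). The class count is a
  convention (config knob) — only the "crosses zero" procedure matters.
* **Modified t-test**: spatial correlation matrices R̂ₓ, R̂ᵧ are assembled as
  I + Σₖ ρ̂ₖ Aₖ from per-class Moran coefficients ρ̂ₖ on classes spanning the
  full distance range; with centering operator B = I − 11ᵀ/n the effective
  sample size is M̂ = 1 + n²/tr(B R̂ₓ B R̂ᵧ), clipped to (2, n]; t = r·√((M̂−2)
  /(1−r²)) on Student t with M̂−2 df. Forcing both matrices to identity
  reproduces the classical test exactly (df = n−2 via the clip), which is
  tested to 1e-10. M̂ ≤ 2 after clipping yields p = 1 with a flag.
* **SAR error model** y = Xβ + u, u = λWu + ε on the raw proportion scale
  ("linear" response; an empirical-logit option exists). Profile likelihood
  over λ in the interval set by the extreme eigenvalues of W; per λ the data
  are whitened by (I − λW) and β, σ² follow by least squares; the Jacobian
  term Σ log(1 − λeᵢ) uses dense eigenvalues computed once (target n ≲
  4,000 cells, O(n³) once per weights matrix). Bounded Brent search to
  1e-8; boundary λ flagged. Residual autocorrelation is reported for both
  the OLS residuals (pre-SAR) and the whitened innovations (I − λW)(y − Xβ̂).
* **Weights**: distance band 0 < d ≤ d*, symmetric before row
  standardization, islands keep zero rows and are flagged. d* is the
  response correlogram's zero crossing, floored at 1.5 × the grid
  resolution so no cell is isolated.
* Two-sided p-values throughout.

One caveat observed on the synthetic system: because the neighborhood
distance is by construction the scale where the response's autocorrelation
vanishes, pre-SAR residual Moran's I at that scale can already be near
zero; the innovations then are not always smaller in that one metric. Where
pre-SAR autocorrelation is substantial the SAR reduces it (tested), and on
data simulated from the SAR model itself the reduction always holds.

### Model selection and attribution

* **Prescreen**: each multi-member category (temperature {MAT, MTCQ},
  precipitation {MPWQ, AI}, seasonality {TSN, PSN}, productivity {AET, NPP,
  GPP}) contributes its highest-univariate-R² member, unless no member is
  significant under the modified t-test (corrected p < α = 0.05), in which
  case the category is dropped. Height and age are singletons and pass
  through.
* **BMA**: all 2^k binomial GLMs (k ≤ 12 enforced; exhaustive enumeration
  replaces branch-and-bound since k ≤ 5 in practice); BIC = −2ℓ + p·ln n;
  posterior ∝ exp(−ΔBIC/2); Occam's window discards models with posterior
  odds vs the best above 20 (the conventional default) before
  renormalization. Reported: ranked models, top 3, per-predictor inclusion
  probabilities, and the **combined model**, defined as the GLM on the union
  of the top-3 predictor sets — the union convention is this package's
  choice for an otherwise undefined "combined" row.
* **Corrected p for multivariate models**: the modified t-test between
  observed and fitted proportions — a single documented convention used
  everywhere a whole-model p is reported.
* **Hierarchical partitioning** (Chevan–Sutherland): goodness of fit is the
  reduction in root-mean-square error between observed and fitted
  proportions relative to the null model (orientation chosen so useful
  predictors score positive; the literature names root-mean-square as the
  binomial GOF without an orientation). I_j averages the marginal GOF gain
  of predictor j over all subsets by hierarchy level; J_j = GOF({j}) − I_j.
  The identity Σ I_j = GOF(full) is asserted at run time to 1e-8. A
  log-likelihood GOF is available; on orthogonal designs it makes the
  decomposition nearly additive (joint ≈ 0), which the RMS scale does not
  guarantee because RMS is nonlinear in the linear predictor.

## The synthetic study system

The generator emulates the *structure* of a county-level national flora
analysis; it makes no claim about any real flora (the motivating study is
observational and specifies no generative model — every distribution below
is a testing scaffold chosen once).

* **Landscape**: planar rectangle in km (equal-area by construction; no
  geographic CRS). Default 40 × 40 raster of 25-km cells (1,000 × 1,000
  km). MAT falls northward at 0.02 °C/km from 22 °C (a latitudinal proxy);
  MPWQ rises eastward at 0.5 mm/km from 100 mm; AET = 150 + 8·MAT +
  0.6·MPWQ — monotone in its energy and water inputs — plus spatially
  smoothed Gaussian noise; AI tracks MPWQ; TSN/PSN carry weak gradients and
  noise. Noise amplitudes scale with a single `noise_sd` multiplier
  (default 1).
* **Counties**: ~400 rectangles from recursive guillotine splits, target
  areas drawn with CV 0.6 (mean area 2,500 km², echoing the size
  heterogeneity of real county tessellations); realized areas equal targets
  and tile the extent exactly.
* **Species pool**: 800 species, form mix herb 0.55 / shrub 0.27 / tree
  0.18; maximum heights lognormal per form (medians ≈ 15, 2, 0.45 m; the
  ordering tree > shrub > herb is enforced by construction). Each species
  has an environmental optimum on the standardized AET axis, correlated
  with its (within-form standardized) log height at ρ = 0.7 — taller floras
  concentrate in productive regions, as observed for real vegetation.
  Fruit type: P(fleshy) = logistic(−2.3 + 2.0·log₁₀(height) + 0.8·z_opt).
  These defaults were fixed once so the pool is ≈ 20% fleshy with the
  tree > shrub > herb ordering and a genuine, spatially structured height
  signal. Genus stem ages ~ Gamma(2, 20) Ma, independent of fruit type by
  default (an optional coupling knob exists to induce an age–fleshiness
  correlation for testing); ~100 genera, every genus non-empty.
* **Ranges**: a centroid county is drawn with probability decaying in the
  mismatch between county AET and the species optimum (softness 0.5 z);
  the species occupies all counties within a lognormal radius (median 300
  km, σ_log 0.7) whose AET lies within ±1.5 z of its optimum; the centroid
  county is always occupied.
* **Determinism**: every stage takes an explicit seed; the pipeline derives
  stage seeds from one master seed; generative parameters are serialized
  next to each dataset.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: taxonomic sampling biases, range cohesion beyond
a disc, elevational heterogeneity, phylogenetic autocorrelation of traits,
spatially varying recording effort, and real county shapes. The end-to-end
tests demonstrate that the chain recovers known drivers under its own
assumptions, not that those assumptions hold in any real flora.

## Problem sizes

Default pipeline runs use 400 grid cells at 50 km (the coarse variant uses
100 cells at 100 km) and 800 species; simulation-based checks use 200
replicates at n = 300 cells (modified-t calibration), a 30 × 30 rook grid
(SAR recovery), and 20 pipeline replicates (end-to-end recovery). These
sizes were chosen so the complete validation suite runs in well under an
hour on a single core while keeping every estimator comfortably inside its
asymptotic regime.

## Known limitations

* No overdispersion correction in the binomial GLMs.
* SAR on the raw proportion scale can in principle produce fitted values
  outside [0, 1]; the empirical-logit option avoids this at the cost of
  changing the response definition.
* The modified t-test's per-class Moran estimates are noisy at small n;
  M̂ is clipped to (2, n] but not smoothed across classes.
* Dense eigenvalue/trace computations bound the practical cell count at a
  few thousand.
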