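# Methods

This note records the models and procedures implemented in `fireflora`,
the assumptions behind them, the defaults that matter, and what the
synthetic test system does and does not establish.

## Fire-layer reconstruction

**Model.**  A burnt cell is a 2.5 × 2.5 km equal-area grid cell containing
at least one retained hotspot.  Retention is per satellite family:
geostationary (Himawari-8) records need brightness temperature
T > 500 K; MODIS (Aqua/Terra) records need T > 0 K and detection
confidence > 50%; VIIRS (Suomi NPP) records carry confidence only and need
> 50%.  All inequalities are strict.  The season window (default
2019-07-01 to 2020-02-11, inclusive of both end dates) bounds timestamps.

**Projection and grid.**  Area metrics require equal-area cells, so
coordinates are projected before gridding.  For synthetic scenarios and as
the default for geographic input the package uses a local Lambert
azimuthal equal-area projection on the authalic sphere
(R = 6 371 008.8 m), centred on the extent.  Cells are half-open
[x, x+Δ) × [y, y+Δ): a point on a shared edge belongs to the
higher-index cell, so cells partition the plane and every record lands in
exactly one cell.

**Relative temperature.**  Per cell, the Himawari maximum takes
precedence; the pooled Aqua/Terra maximum is used only when no Himawari
temperature fell in the cell; VIIRS never contributes temperature.
Rescaling bounds (400–1999.9 K Himawari, 302.1–506 K MODIS) are treated as
dataset extremes, so T_R values outside [0, 1] (possible for synthetic
inputs) are clipped.  Class bins have inclusive upper edges: T_R = 0.25 is
Low, 0.50 Medium, 0.75 High.  Confidence-only cells get a distinct
no-data class and are excluded from every temperature-based statistic.

**Polygonisation.**  Fire components use 8-connectivity (queen), so fires
that touch diagonally merge — the behaviour that produces merged megafire
complexes.  A component is discarded iff its area is ≤ 25 km² (inclusive,
as printed in the rule it implements) *and* no member cell has a Himawari
maximum above 1000 K.  Refugia — unburnt components enclosed by a single
fire — use 4-connectivity (rook) so that a diagonal chain of unburnt
cells cannot "leak" out of a fire; components touching the grid boundary
or adjoining two different fires are not refugia.  Both connectivity
choices are configurable.  Size labels: megafire above 100 000 ha
(strict), major at 50 000–100 000 ha; the printed definition leaves the
exact 0.100-Mha boundary ambiguous and the package closes the gap on the
major side.  Refugia above 5 000 ha are flagged large.

## Vegetation impact

The vegetation raster is aligned to the fire grid (majority-rule
resampling when resolutions differ; ties break toward the smaller code).
A cell straddling a bioregion boundary belongs to the bioregion containing
its centre.  FG_I and PF_T are exact cell counts times the cell area —
no polygon intersection areas are involved, so the conservation identity
(stratum burnt areas sum to the layer total) holds exactly.  PF_T
denominators exclude cells outside every bioregion or vegetation class
(no-data); I_H is computed on burnt, temperature-classed cells only, and
"no classed burnt cell" (category NONE) is deliberately distinct from a
low score (category E requires I_H > 25).

## Species-level burn fractions

Cleaning drops records that are positively identified as unusable
(cultivated, introduced, taxonomically suspect flags; collection year
before 1950; coordinate precision worse than 25 000 m).  Records with
*missing* year or precision are retained: the screen removes identified
bad records, not unknowns.  Exact coordinate duplicates are removed per
taxon before cropping to the study extent; for exact duplicates the order
of deduplication and cropping cannot change the result.

A location counts as burnt when its 2.5 km fire-grid cell is burnt —
consistent with the fire layer's resolution rather than a finer
point-in-polygon test.  PF_SR uses unique record locations; PF_BR uses
occupied cells and is therefore invariant to repeat collections at a
site.  RE_T is the maximum pairwise haversine distance (spherical radius
6 371.0088 km), a CRS-independent choice; range classes have
lower-inclusive bounds (RE_T = 25 km is range-restricted, not very
range-restricted).  Endemism compares unique records inside and outside
the study box: any record outside makes a taxon at best near-endemic
(≤ 10% outside).

## Distribution models and thresholds

The presence–background model is a penalised binomial regression (ridge,
C = 1) on linear + quadratic features of the 21 standardised predictors;
the linear predictor is mapped through the complementary log-log function
to a [0, 1] occurrence scale.  This is a deliberately transparent
maximum-entropy-style surrogate: with linear + quadratic features it spans
the same response shapes as the common default feature classes, and the
package's contribution — thresholding, the TPR screen, the discordance
rule and the PF_M combination — operates identically on any [0, 1]
surface.  Exact parity with any particular MaxEnt release is a non-goal.

Thresholds are found by brute force over all candidate values (the unique
scores of presences and background plus ∓∞ sentinels); ties resolve to
the smallest maximiser, making the search deterministic and
oracle-checkable.  P10 is the lower-value (inverted-CDF) percentile: the
(⌊0.1·n⌋+1)-th smallest presence score, which guarantees strict-below
omission ≤ 10% with ties kept at the threshold.  Kappa-based ranges with
training TPR < 0.80 are suppressed (they underfit disjoint
distributions).  When PF_MTSS − PF_K ≥ 0.2 and PF_MTSS − PF_10 ≥ 0.2 the
taxon is flagged discordant; the published workflow resolved such cases
by expert inspection, which cannot be encoded, so the package substitutes
a deterministic policy (default: keep the conservative kappa estimate, or
none when it is invalid) and reports the flag for review.  In the
concordant case PF_SDM defaults to max(valid PF_K, PF_MTSS) — consistent
with the conservative maximum convention used for PF_M, since unsampled
populations can only be missed; `mtss_only` and `kappa_only` policies are
available.  Background points are drawn uniformly with replacement from
finite-predictor cells and may coincide with presence cells (standard
presence–background practice); the seed is mandatory.

## Statistics

* Kruskal–Wallis with tie correction; an all-identical sample yields
  χ² = 0, p = 1 rather than an error.
* Pairwise Wilcoxon rank-sum tests: exact p when the pooled sample is
  ≤ 20 without ties, otherwise the normal approximation with continuity
  correction; Benjamini–Hochberg step-up adjustment.
* Quantile regression: interior-point fit per τ; slope confidence
  intervals by inverting the regression rank-score test (the classical
  rank method) with expanding-bracket bisection on the monotone step
  statistic; significance means the 95% interval excludes zero.
* Skewness is the moment estimator g1 = m3/m2^{3/2} (no small-sample
  correction), matching the common "moments" convention; normality via
  Shapiro–Wilk (3 ≤ n ≤ 5000).
* Pearson χ² without continuity correction (general r × c case).
* One-way ANOVA on log10(x+1)-transformed values with Tukey HSD.

The framework types dichotomise range extent at < 100 km (restricted)
and ≥ 500 km (widespread); species in between are left unclassified where
the dichotomy matters (types A, C, D, E), an explicit interpretation of a
conceptual axis, and both cut-offs are configurable.  The life-form ×
range-class contingency analysis collapses the 16 life forms to six
groups (low/medium/tall shrubs, trees, perennial forbs, other) and four
range classes (< 25, 25–100, 100–500, > 500 km).

## Synthetic study system

The generator emulates the statistical structure the analysis depends on,
not the physics of fire or the biology of real floras:

* **Landscape** — 21 predictor layers as Gaussian-filtered noise plus a
  random linear gradient on a 1 km grid (default extent ≈ 500 × 500 km,
  hence a 200 × 200 fire grid); a 5-class vegetation raster thresholded
  from two layers plus scattered cleared cells; four rectangular
  bioregions.
* **Fires** — 12 scars grown from ignition points with log-uniform target
  sizes (30 000–2 500 000 ha), ignitions biased toward the eastern
  ("coastal") side so large western areas stay unburnt and true burn
  fractions span the full range; scars may touch and merge into
  complexes.  Typically 20–35% of the landscape burns.  Hotspot emission:
  every burnt cell emits records with a satellite mixture; core cells
  (≥ 2 cells from the edge) emit hot geostationary records up to
  ~1800 K, margins 450–1100 K — sometimes below the retention floor,
  giving genuine under-detection; ~12% of burnt cells are seen only by
  the confidence-only satellite (no-data class); spurious 1–3-cell
  clusters with temperatures ≤ 1000 K and sub-threshold noise records
  are injected and must be removed by the reconstruction rules.
* **Flora** — true ranges are the contiguous patch of a two-predictor
  environmental envelope around a focal cell, widened until the patch
  reaches an area target derived from a lognormal extent draw
  (median ≈ 55 km), giving the strong positive range-size skew the
  downstream analyses assume.  Disjoint same-environment patches
  elsewhere are *not* part of the true range, which reproduces the
  known overestimation mode of sensitivity-based thresholds that the
  discordance screen exists to catch.  Records (mean 90 per species,
  matching large-herbarium sampling density) are drawn uniformly over
  range cells, then inflated with repeat collections at up to three
  favourite sites (exact coordinate repeats — the roadside-bias
  analogue), exact duplicates, pre-1950 years, coarse coordinates and
  cultivated flags; cleaning removes all of these, so the surviving
  unique locations are an unbiased sample of the range and PF_SR
  recovery is governed by binomial error.  Traits are drawn with a 93%
  persister fraction and configurable rainforest-class probabilities.

All randomness flows from a single integer seed through deterministic
child streams; identical configurations give byte-identical fixture
bundles.

**What passing tests show** — that the reconstruction rules remove the
injected noise and recover the true burnt-cell set (Jaccard ≥ 0.85 at
default conditions), that cleaned direct estimates recover true burn
fractions within binomial error, that ranked species impact is preserved
end-to-end (Spearman ≥ 0.9 across 300 species), and that the model-based
route tracks truth for envelope-defined ranges.  **What they do not
show** — performance on real data with taxonomic noise, spatially
structured detection failure (cloud cover), non-envelope range shapes, or
vegetation-dependent fire behaviour; none of these are modelled.

## Problem sizes and numerical choices

Default scenario: 200 × 200 fire grid, 500 × 500 env grid, 300 species,
10 000 background points — a complete run takes a few minutes on one CPU.
Envelope widths are found by 16-step bisection; threshold searches are
exact over all candidates; the logistic fit uses L-BFGS (max 500
iterations); cloglog exponents are clipped at ±30 to avoid overflow;
degenerate inputs (no finite predictor cells, < 10 unique presences,
zero-variance predictors, constant quantile-regression regressor,
zero contingency marginals) raise explicit errors rather than returning
numbers.
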