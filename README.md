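# fireflora

Reconstruction of fire extent from satellite hotspot records, and
quantification of the resulting burn impact on vascular plant species and
vegetation communities.

## The problem

After a major fire season, two questions dominate conservation triage:
*where did it burn, and how hot?* and *which species lost most of their
range?*  `fireflora` answers both from widely available inputs — raw
thermal-anomaly ("hotspot") records from geostationary and polar-orbiting
satellites, herbarium occurrence records, a categorical vegetation raster,
bioregion polygons and a stack of environmental predictor grids — and is
aimed at fire ecologists and conservation biogeographers who need a
reproducible, scriptable version of this workflow.

## The method

**Fire layer.**  Hotspots are screened (Himawari-8 kept when brightness
temperature T > 500 K; Aqua/Terra MODIS when T > 0 K and confidence > 50%;
Suomi NPP VIIRS when confidence > 50%), projected to an equal-area CRS and
gridded at 2.5 × 2.5 km, keeping per-satellite cell maxima T_M.  Cell
temperatures are rescaled to a relative fire temperature

    T_R = (T_M − T_min) / (T_max − T_min)

with family bounds 400–1999.9 K (Himawari-8) or, when no Himawari
temperature exists in a cell, 302.1–506 K (MODIS), then binned Low
(0–0.25), Medium (>0.25–0.50), High (>0.50–0.75), Very High (>0.75–1.0),
with a no-data class for confidence-only cells.  Contiguous burnt cells
are polygonised into fires; components ≤ 25 km² lacking any cell above
1000 K are discarded as spurious.  Fires above 0.1 Mha are megafires;
interior unburnt islands enclosed by a single fire are refugia.

**Vegetation impact.**  For each vegetation stratum (Major Vegetation
Group × bioregion, or broad vegetation type) the package reports the burnt
area FG_I, the percentage burnt PF_T, and the hot-fire score

    I_H = 100 · (A_VH + A_H) / A_TOT

where A_TOT is the stratum's burnt, temperature-classed area, with A–E
severity categories and a Table-style report of strata with PF_T > 50% and
I_H > 25%.

**Species impact.**  Occurrence records are cleaned (cultivated,
introduced, taxonomically suspect, pre-1950 and coarse-coordinate
(> 25 km) records dropped; exact spatial duplicates removed; cropped to
the study extent).  Per taxon the package computes PF_SR (fraction of
unique locations in burnt cells), PF_BR (fraction of occupied 2.5 km cells
burnt — robust to roadside oversampling), the maximum range extent RE_T
(greatest geodesic distance between records) with six range classes, and
an endemism class.

**Distribution models.**  For taxa with ≥ 10 unique locations a
presence–background model (penalised binomial regression on linear +
quadratic standardised predictors, cloglog-scaled output) is fitted
against 10 000 background points over 21 environmental layers.  The
surface is thresholded at max-kappa, max sensitivity+specificity (MTSS)
and the 10th-percentile training presence (P10); each binary range is
overlaid with the fire layer giving PF_K, PF_MTSS, PF_10.  Kappa ranges
with training TPR < 0.80 are discarded; when PF_MTSS exceeds both others
by ≥ 0.2 the case is flagged discordant and a deterministic policy keeps
the conservative kappa estimate.  The species-wide estimate is
PF_M = max(PF_SR, PF_BR, PF_SDM), with support classes 1–7 recording which
estimates individually exceed 0.50.

**Traits and statistics.**  Resprouting (R±) × propagule persistence (P±)
give four fire-response types and a persister flag; a range ×
persistence × fire-history framework assigns Types A–E.  The statistical
battery covers Kruskal–Wallis tests with pairwise Wilcoxon/BH post hocs,
linear quantile regression of PF_M on RE_T (τ = 0.1…0.9) with rank-based
confidence intervals, one-way ANOVA (log10(x+1)) with Tukey HSD, Pearson
χ² contingency tests, and distribution shape (moment skewness,
Shapiro–Wilk W).

**Synthetic data.**  A seeded generator produces the whole study system —
autocorrelated predictor stacks, vegetation and bioregions, growing fire
scars emitting noisy multi-satellite hotspots (plus spurious clusters and
sub-threshold noise), and a virtual flora with envelope-based true ranges,
lognormal range extents, sampling bias, duplicates and contamination —
together with ground truth (true burn mask, true per-species burn
fractions) so every stage can be verified without downloads.

## Worked example

```python
from fireflora import (SyntheticConfig, generate_scenario, run_scenario,
                       recovery_metrics)

scenario = generate_scenario(SyntheticConfig(seed=7, n_species=50))
results = run_scenario(scenario)
layer = results["layer"]
print(f"fires: {len(layer.fires)}  burnt: {layer.total_burnt_area_ha/1e6:.2f} Mha")
print(results["species"].head())
print(recovery_metrics(scenario, results))
```

prints (abridged):

```
fires: 11  burnt: 4.30 Mha
            taxon  n_records  pf_sr  pf_br  pf_sdm  pf_m  support_class  re_t_km range_class
Synthspecies 0000         79   0.00  0.000   0.000 0.000            NaN   78.655          RR
Synthspecies 0004         77   0.61  0.613   0.556 0.613            7.0  152.788          MW
{'burn_mask_jaccard': 0.9996, 'spearman_true_pf_vs_pf_m': 0.937,
 'pf_sr_within_0.1_fraction': 0.98, 'n_species_compared': 50,
 'n_species_30plus_records': 50}
```

Eleven fires were reconstructed covering 4.30 Mha.  Species 0000 is a
range-restricted taxon entirely outside the fires (all burn fractions 0);
species 0004 had 61% of its unique locations, cells and modelled range
burnt, exceeding the 0.5 high-impact criterion with all three estimates in
agreement (support class 7).  The recovery metrics compare the pipeline's
output with the generator's ground truth: the reconstructed burnt-cell set
matches the true mask almost exactly (Jaccard 0.9996), ranked species burn
fractions track the truth (Spearman 0.94), and 98% of well-sampled species
have PF_SR within 0.1 of their true burn fraction.

The same stages are scriptable from the shell:

```
fireflora simulate --seed 1 --out bundle/
fireflora fire-layer --hotspots bundle/hotspots.csv \
    --extent 147.32,-35.25,152.68,-30.75 --out layer/
fireflora species-impact --occurrences bundle/occurrences.csv \
    --fire-layer layer/ --extent 147.32,-35.25,152.68,-30.75 --out species.csv
fireflora run-all --seed 1 --out results/
```

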