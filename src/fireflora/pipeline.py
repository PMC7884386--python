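"""End-to-end orchestration: hotspots -> fire layer -> impact tables.

Glue over the stage modules, used by the ``run-all`` command, the test
suite and the acceptance script.  Also provides recovery metrics against
a synthetic scenario's ground truth.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import sdm as sdm_mod
from . import species_impact as sp_mod
from . import traits_stats as ts_mod
from . import vegetation_impact as veg_mod
from .fire_layer import FireLayer, FireLayerConfig, build_fire_layer
from .synthetic_data import Scenario

logger = logging.getLogger(__name__)


def run_species_stage(cleaned: pd.DataFrame, layer: FireLayer,
                      env=None, seed: int = 0,
                      sdm_config: sdm_mod.SDMConfig | None = None,
                      all_records: pd.DataFrame | None = None,
                      study_extent=sp_mod.DEFAULT_STUDY_EXTENT) -> pd.DataFrame:
    """Direct metrics for every taxon, plus model-based PF where possible."""
    cfg = sdm_config or sdm_mod.SDMConfig()
    table = sp_mod.build_species_table(cleaned, layer,
                                       all_records=all_records,
                                       study_extent=study_extent)
    pf_sdm = {}
    extras: dict[str, dict] = {}
    flags = {}
    if env is not None and len(table):
        background = sdm_mod.sample_background(env, cfg.n_background, seed)
        env_burnt = sdm_mod.env_cell_burnt_mask(env, layer)
        for taxon, df in cleaned.groupby("taxon", sort=True):
            cells = sdm_mod.presence_cells_from_lonlat(
                df["longitude"], df["latitude"], env)
            try:
                res = sdm_mod.fit_sdm(taxon, cells, env, background, cfg)
            except sdm_mod.SDMRefusal as exc:
                logger.info("SDM refused: %s", exc)
                continue
            sdm_mod.compute_thresholds(res)
            sdm_mod.derive_pf_sdm(res, layer, env, policy=cfg.policy,
                                  env_burnt=env_burnt)
            pf_sdm[taxon] = res.pf_sdm
            extras[taxon] = {"pf_k": res.pf_k, "pf_mtss": res.pf_mtss,
                             "pf_10": res.pf_10, "tpr_kappa": res.tpr_kappa}
            flags[taxon] = res.flags
    table["pf_sdm"] = table["taxon"].map(pf_sdm).astype(float)
    for col in ("pf_k", "pf_mtss", "pf_10", "tpr_kappa"):
        table[col] = table["taxon"].map(
            {t: e[col] for t, e in extras.items()}).astype(float)
    combined = [sdm_mod.combine_pf(r.pf_sr, r.pf_br,
                                   None if pd.isna(r.pf_sdm) else r.pf_sdm)
                for r in table.itertuples()]
    table["pf_m"] = [c[0] for c in combined]
    table["support_class"] = [c[1] for c in combined]
    table["high_impact"] = [c[2] for c in combined]
    table["sdm_discordant"] = table["taxon"].map(
        {t: f["discordant"] for t, f in flags.items()})
    return table


def run_scenario(scenario: Scenario, with_sdm: bool = True,
                 fire_config: FireLayerConfig | None = None) -> dict:
    """Run the whole pipeline on a synthetic scenario."""
    land = scenario.landscape
    layer = build_fire_layer(scenario.hotspots, land.fire_grid,
                             fire_config, build_geometry=False)
    strata = veg_mod.StratumLayers(
        mvg=land.mvg,
        bioregion=veg_mod.rasterise_bioregions(land.bioregions, land.fire_grid))
    impacts = veg_mod.compute_burnt_area(layer, strata)
    severity = veg_mod.severity_report(impacts)

    w, s, e, n = scenario.config.extent
    cleaned = sp_mod.clean_occurrences(scenario.occurrences,
                                       study_extent=(w, s, e, n))
    species = run_species_stage(cleaned, layer,
                                env=land.env if with_sdm else None,
                                seed=scenario.config.seed,
                                study_extent=(w, s, e, n))
    report = ts_mod.species_report(species, scenario.traits,
                                   quantiles=len(species) >= 20)
    return {"layer": layer, "strata": strata, "impacts": impacts,
            "severity": severity, "cleaned": cleaned, "species": species,
            "report": report}


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    union = np.logical_or(mask_a, mask_b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(mask_a, mask_b).sum() / union)


def recovery_metrics(scenario: Scenario, results: dict) -> dict:
    """Compare pipeline outputs with the scenario's ground truth."""
    layer = results["layer"]
    species = results["species"].copy()
    truth = pd.DataFrame([
        {"taxon": t, "true_pf": d["true_pf"]}
        for t, d in scenario.truth.species.items()])
    merged = species.merge(truth, on="taxon", how="inner")
    rho = spearmanr(merged["true_pf"], merged["pf_m"]).statistic \
        if len(merged) >= 3 else np.nan
    big = merged[merged["n_records"] >= 30]
    sr_ok = (np.abs(big["pf_sr"] - big["true_pf"]) <= 0.1).mean() \
        if len(big) else np.nan
    return {
        "burn_mask_jaccard": jaccard(layer.burnt_mask, scenario.truth.burn_mask),
        "spearman_true_pf_vs_pf_m": float(rho),
        "pf_sr_within_0.1_fraction": float(sr_ok),
        "n_species_compared": int(len(merged)),
        "n_species_30plus_records": int(len(big)),
    }
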