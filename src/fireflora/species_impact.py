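"""Specimen-record cleaning and direct species-level burn metrics.

For each taxon with cleaned, spatially unique location records the module
computes two direct estimates of the proportion of the species burnt —
``pf_sr`` (fraction of unique record locations falling in burnt cells) and
``pf_br`` (fraction of occupied 2.5 km grid cells that are burnt, which
discounts oversampling of easily reached sites) — plus the maximum range
extent ``re_t_km`` (greatest geodesic distance between any two records)
with its size class, and an endemism class relative to the study extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fire_layer import FireLayer, GridSpec
from .geo import max_pairwise_distance_km

logger = logging.getLogger(__name__)

ENDEMIC, NEAR_ENDEMIC, NON_ENDEMIC = "ENDEMIC", "NEAR_ENDEMIC", "NON_ENDEMIC"

#: Range-extent classes (km), lower-inclusive boundaries.
RANGE_CLASSES = (("XRR", 0.0, 10.0), ("VRR", 10.0, 25.0), ("RR", 25.0, 100.0),
                 ("MW", 100.0, 500.0), ("VW", 500.0, 1000.0),
                 ("EW", 1000.0, np.inf))

#: South-east mainland study extent (west, south, east, north), degrees.
DEFAULT_STUDY_EXTENT = (144.01, -39.17, 154.0, -25.34077)

OCCURRENCE_COLUMNS = ["taxon", "family", "longitude", "latitude", "year",
                      "coord_precision_m", "cultivated", "introduced",
                      "taxonomy_suspect"]


@dataclass
class CleaningRules:
    """Record-level exclusion rules; missing year/precision are retained."""

    min_year: int = 1950                 # strict <  -> dropped
    max_precision_m: float = 25_000.0    # strict >  -> dropped
    drop_cultivated: bool = True
    drop_introduced: bool = True
    drop_taxonomy_suspect: bool = True


def _flag(df: pd.DataFrame, col: str) -> pd.Series:
    if col not in df.columns:
        return pd.Series(False, index=df.index)
    return df[col].fillna(False).astype(bool)


def clean_occurrences(records: pd.DataFrame,
                      study_extent: tuple[float, float, float, float] = DEFAULT_STUDY_EXTENT,
                      rules: CleaningRules | None = None) -> pd.DataFrame:
    """Apply quality screens, deduplicate exact coordinates per taxon and
    crop to the study extent; removal counts are logged per rule.

    Taxa with no surviving records simply have no rows in the result.
    """
    rules = rules or CleaningRules()
    df = records.copy()
    n0 = len(df)

    drop = _flag(df, "cultivated") if rules.drop_cultivated else pd.Series(False, index=df.index)
    n_cult = int(drop.sum())
    intro = _flag(df, "introduced") if rules.drop_introduced else pd.Series(False, index=df.index)
    n_intro = int((intro & ~drop).sum())
    drop |= intro
    tax = _flag(df, "taxonomy_suspect") if rules.drop_taxonomy_suspect else pd.Series(False, index=df.index)
    n_tax = int((tax & ~drop).sum())
    drop |= tax

    year = pd.to_numeric(df.get("year"), errors="coerce")
    old = year < rules.min_year  # NaN compares False -> retained
    n_old = int((old & ~drop).sum())
    drop |= old

    prec = pd.to_numeric(df.get("coord_precision_m"), errors="coerce")
    coarse = prec > rules.max_precision_m
    n_coarse = int((coarse & ~drop).sum())
    drop |= coarse

    df = df[~drop]

    before = len(df)
    df = df.drop_duplicates(subset=["taxon", "longitude", "latitude"])
    n_dupe = before - len(df)

    w, s, e, n = study_extent
    inside = (df["longitude"].between(w, e)) & (df["latitude"].between(s, n))
    n_out = int((~inside).sum())
    df = df[inside]

    logger.info("clean_occurrences: %d -> %d records (cultivated %d, "
                "introduced %d, taxonomy %d, pre-%d %d, precision %d, "
                "duplicates %d, outside extent %d)", n0, len(df), n_cult,
                n_intro, n_tax, rules.min_year, n_old, n_coarse, n_dupe, n_out)
    dropped_taxa = set(records["taxon"].unique()) - set(df["taxon"].unique())
    if dropped_taxa:
        logger.info("clean_occurrences: %d taxa lost all records", len(dropped_taxa))
    return df.reset_index(drop=True)


def classify_endemism(all_records: pd.DataFrame,
                      study_extent: tuple[float, float, float, float] = DEFAULT_STUDY_EXTENT,
                      near_endemic_max_fraction: float = 0.10) -> str:
    """Endemism of one taxon from all its unique records in the wider
    download extent: endemic if none fall outside the study box, near-endemic
    if at most ~10% do, non-endemic otherwise."""
    uniq = all_records.drop_duplicates(subset=["longitude", "latitude"])
    if len(uniq) == 0:
        raise ValueError("taxon has no records")
    w, s, e, n = study_extent
    outside = ~(uniq["longitude"].between(w, e) & uniq["latitude"].between(s, n))
    frac = outside.sum() / len(uniq)
    if frac == 0:
        return ENDEMIC
    if frac <= near_endemic_max_fraction:
        return NEAR_ENDEMIC
    return NON_ENDEMIC


def locations_to_cells(lons, lats, grid: GridSpec):
    """Map lon/lat arrays to fire-grid (row, col); returns (row, col, inside)."""
    row, col = grid.lonlat_to_rowcol(np.asarray(lons, float), np.asarray(lats, float))
    return row, col, grid.inside(row, col)


def compute_pf_direct(lons, lats, layer: FireLayer,
                      burnt_mask: np.ndarray | None = None) -> tuple[float, float]:
    """(pf_sr, pf_br) for one taxon's spatially unique locations.

    A location counts as burnt when its 2.5 km fire-grid cell is burnt;
    locations outside the grid count as unburnt.  ``pf_br`` uses occupied
    cells instead of records, so duplicate sampling within a cell does not
    inflate it.
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    if lons.size == 0:
        raise ValueError("at least one location required")
    mask = layer.burnt_mask if burnt_mask is None else burnt_mask
    row, col, inside = locations_to_cells(lons, lats, layer.grid)
    burnt = np.zeros(lons.size, dtype=bool)
    burnt[inside] = mask[row[inside], col[inside]]
    pf_sr = float(burnt.mean())
    cells = {(int(r), int(c)) for r, c in zip(row, col)}
    burnt_cells = sum(
        1 for r, c in cells
        if 0 <= r < layer.grid.n_rows and 0 <= c < layer.grid.n_cols and mask[r, c])
    pf_br = burnt_cells / len(cells)
    return pf_sr, float(pf_br)


def classify_range(re_t_km: float) -> str:
    for name, lo, hi in RANGE_CLASSES:
        if lo <= re_t_km < hi:
            return name
    return RANGE_CLASSES[-1][0]


def compute_range_extent(lons, lats) -> tuple[float, str]:
    """Maximum geodesic distance between records (km) and its size class."""
    re_t = max_pairwise_distance_km(lons, lats)
    return re_t, classify_range(re_t)


def richness_grids(per_taxon: dict[str, pd.DataFrame], layer: FireLayer,
                   agg_factor: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Burnt and unburnt species-richness grids at an aggregated resolution.

    ``per_taxon`` maps taxon -> DataFrame with longitude/latitude columns
    (typically restricted to high-impact species).  The aggregated cell is
    ``agg_factor`` x ``agg_factor`` fire cells (3 -> 7.5 km).  Burnt richness
    counts distinct taxa with at least one record whose fire cell is burnt
    within the aggregated cell; unburnt richness the analogue.
    """
    grid = layer.grid
    mask = layer.burnt_mask
    n_r = int(np.ceil(grid.n_rows / agg_factor))
    n_c = int(np.ceil(grid.n_cols / agg_factor))
    burnt_r = np.zeros((n_r, n_c), dtype=np.int32)
    unburnt_r = np.zeros((n_r, n_c), dtype=np.int32)
    for _, df in per_taxon.items():
        row, col, inside = locations_to_cells(
            df["longitude"].to_numpy(float), df["latitude"].to_numpy(float), grid)
        row, col = row[inside], col[inside]
        if row.size == 0:
            continue
        rec_burnt = mask[row, col]
        ar, ac = row // agg_factor, col // agg_factor
        for flag, target in ((rec_burnt, burnt_r), (~rec_burnt, unburnt_r)):
            cells = {(int(r), int(c)) for r, c in zip(ar[flag], ac[flag])}
            for r, c in cells:
                target[r, c] += 1
    return burnt_r, unburnt_r


def build_species_table(cleaned: pd.DataFrame, layer: FireLayer,
                        all_records: pd.DataFrame | None = None,
                        study_extent: tuple[float, float, float, float] = DEFAULT_STUDY_EXTENT,
                        ) -> pd.DataFrame:
    """Per-taxon direct metrics from cleaned records.

    Columns: taxon, n_records (unique cleaned locations), n_cells, pf_sr,
    pf_br, re_t_km, range_class, endemism.  ``all_records`` (pre-crop, may
    include the wider download extent) feeds the endemism classification;
    when omitted every taxon is reported endemic by construction.
    """
    burnt = layer.burnt_mask
    rows = []
    for taxon, df in cleaned.groupby("taxon", sort=True):
        lons = df["longitude"].to_numpy(float)
        lats = df["latitude"].to_numpy(float)
        pf_sr, pf_br = compute_pf_direct(lons, lats, layer, burnt_mask=burnt)
        re_t, rclass = compute_range_extent(lons, lats)
        r, c, inside = locations_to_cells(lons, lats, layer.grid)
        n_cells = len({(int(rr), int(cc)) for rr, cc in zip(r, c)})
        if all_records is not None:
            endem = classify_endemism(all_records[all_records["taxon"] == taxon],
                                      study_extent)
        else:
            endem = ENDEMIC
        rows.append({"taxon": taxon, "n_records": len(df), "n_cells": n_cells,
                     "pf_sr": pf_sr, "pf_br": pf_br, "re_t_km": re_t,
                     "range_class": rclass, "endemism": endem})
    return pd.DataFrame(rows)


def read_occurrence_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("taxon", "longitude", "latitude") if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {missing}")
    return df
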