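"""Vegetation and bioregion overlay of the fire layer.

Per stratum (a Major Vegetation Group, a broad vegetation type, or either
crossed with a bioregion) this module reports:

* ``fg_i`` — burnt area inside the stratum (thousand hectares), by cell
  counting on the equal-area fire grid;
* ``pf_t`` — the percentage of the stratum's total area burnt;
* ``i_h``  — the hot-fire score: percentage of the stratum's burnt,
  temperature-classed area in the High or Very High relative-temperature
  classes, I_H = 100 * (A_VH + A_H) / A_TOT, where A_TOT excludes burnt
  cells lacking temperature data;
* an A-E category for ``i_h`` and a ``severe`` flag (pf_t > 50 and
  i_h > 25).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy

from .fire_layer import FireLayer, GridSpec, HIGH, VHIGH, ND, TEMP_CLASS_CODES

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# MVG codes -> broad vegetation types
# ---------------------------------------------------------------------------

RF, EF, OF, SH, GH, OTHER = "RF", "EF", "OF", "SH", "GH", "OTHER"

#: National vegetation groups aggregated into five physiognomic types:
#: rainforests (RF), eucalypt forests/woodlands (EF), other forests and
#: woodlands (OF), shrublands/heathlands (SH) and grasslands/herblands/
#: sedgelands/rushlands (GH).
BROAD_TYPE_CODES: dict[str, tuple[int, ...]] = {
    RF: (1,),
    EF: (2, 3, 4, 5, 11),
    OF: (6, 7, 8, 9, 10, 13, 15, 31),
    SH: (14, 16, 17, 18),
    GH: (19, 20, 21, 22),
}

#: Coastal / near-coastal bioregions grouped for reporting.
COASTAL_BIOREGIONS = ("NET", "NNC", "SYB", "SEC")

_CODE_TO_BROAD = {code: bt for bt, codes in BROAD_TYPE_CODES.items()
                  for code in codes}


def assign_broad_type(mvg_code) -> str:
    """Map an MVG integer code to its broad vegetation type (else OTHER)."""
    if isinstance(mvg_code, bool) or not isinstance(mvg_code, (int, np.integer)):
        raise TypeError(f"MVG code must be an integer, got {mvg_code!r}")
    return _CODE_TO_BROAD.get(int(mvg_code), OTHER)


# ---------------------------------------------------------------------------
# Strata
# ---------------------------------------------------------------------------

@dataclass
class StratumLayers:
    """MVG codes and bioregion labels aligned to the fire grid.

    ``mvg`` is an integer array on the fire grid (one code per cell);
    ``bioregion`` an object array of bioregion code strings ('' where no
    bioregion covers the cell centre).
    """

    mvg: np.ndarray
    bioregion: np.ndarray
    coastal_bioregions: tuple[str, ...] = COASTAL_BIOREGIONS

    def __post_init__(self):
        if self.mvg.shape != self.bioregion.shape:
            raise ValueError("MVG and bioregion layers must share the fire grid")


def rasterise_bioregions(features: list[dict], grid: GridSpec) -> np.ndarray:
    """Assign each fire-grid cell to the bioregion containing its centre."""
    xs, ys = grid.cell_centres()
    out = np.full(xs.shape, "", dtype=object)
    for feat in features:
        geom = feat["geometry"]
        code = feat["properties"].get("code", "")
        hit = contains_xy(geom, xs.ravel(), ys.ravel()).reshape(xs.shape)
        out[hit & (out == "")] = code
    return out


def resample_majority(categorical: np.ndarray, src_grid: GridSpec,
                      dst_grid: GridSpec) -> np.ndarray:
    """Majority-rule resampling of a categorical raster onto another grid.

    Each source cell votes into the destination cell containing its centre;
    ties break toward the smaller code (deterministic).
    """
    xs, ys = src_grid.cell_centres()
    row, col = dst_grid.xy_to_rowcol(xs.ravel(), ys.ravel())
    inside = dst_grid.inside(row, col)
    df = pd.DataFrame({"row": row[inside], "col": col[inside],
                       "val": categorical.ravel()[inside]})
    counts = (df.groupby(["row", "col", "val"]).size()
              .reset_index(name="n")
              .sort_values(["row", "col", "n", "val"],
                           ascending=[True, True, False, True]))
    winners = counts.drop_duplicates(["row", "col"])
    out = np.zeros((dst_grid.n_rows, dst_grid.n_cols),
                   dtype=np.asarray(categorical).dtype)
    out[winners["row"].to_numpy(), winners["col"].to_numpy()] = winners["val"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Impact metrics
# ---------------------------------------------------------------------------

#: I_H category bins (percent): A > 80; B > 65-80; C > 50-65; D > 35-50;
#: E > 25-35; NONE at or below 25 or when no classed burnt cell exists.
def ih_category(i_h: float | None) -> str:
    if i_h is None:
        return "NONE"
    if i_h > 80:
        return "A"
    if i_h > 65:
        return "B"
    if i_h > 50:
        return "C"
    if i_h > 35:
        return "D"
    if i_h > 25:
        return "E"
    return "NONE"


def compute_IH(layer: FireLayer, stratum_mask: np.ndarray) -> tuple[float | None, str]:
    """Hot-fire score over the burnt, temperature-classed cells of a stratum."""
    codes = layer.temp_class_codes
    burnt_classed = stratum_mask & (codes > 0) & (codes != TEMP_CLASS_CODES[ND])
    a_tot = int(burnt_classed.sum())
    if a_tot == 0:
        return None, "NONE"
    hot = burnt_classed & ((codes == TEMP_CLASS_CODES[HIGH])
                           | (codes == TEMP_CLASS_CODES[VHIGH]))
    i_h = 100.0 * int(hot.sum()) / a_tot
    return i_h, ih_category(i_h)


@dataclass
class GroupingConfig:
    """Which strata to report."""

    per_bioregion: bool = True
    all_bioregions: bool = True
    coastal_group: bool = True
    broad_types: bool = True


def compute_burnt_area(layer: FireLayer, strata: StratumLayers,
                       grouping: GroupingConfig | None = None) -> pd.DataFrame:
    """Per-stratum burnt area and burn percentage, with the hot-fire score.

    Returns one row per (mvg or broad type) x (bioregion | ALL | COASTAL4)
    with columns ``mvg, broad_type, bioregion, fg_i_kha, pf_t_pct, i_h_pct,
    i_h_category, severe``.  Strata with zero total area are omitted with a
    warning.  Areas are exact cell counts times the cell area.
    """
    grouping = grouping or GroupingConfig()
    grid = layer.grid
    burnt = layer.burnt_mask
    cell_kha = grid.cell_area_ha / 1000.0
    mvg = strata.mvg
    bio = strata.bioregion

    bioregion_sets: list[tuple[str, np.ndarray]] = []
    if grouping.per_bioregion:
        for code in sorted({str(b) for b in bio.ravel() if b}):
            bioregion_sets.append((code, bio == code))
    if grouping.all_bioregions:
        bioregion_sets.append(("ALL", np.ones_like(burnt, dtype=bool)))
    if grouping.coastal_group:
        coastal = np.isin(bio.astype(str), strata.coastal_bioregions)
        bioregion_sets.append(("COASTAL4", coastal))

    strata_defs: list[tuple[object, str, np.ndarray]] = []
    for code in sorted({int(v) for v in np.unique(mvg)}):
        strata_defs.append((code, assign_broad_type(code), mvg == code))
    if grouping.broad_types:
        for bt, codes in BROAD_TYPE_CODES.items():
            strata_defs.append((bt, bt, np.isin(mvg, codes)))

    rows = []
    for stratum_id, broad, smask in strata_defs:
        for bio_code, bmask in bioregion_sets:
            mask = smask & bmask
            total = int(mask.sum())
            if total == 0:
                logger.warning("stratum %s x %s has zero area; omitted",
                               stratum_id, bio_code)
                continue
            nburnt = int((mask & burnt).sum())
            i_h, cat = compute_IH(layer, mask)
            pf_t = 100.0 * nburnt / total
            rows.append({
                "mvg": stratum_id, "broad_type": broad, "bioregion": bio_code,
                "fg_i_kha": nburnt * cell_kha, "pf_t_pct": pf_t,
                "i_h_pct": i_h, "i_h_category": cat,
                "severe": bool(pf_t > 50 and i_h is not None and i_h > 25),
            })
    return pd.DataFrame(rows)


def severity_report(impacts: pd.DataFrame) -> pd.DataFrame:
    """Severely impacted vegetation types, in the shape of the per-bioregion
    severity table: MVG rows with pf_t > 50% and i_h > 25% in at least one
    bioregion, grouped by broad type with per-bioregion area and category."""
    if len(impacts) == 0:
        return pd.DataFrame(columns=["broad_type", "mvg", "bioregion",
                                     "fg_i_kha", "pf_t_pct", "i_h_category"])
    per_bio = impacts[~impacts["bioregion"].isin(["ALL", "COASTAL4"])
                      & impacts["mvg"].apply(lambda v: isinstance(v, (int, np.integer)))]
    severe_mvgs = per_bio.loc[per_bio["severe"], "mvg"].unique()
    rep = per_bio[per_bio["mvg"].isin(severe_mvgs) & (per_bio["fg_i_kha"] > 0)]
    rep = rep.sort_values(["broad_type", "mvg", "bioregion"])
    return rep[["broad_type", "mvg", "bioregion", "fg_i_kha",
                "pf_t_pct", "i_h_pct", "i_h_category"]].reset_index(drop=True)
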