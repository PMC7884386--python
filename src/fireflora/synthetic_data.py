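"""Synthetic study systems with known ground truth.

Every pipeline stage can be exercised without downloads: the generator
emulates (a) a stack of 21 spatially autocorrelated environmental
predictors with a categorical vegetation raster and a few bioregion
polygons, (b) compact fire scars that emit noisy hotspot records from a
mixture of satellites (geostationary temperatures hottest in fire cores,
polar-orbiter temperature + confidence records, confidence-only
detections), plus spurious isolated clusters and sub-threshold noise, and
(c) a virtual flora whose true ranges are environmental envelopes with a
positively skewed range-size distribution, sampled with roadside-style
repeat collections, exact duplicates, pre-1950 records and flagged
contamination.  The truth object records the burn mask and each species'
true range and burn fraction, which is the recovery surface the test
suite measures against.

All randomness flows from one integer seed through deterministic child
streams, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box as shapely_box

from . import io as ffio
from .fire_layer import (AQUA, DEFAULT_WINDOW, GridSpec, HIMAWARI8,
                         SUOMI_NPP, TERRA)
from .sdm import ENV_VARIABLES, EnvStack

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Scenario parameters; defaults give a ~500 x 500 km landscape on a
    200 x 200 fire grid with ~300 virtual species, sized so the whole
    pipeline (including distribution models) runs in minutes."""

    seed: int
    extent: tuple[float, float, float, float] = (147.32, -35.25, 152.68, -30.75)
    fire_grid_cell_m: float = 2500.0
    env_cell_m: float = 1000.0

    # fires and hotspot emission
    n_fires: int = 12
    fire_size_range_ha: tuple[float, float] = (30_000.0, 2_500_000.0)
    hotspot_density: float = 3.0          # mean extra hotspots per burnt cell
    spurious_rate: float = 12.0           # expected spurious clusters
    confidence_only_fraction: float = 0.12
    window: tuple[date, date] = DEFAULT_WINDOW

    # flora
    n_species: int = 300
    range_size_lognormal_mu: float = 4.0   # ln km; median ~55 km
    range_size_lognormal_sigma: float = 1.0
    records_per_species: float = 90.0
    oversample_intensity: float = 0.6      # repeat-visit records per original
    duplicate_rate: float = 0.08
    pre1950_rate: float = 0.05
    cultivated_rate: float = 0.02
    low_precision_rate: float = 0.03
    trait_unknown_rate: float = 0.05
    persister_fraction: float = 0.93
    rf_class_probs: tuple[float, ...] = (0.05, 0.07, 0.08, 0.80)
    mvg_codes: tuple[int, ...] = (1, 3, 8, 16, 20, 25)

    def __post_init__(self):
        for name in ("confidence_only_fraction", "duplicate_rate",
                     "pre1950_rate", "cultivated_rate", "low_precision_rate",
                     "trait_unknown_rate", "persister_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Landscape:
    env: EnvStack
    mvg: np.ndarray                      # fire-grid integer codes
    bioregions: list[dict]               # GeoJSON-style features (projected)
    fire_grid: GridSpec


@dataclass
class GroundTruth:
    """True burn mask, per-species ranges/burn fractions, per-fire footprints."""

    burn_mask: np.ndarray                           # fire grid, bool
    species: dict[str, dict] = field(default_factory=dict)
    fire_footprints: list[np.ndarray] = field(default_factory=list)


@dataclass
class Scenario:
    config: SyntheticConfig
    landscape: Landscape
    hotspots: pd.DataFrame
    occurrences: pd.DataFrame
    traits: pd.DataFrame
    truth: GroundTruth


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def _random_field(rng, shape, sigma_cells, gradient_weight=0.6):
    """Gaussian-filtered noise plus a random linear gradient, standardised."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells)
    rr, cc = np.meshgrid(np.linspace(-1, 1, shape[0]),
                         np.linspace(-1, 1, shape[1]), indexing="ij")
    theta = rng.uniform(0, 2 * np.pi)
    grad = np.cos(theta) * rr + np.sin(theta) * cc
    f = noise / max(noise.std(), 1e-12) + gradient_weight * grad
    return (f - f.mean()) / f.std()


def generate_landscape(config: SyntheticConfig) -> Landscape:
    """Predictor stack, vegetation raster and bioregion polygons."""
    w, s, e, n = config.extent
    env_grid = GridSpec.from_extent_lonlat(w, s, e, n, config.env_cell_m)
    fire_grid = GridSpec.from_extent_lonlat(w, s, e, n, config.fire_grid_cell_m)
    if env_grid.n_rows < 4 or env_grid.n_cols < 4:
        raise ValueError("extent too small for the environmental grid")
    rngs = _child_rngs(config.seed, len(ENV_VARIABLES) + 2)
    shape = (env_grid.n_rows, env_grid.n_cols)
    layers = {name: _random_field(rngs[i], shape,
                                  sigma_cells=float(rngs[i].uniform(8, 25)))
              for i, name in enumerate(ENV_VARIABLES)}
    env = EnvStack(layers=layers, grid=env_grid)

    # vegetation from two climate-like layers sampled at fire-cell centres
    xs, ys = fire_grid.cell_centres()
    er, ec = env_grid.xy_to_rowcol(xs.ravel(), ys.ravel())
    er = np.clip(er, 0, env_grid.n_rows - 1)
    ec = np.clip(ec, 0, env_grid.n_cols - 1)
    wet = layers[ENV_VARIABLES[5]][er, ec].reshape(xs.shape)   # Bio12-like
    hot = layers[ENV_VARIABLES[1]][er, ec].reshape(xs.shape)   # Bio05-like
    codes = config.mvg_codes
    mvg = np.full(xs.shape, codes[2], dtype=np.int32)          # other forests
    mvg[wet > np.quantile(wet, 0.85)] = codes[0]               # rainforest
    mvg[(wet > np.quantile(wet, 0.45)) & (wet <= np.quantile(wet, 0.85))] = codes[1]
    mvg[(wet <= np.quantile(wet, 0.45)) & (hot > np.quantile(hot, 0.6))] = codes[3]
    mvg[(wet <= np.quantile(wet, 0.45)) & (hot <= np.quantile(hot, 0.2))] = codes[4]
    cleared = rngs[-2].random(xs.shape) < 0.08                 # scattered clearing
    mvg[cleared] = codes[5]

    # 4 bioregion rectangles around a jittered interior split point
    rng = rngs[-1]
    x0, y0 = fire_grid.origin_x, fire_grid.origin_y
    x1 = x0 + fire_grid.n_cols * fire_grid.cell_size_m
    y1 = y0 + fire_grid.n_rows * fire_grid.cell_size_m
    sx = x0 + (x1 - x0) * rng.uniform(0.4, 0.6)
    sy = y0 + (y1 - y0) * rng.uniform(0.4, 0.6)
    quads = [("NET", shapely_box(x0, sy, sx, y1)), ("NNC", shapely_box(sx, sy, x1, y1)),
             ("SYB", shapely_box(x0, y0, sx, sy)), ("SEC", shapely_box(sx, y0, x1, sy))]
    features = [{"geometry": g, "properties": {"code": c}} for c, g in quads]
    return Landscape(env=env, mvg=mvg, bioregions=features, fire_grid=fire_grid)


# ---------------------------------------------------------------------------
# Fires and hotspots
# ---------------------------------------------------------------------------

def _grow_fire(rng, grid: GridSpec, occupied: np.ndarray, n_cells: int) -> np.ndarray:
    """Grow a compact connected scar of ~n_cells from a random ignition.

    Ignitions are biased toward the eastern (coastal) side of the domain,
    mirroring the concentration of the emulated fire season along the
    seaboard, so large parts of the west stay unburnt.  Frontier cells are
    added with probability weighted by the square of the number of
    already-burnt neighbours, which keeps scars blobby with irregular
    margins.
    """
    free = np.argwhere(~occupied)
    w = np.exp(3.0 * free[:, 1] / max(grid.n_cols - 1, 1))
    start = tuple(free[rng.choice(len(free), p=w / w.sum())])
    burnt = {start}
    frontier: dict[tuple[int, int], int] = {}

    def push(cell):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r, c = cell[0] + dr, cell[1] + dc
                if (dr or dc) and 0 <= r < grid.n_rows and 0 <= c < grid.n_cols:
                    if (r, c) not in burnt and not occupied[r, c]:
                        frontier[(r, c)] = frontier.get((r, c), 0) + 1

    push(start)
    while len(burnt) < n_cells and frontier:
        cells = list(frontier)
        weights = np.array([frontier[c] for c in cells], dtype=float) ** 2
        pick = cells[rng.choice(len(cells), p=weights / weights.sum())]
        del frontier[pick]
        burnt.add(pick)
        push(pick)
    mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for r, c in burnt:
        mask[r, c] = True
    return mask


def _random_timestamps(rng, n, window):
    start = pd.Timestamp(window[0])
    end = pd.Timestamp(window[1]) + pd.Timedelta(days=1)
    secs = rng.integers(0, int((end - start).total_seconds()), size=n)
    return start + pd.to_timedelta(secs, unit="s")


def _cell_lonlat(rng, grid: GridSpec, rows, cols):
    """Random positions inside the given cells, in degrees."""
    x = grid.origin_x + (np.asarray(cols) + rng.random(len(cols))) * grid.cell_size_m
    y = grid.origin_y + (np.asarray(rows) + rng.random(len(rows))) * grid.cell_size_m
    return grid.projection.inverse(x, y)


def generate_fire_event(config: SyntheticConfig, landscape: Landscape
                        ) -> tuple[np.ndarray, pd.DataFrame, list[np.ndarray]]:
    """True burn mask plus the noisy hotspot stream it emits.

    Core cells (2+ cells from the fire edge) emit hot geostationary
    records (up to ~1800 K); margins cooler, sometimes below the 500 K
    retention floor.  A configurable share of burnt cells is seen only by
    the confidence-only satellite.  Spurious clusters (<= 3 cells, all
    temperatures <= 1000 K) and sub-threshold noise records are added on
    top; both are removed by the reconstruction rules.
    """
    rng_fire, rng_spot, rng_noise = _child_rngs(config.seed + 1, 3)
    grid = landscape.fire_grid
    burn = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    footprints = []
    lo, hi = config.fire_size_range_ha
    for _ in range(config.n_fires):
        target_ha = float(np.exp(rng_fire.uniform(np.log(lo), np.log(hi))))
        n_cells = max(int(round(target_ha / grid.cell_area_ha)), 1)
        scar = _grow_fire(rng_fire, grid, burn, n_cells)
        footprints.append(scar)
        burn |= scar

    interior = ndimage.distance_transform_cdt(burn, metric="taxicab") >= 2
    rows, cols = np.nonzero(burn)
    records = []

    conf_only = rng_spot.random(rows.size) < config.confidence_only_fraction
    n_extra = rng_spot.poisson(config.hotspot_density, size=rows.size)
    for i, (r, c) in enumerate(zip(rows, cols)):
        core = interior[r, c]
        if conf_only[i]:
            for _ in range(1 + n_extra[i] // 2):
                records.append((r, c, SUOMI_NPP, np.nan,
                                rng_spot.uniform(55, 95)))
            continue
        # geostationary record, hotter in fire cores; margin temperatures can
        # dip below the 500 K retention floor (genuine under-detection)
        t0 = rng_spot.uniform(1000, 1800) if core else rng_spot.uniform(450, 1100)
        records.append((r, c, HIMAWARI8, t0, np.nan))
        for _ in range(n_extra[i]):
            u = rng_spot.random()
            if u < 0.5:
                t = rng_spot.uniform(700, 1999.9) if core else rng_spot.uniform(350, 1100)
                records.append((r, c, HIMAWARI8, t, np.nan))
            elif u < 0.85:
                sat = AQUA if rng_spot.random() < 0.5 else TERRA
                t = rng_spot.uniform(330, 506) if core else rng_spot.uniform(302.1, 420)
                records.append((r, c, sat, t, rng_spot.uniform(40, 100)))
            else:
                records.append((r, c, SUOMI_NPP, np.nan, rng_spot.uniform(30, 100)))

    # spurious clusters: small, cool, off-fire; pruned by the 25 km^2/1000 K rule
    n_clusters = rng_noise.poisson(config.spurious_rate)
    unburnt = np.argwhere(~burn)
    for _ in range(n_clusters):
        r0, c0 = unburnt[rng_noise.integers(len(unburnt))]
        size = rng_noise.integers(1, 4)
        cells = [(r0, c0)]
        while len(cells) < size:
            r, c = cells[-1]
            r = int(np.clip(r + rng_noise.integers(-1, 2), 0, grid.n_rows - 1))
            c = int(np.clip(c + rng_noise.integers(-1, 2), 0, grid.n_cols - 1))
            if not burn[r, c]:
                cells.append((r, c))
            else:
                break
        for r, c in cells:
            records.append((r, c, HIMAWARI8, rng_noise.uniform(520, 990), np.nan))

    # sub-threshold noise: filtered before gridding
    n_noise = rng_noise.poisson(config.spurious_rate * 3)
    for _ in range(n_noise):
        r, c = unburnt[rng_noise.integers(len(unburnt))]
        if rng_noise.random() < 0.5:
            records.append((r, c, HIMAWARI8, rng_noise.uniform(200, 499), np.nan))
        else:
            records.append((r, c, AQUA, rng_noise.uniform(302.1, 500),
                            rng_noise.uniform(0, 50)))

    if records:
        rec = pd.DataFrame(records, columns=["row", "col", "satellite",
                                             "temp_kelvin", "confidence"])
        lon, lat = _cell_lonlat(rng_spot, grid, rec["row"].to_numpy(),
                                rec["col"].to_numpy())
        hotspots = pd.DataFrame({
            "longitude": lon, "latitude": lat,
            "datetime": _random_timestamps(rng_spot, len(rec), config.window),
            "satellite": rec["satellite"],
            "temp_kelvin": rec["temp_kelvin"],
            "confidence": rec["confidence"],
        })
    else:
        hotspots = pd.DataFrame(columns=["longitude", "latitude", "datetime",
                                         "satellite", "temp_kelvin", "confidence"])
    return burn, hotspots, footprints


# ---------------------------------------------------------------------------
# Flora
# ---------------------------------------------------------------------------

def _envelope_range(rng, env: EnvStack, target_area_km2: float
                    ) -> np.ndarray:
    """True range: the connected patch of an environmental envelope.

    A box rule on two predictors around a random focal cell is widened
    until the contiguous envelope patch containing the focal cell reaches
    the target area; that patch is the range (flat indices).  Restricting
    to one patch keeps ranges spatially coherent, so realised extents
    track the lognormal extent targets; disjoint same-environment patches
    elsewhere remain attractive to a distribution model, reproducing the
    overestimation behaviour the discordance screen exists for.
    """
    _, finite = env.design_matrix()
    names = list(env.layers)
    i, j = rng.choice(len(names), size=2, replace=False)
    A = env.layers[names[i]]
    B = env.layers[names[j]]
    finite2 = finite.reshape(A.shape)
    focal = rng.choice(np.flatnonzero(finite))
    fr, fc = divmod(int(focal), env.grid.n_cols)
    va, vb = A[fr, fc], B[fr, fc]
    target_cells = min(max(target_area_km2 / env.grid.cell_area_km2, 4),
                       0.8 * finite.sum())
    eight = np.ones((3, 3), dtype=bool)

    def patch(w):
        mask = (np.abs(A - va) <= w) & (np.abs(B - vb) <= w) & finite2
        labels, _ = ndimage.label(mask, structure=eight)
        return labels == labels[fr, fc]

    lo, hi = 0.005, 6.0
    for _ in range(16):
        w = 0.5 * (lo + hi)
        if patch(w).sum() < target_cells:
            lo = w
        else:
            hi = w
    return np.flatnonzero(patch(hi).ravel())


def _draw_traits(rng, config: SyntheticConfig) -> dict:
    from .traits_stats import LIFE_FORMS, RF_CLASSES, HABITAT_FLAGS
    lf_weights = np.array([3, 6, 8, 1, 8, 12, 16, 8, 6, 3, 1, 3, 2, 2, 1, 0.5])
    life_form = LIFE_FORMS[rng.choice(len(LIFE_FORMS),
                                      p=lf_weights / lf_weights.sum())]
    rf = RF_CLASSES[rng.choice(4, p=np.asarray(config.rf_class_probs))]
    if rng.random() < config.trait_unknown_rate:
        resprouter, propagule = "unknown", "unknown"
        if rng.random() < 0.5:
            resprouter = "Rplus" if rng.random() < config.persister_fraction else "Rminus"
        else:
            propagule = "Pplus" if rng.random() < config.persister_fraction else "Pminus"
    elif rng.random() < config.persister_fraction:
        u = rng.random()
        resprouter, propagule = (("Rplus", "Pplus") if u < 0.5 else
                                 ("Rplus", "Pminus") if u < 0.75 else
                                 ("Rminus", "Pplus"))
    else:
        resprouter, propagule = "Rminus", "Pminus"
    flags = [f for f in HABITAT_FLAGS[:5] if rng.random() < 0.25] or ["other"]
    fire_history = "infrequent" if (rf in ("RFPP", "RFP") and rng.random() < 0.8) \
        else "frequent"
    return {"life_form": life_form, "rf_class": rf,
            "habitat_flags": ";".join(flags), "resprouter": resprouter,
            "propagule_persister": propagule, "fire_history": fire_history}


def generate_flora(config: SyntheticConfig, landscape: Landscape,
                   burn_mask: np.ndarray
                   ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Virtual species with envelope ranges, biased sampling and traits.

    Ranges follow a lognormal extent distribution (positive skew); records
    are sampled uniformly over range cells, then inflated with repeat
    collections at a few favourite sites (exact coordinate repeats, the
    roadside-bias analogue), exact duplicates, pre-1950 records and flagged
    cultivated / coarse-coordinate contamination, all of which the cleaning
    stage removes.  True burn fraction is the burnt share of range cells.
    """
    rng_rng, rng_occ, rng_tr = _child_rngs(config.seed + 2, 3)
    env = landscape.env
    fire_grid = landscape.fire_grid

    # env cell -> burnt? (true mask)
    xs, ys = env.grid.cell_centres()
    fr, fc = fire_grid.xy_to_rowcol(xs.ravel(), ys.ravel())
    inside = fire_grid.inside(fr, fc)
    env_burnt = np.zeros(fr.size, dtype=bool)
    env_burnt[inside] = burn_mask[fr[inside], fc[inside]]

    truth = GroundTruth(burn_mask=burn_mask)
    occ_rows, trait_rows = [], []
    year_hi = min(config.window[0].year - 1, 2019)
    for k in range(config.n_species):
        taxon = f"Synthspecies {k:04d}"
        extent_km = float(np.exp(rng_rng.normal(config.range_size_lognormal_mu,
                                                config.range_size_lognormal_sigma)))
        extent_km = float(np.clip(extent_km, 2.0, 1200.0))
        range_cells = _envelope_range(rng_rng, env, 0.4 * extent_km ** 2)
        true_pf = float(env_burnt[range_cells].mean())
        truth.species[taxon] = {"range_cells": range_cells, "true_pf": true_pf,
                                "target_extent_km": extent_km}

        n_rec = max(int(rng_occ.poisson(config.records_per_species)), 3)
        cells = rng_occ.choice(range_cells, size=n_rec, replace=True)
        rr, cc = cells // env.grid.n_cols, cells % env.grid.n_cols
        lon, lat = _cell_lonlat(rng_occ, env.grid, rr, cc)
        base = pd.DataFrame({
            "taxon": taxon, "family": f"Synthfamily {k % 20:02d}",
            "longitude": np.round(lon, 6), "latitude": np.round(lat, 6),
            "year": rng_occ.integers(1960, year_hi + 1, size=n_rec),
            "coord_precision_m": rng_occ.choice([10.0, 100.0, 1000.0], size=n_rec),
            "cultivated": False, "introduced": False, "taxonomy_suspect": False,
        })
        extras = [base]
        # favourite-site repeat collections: exact coordinate repeats
        n_over = rng_occ.poisson(config.oversample_intensity * n_rec)
        if n_over > 0:
            sites = base.iloc[rng_occ.choice(min(3, len(base)), size=n_over,
                                             replace=True)].copy()
            sites["year"] = rng_occ.integers(1960, year_hi + 1, size=n_over)
            extras.append(sites)
        # exact duplicates of random records
        n_dup = rng_occ.binomial(n_rec, config.duplicate_rate)
        if n_dup > 0:
            extras.append(base.iloc[rng_occ.choice(n_rec, size=n_dup)].copy())
        occ = pd.concat(extras, ignore_index=True)
        # contamination (removed by cleaning): old, coarse, cultivated
        m = len(occ)
        old = rng_occ.random(m) < config.pre1950_rate
        occ.loc[old, "year"] = rng_occ.integers(1900, 1950, size=int(old.sum()))
        coarse = rng_occ.random(m) < config.low_precision_rate
        occ.loc[coarse, "coord_precision_m"] = 30_000.0
        cult = rng_occ.random(m) < config.cultivated_rate
        occ.loc[cult, "cultivated"] = True
        occ_rows.append(occ)

        trait_rows.append({"taxon": taxon, **_draw_traits(rng_tr, config)})

    occurrences = pd.concat(occ_rows, ignore_index=True)
    traits = pd.DataFrame(trait_rows)
    truth.fire_footprints = []
    return occurrences, traits, truth


# ---------------------------------------------------------------------------
# Orchestration and fixture bundles
# ---------------------------------------------------------------------------

def generate_scenario(config: SyntheticConfig) -> Scenario:
    """Full synthetic study system: landscape, fires, hotspots, flora."""
    landscape = generate_landscape(config)
    burn, hotspots, footprints = generate_fire_event(config, landscape)
    occurrences, traits, truth = generate_flora(config, landscape, burn)
    truth.fire_footprints = footprints
    return Scenario(config=config, landscape=landscape, hotspots=hotspots,
                    occurrences=occurrences, traits=traits, truth=truth)


def write_fixture_bundle(scenario: Scenario, out_dir) -> None:
    """Write the scenario as plain-text files plus a seeded manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = scenario
    sc.hotspots.to_csv(out / "hotspots.csv", index=False)
    sc.occurrences.to_csv(out / "occurrences.csv", index=False)
    sc.traits.to_csv(out / "traits.csv", index=False)
    ffio.write_ascii_grid(out / "true_burn_mask.asc",
                          sc.truth.burn_mask.astype(np.int16),
                          sc.landscape.fire_grid)
    ffio.write_ascii_grid(out / "mvg.asc", sc.landscape.mvg, sc.landscape.fire_grid)
    for name, layer in sc.landscape.env.layers.items():
        ffio.write_ascii_grid(out / f"env_{name}.asc", layer, sc.landscape.env.grid)
    ffio.write_geojson(out / "bioregions.geojson", sc.landscape.bioregions)
    pd.DataFrame([
        {"taxon": t, "true_pf": d["true_pf"],
         "target_extent_km": d["target_extent_km"],
         "n_range_cells": len(d["range_cells"])}
        for t, d in sc.truth.species.items()
    ]).to_csv(out / "truth_species.csv", index=False)
    manifest = {"seed": sc.config.seed, "config_hash": sc.config.content_hash(),
                "config": {k: str(v) for k, v in asdict(sc.config).items()}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_fixture_bundle(bundle_dir) -> dict:
    """Read a written bundle back into tables and rasters."""
    d = Path(bundle_dir)
    out = {
        "hotspots": pd.read_csv(d / "hotspots.csv"),
        "occurrences": pd.read_csv(d / "occurrences.csv"),
        "traits": pd.read_csv(d / "traits.csv"),
        "truth_species": pd.read_csv(d / "truth_species.csv"),
        "manifest": json.loads((d / "manifest.json").read_text()),
    }
    out["true_burn_mask"], _ = ffio.read_ascii_grid(d / "true_burn_mask.asc")
    out["mvg"], _ = ffio.read_ascii_grid(d / "mvg.asc")
    out["bioregions"] = ffio.read_geojson(d / "bioregions.geojson")
    return out
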