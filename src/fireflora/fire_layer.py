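"""Fire-extent reconstruction from satellite hotspot records.

A fire layer is built in four steps:

1. **Filter** raw hotspot records: keep geostationary (Himawari-8) records
   with brightness temperature T > 500 K, polar MODIS (Aqua/Terra) records
   with T > 0 K and detection confidence > 50%, and VIIRS (Suomi NPP)
   records with confidence > 50%, within the fire-season window
   (default 2019-07-01 to 2020-02-11 inclusive).
2. **Grid** retained records onto an equal-area 2.5 x 2.5 km grid, keeping
   the per-cell maximum temperature for each satellite family.
3. **Rescale** per-cell maxima to a relative fire temperature T_R in [0, 1]
   (Himawari bounds 400-1999.9 K; if no Himawari temperature, MODIS bounds
   302.1-506 K) and bin into Low / Medium / High / Very High classes, with
   a no-data class for confidence-only detections.
4. **Polygonise** contiguous burnt cells into individual fires, prune small
   cool components (area <= 25 km^2 with no Himawari cell > 1000 K), and
   collect interior unburnt refugia enclosed by single fires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from . import io as ffio
from .geo import LocalEqualAreaProjection

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Constants and configuration
# ---------------------------------------------------------------------------

HIMAWARI8 = "HIMAWARI8"
AQUA = "AQUA"
TERRA = "TERRA"
SUOMI_NPP = "SUOMI_NPP"
SATELLITES = (HIMAWARI8, AQUA, TERRA, SUOMI_NPP)

#: Relative-temperature rescaling bounds, Kelvin (dataset min/max by family).
HIMAWARI_T_BOUNDS = (400.0, 1999.9)
MODIS_T_BOUNDS = (302.1, 506.0)

#: Temperature classes; integer codes used in raster output.
LOW, MED, HIGH, VHIGH, ND = "LOW", "MED", "HIGH", "VHIGH", "ND"
TEMP_CLASS_CODES = {LOW: 1, MED: 2, HIGH: 3, VHIGH: 4, ND: 5}

DEFAULT_WINDOW = (date(2019, 7, 1), date(2020, 2, 11))

HOTSPOT_COLUMNS = ["longitude", "latitude", "datetime", "satellite",
                   "temp_kelvin", "confidence"]


@dataclass
class FireLayerConfig:
    """Filtering, pruning and classification thresholds."""

    window: tuple[date, date] = DEFAULT_WINDOW
    himawari_min_temp_k: float = 500.0      # strict >
    min_confidence_pct: float = 50.0        # strict >
    prune_max_area_km2: float = 25.0        # inclusive <=
    prune_himawari_temp_k: float = 1000.0   # strict >
    fire_connectivity: int = 8              # queen
    refugium_connectivity: int = 4          # rook
    megafire_min_ha: float = 100_000.0      # strict >
    major_min_ha: float = 50_000.0          # inclusive, up to megafire bound
    large_refugium_min_ha: float = 5_000.0  # strict >


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Equal-area raster grid: lower-left origin, row 0 at the southern edge.

    Cells are half-open intervals [x, x + cell) x [y, y + cell): a point on
    a shared edge belongs to the higher-index cell, so cells partition the
    plane.  ``projection`` maps geographic degrees to the grid's projected
    metres (an equal-area CRS so that cell area is exactly cell_size_m^2).
    """

    origin_x: float
    origin_y: float
    cell_size_m: float
    n_rows: int
    n_cols: int
    projection: LocalEqualAreaProjection | None = None

    def __post_init__(self):
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def crs(self) -> str:
        return self.projection.name if self.projection is not None else "projected"

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size_m ** 2 / 10_000.0

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_m ** 2 / 1e6

    @classmethod
    def from_extent_lonlat(cls, west, south, east, north,
                           cell_size_m: float = 2500.0) -> "GridSpec":
        """Build a grid covering a geographic box, projected locally."""
        proj = LocalEqualAreaProjection((west + east) / 2.0, (south + north) / 2.0)
        xs, ys = proj.forward(np.array([west, east, west, east]),
                              np.array([south, south, north, north]))
        x0, y0 = float(xs.min()), float(ys.min())
        n_cols = int(np.ceil((float(xs.max()) - x0) / cell_size_m))
        n_rows = int(np.ceil((float(ys.max()) - y0) / cell_size_m))
        return cls(origin_x=x0, origin_y=y0, cell_size_m=cell_size_m,
                   n_rows=max(n_rows, 1), n_cols=max(n_cols, 1), projection=proj)

    def xy_to_rowcol(self, x, y):
        """Projected metres -> (row, col); may fall outside the grid."""
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size_m)
        row = np.floor((np.asarray(y, float) - self.origin_y) / self.cell_size_m)
        return row.astype(int), col.astype(int)

    def lonlat_to_rowcol(self, lon, lat):
        if self.projection is None:
            raise ValueError("grid has no geographic projection")
        x, y = self.projection.forward(lon, lat)
        return self.xy_to_rowcol(x, y)

    def inside(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_box(self, row: int, col: int):
        x0 = self.origin_x + col * self.cell_size_m
        y0 = self.origin_y + row * self.cell_size_m
        return box(x0, y0, x0 + self.cell_size_m, y0 + self.cell_size_m)

    def cell_centres(self):
        """(x, y) arrays of shape (n_rows, n_cols) of projected cell centres."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size_m
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass
class FireCell:
    """Per-cell hotspot summary and relative temperature."""

    row: int
    col: int
    t_max_himawari: float | None = None
    t_max_modis: float | None = None
    confident_detection: bool = True
    t_r: float | None = None
    temp_class: str | None = None


@dataclass
class FirePolygon:
    fire_id: int
    cells: list[tuple[int, int]]
    area_ha: float
    max_himawari_k: float | None
    size_label: str  # MEGAFIRE | MAJOR | OTHER
    geometry: object = None


@dataclass
class Refugium:
    cells: list[tuple[int, int]]
    area_ha: float
    large_flag: bool
    fire_id: int
    geometry: object = None


@dataclass
class FireLayer:
    """Reconstructed fire extent: burnt cells, T_R classes, fires, refugia."""

    grid: GridSpec
    cells: dict[tuple[int, int], FireCell]
    fires: list[FirePolygon] = field(default_factory=list)
    refugia: list[Refugium] = field(default_factory=list)

    @property
    def burnt_mask(self) -> np.ndarray:
        m = np.zeros((self.grid.n_rows, self.grid.n_cols), dtype=bool)
        for fire in self.fires:
            for r, c in fire.cells:
                m[r, c] = True
        return m

    @property
    def temp_class_codes(self) -> np.ndarray:
        """0 = unburnt, 1-4 = Low..Very High, 5 = no temperature data."""
        codes = np.zeros((self.grid.n_rows, self.grid.n_cols), dtype=np.int16)
        burnt = self.burnt_mask
        for (r, c), cell in self.cells.items():
            if burnt[r, c]:
                codes[r, c] = TEMP_CLASS_CODES[cell.temp_class or ND]
        return codes

    @property
    def total_burnt_area_ha(self) -> float:
        return sum(f.area_ha for f in self.fires)

    def write(self, out_dir) -> None:
        """Write burnt mask and class rasters (.asc) and GeoJSON polygons."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ffio.write_ascii_grid(out / "burnt_mask.asc",
                              self.burnt_mask.astype(np.int16), self.grid)
        ffio.write_ascii_grid(out / "temp_class.asc", self.temp_class_codes, self.grid)
        ffio.write_geojson(out / "fires.geojson", [
            {"geometry": f.geometry, "properties": {
                "fire_id": f.fire_id, "area_ha": f.area_ha,
                "size_label": f.size_label, "max_himawari_k": f.max_himawari_k}}
            for f in self.fires])
        ffio.write_geojson(out / "refugia.geojson", [
            {"geometry": r.geometry, "properties": {
                "area_ha": r.area_ha, "large_flag": r.large_flag,
                "fire_id": r.fire_id}}
            for r in self.refugia])


# ---------------------------------------------------------------------------
# Step 1: filtering
# ---------------------------------------------------------------------------

def filter_hotspots(records: pd.DataFrame,
                    window: tuple[date, date] | None = None,
                    config: FireLayerConfig | None = None) -> pd.DataFrame:
    """Apply the per-satellite retention rules within the season window.

    Retention (all inequalities strict):
    Himawari-8 -> T > 500 K; Aqua/Terra -> T > 0 K and confidence > 50%;
    Suomi NPP -> confidence > 50%.  Records with unknown satellite names
    are rejected with a warning; per-source retained counts are logged.
    """
    cfg = config or FireLayerConfig()
    window = window or cfg.window
    df = records.copy()
    ts = pd.to_datetime(df["datetime"])
    start = pd.Timestamp(window[0])
    end = pd.Timestamp(window[1]) + pd.Timedelta(days=1)  # inclusive end date
    in_window = (ts >= start) & (ts < end)

    sat = df["satellite"].astype(str)
    unknown = ~sat.isin(SATELLITES)
    if unknown.any():
        logger.warning("rejected %d hotspot records with unknown satellite "
                       "values: %s", int(unknown.sum()),
                       sorted(sat[unknown].unique()))

    temp = pd.to_numeric(df.get("temp_kelvin"), errors="coerce")
    conf = pd.to_numeric(df.get("confidence"), errors="coerce")
    keep = in_window & ~unknown & (
        ((sat == HIMAWARI8) & (temp > cfg.himawari_min_temp_k))
        | (sat.isin([AQUA, TERRA]) & (temp > 0) & (conf > cfg.min_confidence_pct))
        | ((sat == SUOMI_NPP) & (conf > cfg.min_confidence_pct))
    )
    out = df[keep.fillna(False)].copy()
    for s in SATELLITES:
        logger.info("filter_hotspots: %s retained %d of %d records",
                    s, int((out["satellite"] == s).sum()), int((sat == s).sum()))
    return out


# ---------------------------------------------------------------------------
# Step 2: gridding
# ---------------------------------------------------------------------------

def grid_hotspots(records: pd.DataFrame,
                  grid: GridSpec) -> dict[tuple[int, int], FireCell]:
    """Summarise filtered records per grid cell (per-satellite maxima)."""
    cells: dict[tuple[int, int], FireCell] = {}
    if len(records) == 0:
        return cells
    row, col = grid.lonlat_to_rowcol(records["longitude"].to_numpy(float),
                                     records["latitude"].to_numpy(float))
    inside = grid.inside(row, col)
    if not inside.all():
        logger.warning("grid_hotspots: dropped %d records outside the grid",
                       int((~inside).sum()))
    df = records.loc[inside, ["satellite", "temp_kelvin"]].copy()
    df["row"] = row[inside]
    df["col"] = col[inside]
    df["temp_kelvin"] = pd.to_numeric(df["temp_kelvin"], errors="coerce")

    him = df[df["satellite"] == HIMAWARI8].groupby(["row", "col"])["temp_kelvin"].max()
    modis = (df[df["satellite"].isin([AQUA, TERRA])]
             .groupby(["row", "col"])["temp_kelvin"].max())
    occupied = df.groupby(["row", "col"]).size()

    for (r, c) in occupied.index:
        th = him.get((r, c), np.nan)
        tm = modis.get((r, c), np.nan)
        cells[(int(r), int(c))] = FireCell(
            row=int(r), col=int(c),
            t_max_himawari=None if pd.isna(th) else float(th),
            t_max_modis=None if pd.isna(tm) else float(tm),
            confident_detection=True,
        )
    return cells


# ---------------------------------------------------------------------------
# Step 3: relative temperature
# ---------------------------------------------------------------------------

def classify_t_r(t_r: float) -> str:
    """Bin T_R with boundary-inclusive upper edges (0.25 -> Low, 0.50 -> Med)."""
    if t_r <= 0.25:
        return LOW
    if t_r <= 0.50:
        return MED
    if t_r <= 0.75:
        return HIGH
    return VHIGH


def compute_relative_temperature(cell: FireCell) -> FireCell:
    """Set ``t_r`` and ``temp_class`` in place (and return the cell).

    Himawari temperature takes precedence; MODIS (pooled Aqua/Terra) is used
    only when no Himawari temperature fell in the cell.  Values outside the
    family bounds are clipped to [0, 1].  Confidence-only cells get the
    no-data class.
    """
    if cell.t_max_himawari is not None:
        lo, hi = HIMAWARI_T_BOUNDS
        t_r = (cell.t_max_himawari - lo) / (hi - lo)
    elif cell.t_max_modis is not None:
        lo, hi = MODIS_T_BOUNDS
        t_r = (cell.t_max_modis - lo) / (hi - lo)
    else:
        cell.t_r = None
        cell.temp_class = ND
        return cell
    cell.t_r = float(np.clip(t_r, 0.0, 1.0))
    cell.temp_class = classify_t_r(cell.t_r)
    return cell


# ---------------------------------------------------------------------------
# Step 4: polygonisation, pruning, refugia
# ---------------------------------------------------------------------------

def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def _cells_to_geometry(cells, grid: GridSpec):
    return unary_union([grid.cell_box(r, c) for r, c in cells])


def size_label(area_ha: float, config: FireLayerConfig | None = None) -> str:
    cfg = config or FireLayerConfig()
    if area_ha > cfg.megafire_min_ha:
        return "MEGAFIRE"
    if area_ha >= cfg.major_min_ha:
        return "MAJOR"
    return "OTHER"


def polygonise_and_prune(cells: dict[tuple[int, int], FireCell],
                         grid: GridSpec,
                         config: FireLayerConfig | None = None,
                         build_geometry: bool = True) -> list[FirePolygon]:
    """Connected burnt components -> fires; drop small components lacking
    any Himawari cell above 1000 K (area <= 25 km^2, both conditions)."""
    cfg = config or FireLayerConfig()
    mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for (r, c) in cells:
        mask[r, c] = True
    labels, n = ndimage.label(mask, structure=_structure(cfg.fire_connectivity))
    fires: list[FirePolygon] = []
    fire_id = 0
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        comp = list(zip(rows.tolist(), cols.tolist()))
        area_km2 = len(comp) * grid.cell_area_km2
        him = [cells[(r, c)].t_max_himawari for r, c in comp
               if cells[(r, c)].t_max_himawari is not None]
        max_him = max(him) if him else None
        hot = max_him is not None and max_him > cfg.prune_himawari_temp_k
        if area_km2 <= cfg.prune_max_area_km2 and not hot:
            continue
        fire_id += 1
        area_ha = len(comp) * grid.cell_area_ha
        fires.append(FirePolygon(
            fire_id=fire_id, cells=comp, area_ha=area_ha,
            max_himawari_k=max_him, size_label=size_label(area_ha, cfg),
            geometry=_cells_to_geometry(comp, grid) if build_geometry else None))
    return fires


def identify_unburnt_interior(fires: list[FirePolygon], grid: GridSpec,
                              config: FireLayerConfig | None = None,
                              build_geometry: bool = True) -> list[Refugium]:
    """Unburnt components fully enclosed by the cells of a single fire.

    Components touching the grid boundary are open landscape, not refugia;
    components adjoining more than one fire are inter-fire corridors.
    """
    cfg = config or FireLayerConfig()
    fire_label = np.zeros((grid.n_rows, grid.n_cols), dtype=np.int32)
    for fire in fires:
        for r, c in fire.cells:
            fire_label[r, c] = fire.fire_id
    unburnt = fire_label == 0
    labels, n = ndimage.label(unburnt, structure=_structure(cfg.refugium_connectivity))
    refugia: list[Refugium] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        if (rows.min() == 0 or cols.min() == 0
                or rows.max() == grid.n_rows - 1 or cols.max() == grid.n_cols - 1):
            continue
        # neighbouring fire ids across queen adjacency (diagonal burnt cells
        # also enclose); any adjacency to a second fire disqualifies
        neighbours = set()
        for r, c in zip(rows, cols):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    v = fire_label[r + dr, c + dc]
                    if v > 0:
                        neighbours.add(int(v))
        if len(neighbours) != 1:
            continue
        comp = list(zip(rows.tolist(), cols.tolist()))
        area_ha = len(comp) * grid.cell_area_ha
        refugia.append(Refugium(
            cells=comp, area_ha=area_ha,
            large_flag=area_ha > cfg.large_refugium_min_ha,
            fire_id=neighbours.pop(),
            geometry=_cells_to_geometry(comp, grid) if build_geometry else None))
    return refugia


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def build_fire_layer(records: pd.DataFrame, grid: GridSpec,
                     config: FireLayerConfig | None = None,
                     build_geometry: bool = True) -> FireLayer:
    """Run filtering, gridding, T_R classification, polygonisation and
    refugium detection; deterministic given its inputs."""
    cfg = config or FireLayerConfig()
    kept = filter_hotspots(records, config=cfg)
    cells = grid_hotspots(kept, grid)
    for cell in cells.values():
        compute_relative_temperature(cell)
    fires = polygonise_and_prune(cells, grid, cfg, build_geometry=build_geometry)
    refugia = identify_unburnt_interior(fires, grid, cfg,
                                        build_geometry=build_geometry)
    return FireLayer(grid=grid, cells=cells, fires=fires, refugia=refugia)


def read_hotspot_csv(path) -> pd.DataFrame:
    """Read a hotspot CSV with the standard column names."""
    df = pd.read_csv(path)
    missing = [c for c in ("longitude", "latitude", "datetime", "satellite")
               if c not in df.columns]
    if missing:
        raise ValueError(f"hotspot CSV missing columns: {missing}")
    for c in ("temp_kelvin", "confidence"):
        if c not in df.columns:
            df[c] = np.nan
    return df
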