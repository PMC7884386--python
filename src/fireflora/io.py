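"""Plain-text raster and vector I/O.

Rasters are exchanged as ESRI ASCII grids (``.asc``), a widely supported
text format (GDAL driver ``AAIGrid``); vector layers as GeoJSON.  Grid
georeferencing follows this package's :class:`~fireflora.fire_layer.GridSpec`
convention: projected metres, lower-left origin, row 0 at the southern edge.
ASCII grids are stored north-up, so arrays are flipped on write and read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from shapely.geometry import mapping, shape

if TYPE_CHECKING:  # pragma: no cover
    from .fire_layer import GridSpec

NODATA = -9999


def write_ascii_grid(path, array: np.ndarray, grid: "GridSpec") -> None:
    """Write a 2-D array (row 0 = south) as an ESRI ASCII grid."""
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise ValueError("raster array must be 2-D")
    a = np.where(np.isfinite(arr.astype(float)), arr, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x:.6f}\n"
        f"yllcorner {grid.origin_y:.6f}\n"
        f"cellsize {grid.cell_size_m:.6f}\n"
        f"NODATA_value {NODATA}\n"
    )
    fmt = "%d" if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool else "%.6f"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.flipud(a), fmt=fmt)


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (array row0=south, header dict)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    arr = np.loadtxt(lines[n_header:])
    arr = np.atleast_2d(arr)
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return np.flipud(arr), header


def write_geojson(path, features: list[dict]) -> None:
    """Write features [{'geometry': shapely geom, 'properties': {...}}] to GeoJSON."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f["geometry"]),
                "properties": f.get("properties", {}),
            }
            for f in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path) -> list[dict]:
    """Read a GeoJSON FeatureCollection into shapely geometries + properties."""
    fc = json.loads(Path(path).read_text())
    return [
        {"geometry": shape(f["geometry"]), "properties": f.get("properties", {})}
        for f in fc.get("features", [])
    ]
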