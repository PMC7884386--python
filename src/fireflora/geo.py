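"""Geodesy and map-projection helpers.

Area-based metrics (hectares, Mha) require an equal-area working grid, so
geographic hotspot and specimen coordinates are projected with a local
Lambert azimuthal equal-area (LAEA) projection centred on the study extent
before gridding.  Range extents are geodesic (haversine) distances and are
therefore independent of the working projection.
"""

from __future__ import annotations

import numpy as np

#: Mean Earth radius (IUGG), kilometres.
EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def max_pairwise_distance_km(lons, lats) -> float:
    """Maximum geodesic distance between any two of the given points (km).

    Exhaustive O(n^2) evaluation, vectorised row-by-row; adequate for the
    record counts seen per taxon (hundreds to a few thousand).
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    n = lons.size
    if n < 2:
        return 0.0
    best = 0.0
    for i in range(n - 1):
        d = haversine_km(lons[i], lats[i], lons[i + 1:], lats[i + 1:])
        m = float(d.max())
        if m > best:
            best = m
    return best


class LocalEqualAreaProjection:
    """Lambert azimuthal equal-area projection on the authalic sphere.

    Centred at (``lon0``, ``lat0``); forward maps degrees to metres.  Used
    as the working CRS for synthetic scenarios and as a default for real
    coordinates when no continental equal-area CRS is supplied.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._lam0 = np.radians(lon0)
        self._phi0 = np.radians(lat0)
        self._R = EARTH_RADIUS_KM * 1000.0

    @property
    def name(self) -> str:
        return f"LAEA(lon0={self.lon0:g},lat0={self.lat0:g})"

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) metres."""
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        cosc = (np.sin(self._phi0) * np.sin(phi)
                + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam))
        # k' = sqrt(2/(1+cos c)); antipodal point is outside any sane extent
        k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
        x = self._R * k * np.cos(phi) * np.sin(dlam)
        y = self._R * k * (np.cos(self._phi0) * np.sin(phi)
                           - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam))
        return x, y

    def inverse(self, x, y):
        """(x, y) metres -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float) / self._R
        y = np.asarray(y, dtype=float) / self._R
        rho = np.sqrt(x ** 2 + y ** 2)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        with np.errstate(invalid="ignore"):
            phi = np.where(
                rho == 0.0,
                self._phi0,
                np.arcsin(np.clip(
                    np.cos(c) * np.sin(self._phi0)
                    + np.where(rho == 0, 0.0, y * np.sin(c) / np.where(rho == 0, 1.0, rho))
                    * np.cos(self._phi0), -1.0, 1.0)),
            )
            lam = self._lam0 + np.arctan2(
                x * np.sin(c),
                rho * np.cos(self._phi0) * np.cos(c) - y * np.sin(self._phi0) * np.sin(c),
            )
        return np.degrees(lam), np.degrees(phi)
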