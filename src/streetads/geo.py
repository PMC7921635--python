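"""Geodesic helpers for geo-tagged frames.

Distances between capture points in this pipeline are tens of metres at
most, so a spherical haversine distance and a local equirectangular
approximation for metre/degree conversion are accurate to well under a
centimetre at the scales involved.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius


def haversine_m(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in metres between two WGS84 points."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


def offset_lonlat(lon: float, lat: float, east_m: float, north_m: float) -> tuple[float, float]:
    """Move a point by metre offsets using a local equirectangular frame.

    Valid for offsets up to ~1 km away from the anchor; error grows with
    distance and latitude but is negligible for survey-route fixtures.
    """
    dlat = north_m / EARTH_RADIUS_M
    dlon = east_m / (EARTH_RADIUS_M * np.cos(np.radians(lat)))
    return lon + float(np.degrees(dlon)), lat + float(np.degrees(dlat))


def pairwise_distances_m(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Symmetric matrix of haversine distances for coordinate vectors."""
    lons = np.radians(np.asarray(lons, dtype=float))
    lats = np.radians(np.asarray(lats, dtype=float))
    dlat = lats[:, None] - lats[None, :]
    dlon = lons[:, None] - lons[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lats)[:, None] * np.cos(lats)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
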