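"""Small geodesy helpers: haversine distances and an equal-area projection.

All analyses in this package run on geographic (lon/lat) coordinates. Distances
are great-circle (haversine) on a spherical Earth; the 50-km occurrence grid is
realized in a Lambert cylindrical equal-area projection so that "50 km" means
the same cell area everywhere.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Inputs broadcast like numpy arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lon, lat):
    """Full n x n haversine distance matrix (km) for coordinate vectors."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def equal_area_xy_km(lon, lat):
    """Lambert cylindrical equal-area projection, in kilometres.

    x = R * lambda, y = R * sin(phi). Area-preserving, which is all the 50-km
    downsampling grid needs; shape distortion is irrelevant for cell indexing.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return EARTH_RADIUS_KM * lon, EARTH_RADIUS_KM * np.sin(lat)
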