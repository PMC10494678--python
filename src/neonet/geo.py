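"""Great-circle distances between municipality seats.

Distances are haversine distances on a sphere of radius 6,371 km between
the seat coordinates of two municipalities.  Straight-line seat-to-seat
distance is used throughout the package; road distance and travel time are
out of scope.
"""

from __future__ import annotations

import numpy as np

from neonet.errors import DataValidationError

EARTH_RADIUS_KM = 6371.0


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise DataValidationError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise DataValidationError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise DataValidationError("longitude outside [-180, 180]")


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.  Symmetric, non-negative and
    zero exactly when the two points coincide.
    """
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def pairwise_distance_matrix(lat, lon) -> np.ndarray:
    """All-pairs haversine distance (km) for coordinate vectors."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
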