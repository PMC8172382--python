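"""Great-circle geometry on the WGS84 sphere.

Every distance used anywhere in the package — variogram lags, kriging
covariances, nearest-neighbour linkage, close-pair placement — goes through
:func:`great_circle_distance`, so the metric is identical across stages.
Coordinates are (lon, lat) in decimal degrees.
"""

from __future__ import annotations

import numpy as np

#: Sphere radius in metres (WGS84 equatorial radius, the geosphere default).
EARTH_RADIUS_M = 6_378_137.0


def _validate_coords(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not np.all(np.isfinite(lon)) or not np.all(np.isfinite(lat)):
        raise ValueError("non-finite coordinates")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180]")


def great_circle_distance(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres (haversine, spherical earth).

    Accepts scalars or broadcastable arrays. Symmetric; zero iff the two
    points coincide (up to floating rounding).
    """
    _validate_coords(lon1, lat1)
    _validate_coords(lon2, lat2)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(a))


def pairwise_distances(lon, lat):
    """Full symmetric matrix of great-circle distances (metres)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return great_circle_distance(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def cross_distances(lon1, lat1, lon2, lat2):
    """(n1, n2) matrix of great-circle distances (metres) between two point sets."""
    lon1 = np.asarray(lon1, dtype=float)
    lat1 = np.asarray(lat1, dtype=float)
    lon2 = np.asarray(lon2, dtype=float)
    lat2 = np.asarray(lat2, dtype=float)
    return great_circle_distance(lon1[:, None], lat1[:, None], lon2[None, :], lat2[None, :])


def destination_point(lon, lat, bearing_deg, distance_m):
    """Point reached from (lon, lat) travelling `distance_m` on bearing `bearing_deg`.

    Standard direct geodesic on the sphere; used to place close-pair sites.
    Returns (lon, lat) in degrees.
    """
    _validate_coords(lon, lat)
    lam1 = np.radians(np.asarray(lon, dtype=float))
    phi1 = np.radians(np.asarray(lat, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta)
                     + np.cos(phi1) * np.sin(delta) * np.cos(theta))
    lam2 = lam1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(phi1),
                             np.cos(delta) - np.sin(phi1) * np.sin(phi2))
    lon2 = (np.degrees(lam2) + 540.0) % 360.0 - 180.0
    return lon2, np.degrees(phi2)
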