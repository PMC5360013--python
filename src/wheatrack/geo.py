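"""Great-circle geometry on a spherical Earth (R = 6371 km).

Coordinates are decimal degrees, latitude in [-90, 90], longitude
normalised to (-180, 180].
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "wrap_lon",
    "gc_distance",
    "initial_bearing",
    "destination",
    "gc_waypoints",
]


def wrap_lon(lon):
    """Normalise longitude to (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = -((-lon + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def gc_distance(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance [km]."""
    p1, p2 = np.deg2rad(np.asarray(lat1, float)), np.deg2rad(np.asarray(lat2, float))
    dl = np.deg2rad(np.asarray(lon2, float) - np.asarray(lon1, float))
    dp = p2 - p1
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if np.ndim(d) else float(d)


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing [deg clockwise from north] from 1 to 2."""
    p1, p2 = np.deg2rad(np.asarray(lat1, float)), np.deg2rad(np.asarray(lat2, float))
    dl = np.deg2rad(np.asarray(lon2, float) - np.asarray(lon1, float))
    x = np.sin(dl) * np.cos(p2)
    y = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    b = np.rad2deg(np.arctan2(x, y)) % 360.0
    return b if np.ndim(b) else float(b)


def destination(lat, lon, bearing, distance_km):
    """Point reached from (lat, lon) on `bearing` after `distance_km`."""
    p1 = np.deg2rad(np.asarray(lat, float))
    l1 = np.deg2rad(np.asarray(lon, float))
    br = np.deg2rad(np.asarray(bearing, float))
    dr = np.asarray(distance_km, float) / EARTH_RADIUS_KM
    p2 = np.arcsin(
        np.sin(p1) * np.cos(dr) + np.cos(p1) * np.sin(dr) * np.cos(br)
    )
    l2 = l1 + np.arctan2(
        np.sin(br) * np.sin(dr) * np.cos(p1),
        np.cos(dr) - np.sin(p1) * np.sin(p2),
    )
    lat2, lon2 = np.rad2deg(p2), wrap_lon(np.rad2deg(l2))
    if np.ndim(lat2):
        return lat2, lon2
    return float(lat2), float(lon2)


def gc_waypoints(lat1, lon1, lat2, lon2, n: int):
    """n points evenly spaced along the great circle from 1 to 2 (inclusive)."""
    total = gc_distance(lat1, lon1, lat2, lon2)
    if total == 0.0 or n == 1:
        return np.full(n, lat1, float), np.full(n, lon1, float)
    lats, lons = [], []
    la, lo = float(lat1), float(lon1)
    lats.append(la)
    lons.append(lo)
    step = total / (n - 1)
    for _ in range(n - 1):
        # re-aim each step so the path tracks the great circle
        b = initial_bearing(la, lo, lat2, lon2)
        la, lo = destination(la, lo, b, step)
        lats.append(la)
        lons.append(lo)
    return np.asarray(lats), np.asarray(lons)
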