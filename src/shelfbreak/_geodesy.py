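"""Spherical-Earth geodesy primitives.

All operations use a sphere of radius ``EARTH_RADIUS_M`` = 6,371,008.8 m
(IUGG mean radius). At foraging-trip scales (tens to hundreds of km) the
spherical error is far below GPS positional noise, and a fixed sphere keeps
every distance, bearing and rotation exactly reproducible.

Angles follow navigation conventions: bearings are degrees clockwise from
true north; longitudes are positive east, latitudes positive north.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between points in decimal degrees.

    Accepts scalars or broadcastable arrays; symmetric; zero iff the
    points coincide.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards tiny negative round-off before sqrt
    a = np.clip(a, 0.0, 1.0)
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(a))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination_point(lon, lat, bearing_deg, distance_m):
    """Point reached travelling ``distance_m`` along the great circle with the
    given initial bearing. Returns (lon, lat) in degrees, lon wrapped to
    (-180, 180]."""
    lon, lat, brg = (np.radians(np.asarray(x, dtype=float))
                     for x in (lon, lat, bearing_deg))
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M
    sin_lat2 = np.sin(lat) * np.cos(delta) + np.cos(lat) * np.sin(delta) * np.cos(brg)
    sin_lat2 = np.clip(sin_lat2, -1.0, 1.0)
    lat2 = np.arcsin(sin_lat2)
    y = np.sin(brg) * np.sin(delta) * np.cos(lat)
    x = np.cos(delta) - np.sin(lat) * sin_lat2
    lon2 = lon + np.arctan2(y, x)
    lon2_deg = (np.degrees(lon2) + 180.0) % 360.0 - 180.0
    # map the -180 branch to +180 so output stays in (-180, 180]
    lon2_deg = np.where(lon2_deg == -180.0, 180.0, lon2_deg)
    if np.ndim(lon2_deg) == 0:
        return float(lon2_deg), float(np.degrees(lat2))
    return lon2_deg, np.degrees(lat2)


def azimuthal_equal_area_xy(lon, lat, lon0, lat0):
    """Lambert azimuthal equal-area projection centred on (lon0, lat0).

    Returns planar (x, y) in metres. Equal-area by construction, so hull
    areas computed in this plane equal areas on the sphere up to the
    (negligible at trip scale) difference between the projected hull and
    the projection of the spherical hull.
    """
    lon, lat = np.radians(np.asarray(lon, dtype=float)), np.radians(np.asarray(lat, dtype=float))
    lon0, lat0 = np.radians(float(lon0)), np.radians(float(lat0))
    dlon = lon - lon0
    denom = 1.0 + np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_M * k * np.cos(lat) * np.sin(dlon)
    y = EARTH_RADIUS_M * k * (np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon))
    return x, y


def wrap_angle_deg(angle):
    """Wrap an angle (or array) in degrees to the interval (-180, 180]."""
    a = -((-np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0)
    if np.ndim(a) == 0:
        return float(a)
    return a
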