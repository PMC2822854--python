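"""Track kinematics: speeds, burst clusters, window merging, trip summaries.

All distances are great-circle (haversine) on a sphere of radius
6,371,008.8 m; see :mod:`shelfbreak._geodesy`. Over-ground speed between
consecutive fixes is distance / elapsed time, the quantity modelled by the
behavioural speed mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from ._geodesy import (EARTH_RADIUS_M, azimuthal_equal_area_xy, haversine_m,
                       initial_bearing_deg)
from .track_io import Track


def great_circle_distance(p1: Tuple[float, float], p2: Tuple[float, float]) -> float:
    """Great-circle distance in metres between two (lon, lat) points."""
    return float(haversine_m(p1[0], p1[1], p2[0], p2[1]))


def compute_speeds(track: Track, max_dt: float) -> pd.DataFrame:
    """Over-ground speed for every consecutive fix pair with dt <= max_dt.

    Pairs spanning a gap longer than ``max_dt`` seconds (e.g. the two-hour
    sleep between duty-cycle bursts) are skipped: the straight-line speed
    across such gaps is not an estimate of instantaneous speed.

    Returns a DataFrame with one row per retained pair: ``mid_time``
    (midpoint timestamp), ``speed`` (m/s), ``dt`` (s) and the endpoint fix
    indices ``i0``/``i1``.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 fixes to compute speeds")
    t = track.t_seconds
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dist = haversine_m(track.lon[:-1], track.lat[:-1], track.lon[1:], track.lat[1:])
    keep = dt <= max_dt
    i0 = np.flatnonzero(keep)
    mid = track.time[:-1][keep] + pd.to_timedelta(dt[keep] / 2.0, unit="s")
    return pd.DataFrame({
        "mid_time": mid,
        "speed": dist[keep] / dt[keep],
        "dt": dt[keep],
        "i0": i0,
        "i1": i0 + 1,
    })


@dataclass
class ClusterSummary:
    """One burst of fixes from a duty-cycled track.

    ``speed`` is the median of within-cluster consecutive speeds — the
    "accurate speed within each cluster" a burst of closely spaced fixes
    provides. Clusters with fewer than two fixes carry no defined speed and
    are flagged (``defined=False``).
    """

    cluster_id: int
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    lon: float
    lat: float
    speed: float  # m/s; NaN when undefined
    n_fixes: int
    defined: bool


def segment_clusters(track: Track, gap_s: float = 600.0) -> List[ClusterSummary]:
    """Split a track into fix clusters wherever the inter-fix gap exceeds
    ``gap_s`` seconds (strictly: a gap exactly equal to ``gap_s`` does not
    split). The default 600 s cleanly separates bursts logged every two
    hours. Centroid is the arithmetic mean lon/lat of the cluster's fixes.
    """
    n = len(track)
    if n == 0:
        return []
    t = track.t_seconds
    breaks = np.flatnonzero(np.diff(t) > gap_s) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n]))
    out = []
    for cid, (a, b) in enumerate(zip(starts, ends)):
        n_fix = b - a
        if n_fix >= 2:
            dist = haversine_m(track.lon[a:b - 1], track.lat[a:b - 1],
                               track.lon[a + 1:b], track.lat[a + 1:b])
            speeds = dist / np.diff(t[a:b])
            rep = float(np.median(speeds))
            defined = True
        else:
            rep = float("nan")
            defined = False
        out.append(ClusterSummary(
            cluster_id=cid,
            t_start=track.time[a], t_end=track.time[b - 1],
            lon=float(np.mean(track.lon[a:b])), lat=float(np.mean(track.lat[a:b])),
            speed=rep, n_fixes=int(n_fix), defined=defined))
    return out


def merge_windows(track: Track, window_s: float = 120.0) -> Track:
    """Collapse fixes into one location per fixed time window.

    The time axis is partitioned into consecutive half-open windows
    ``[k*window_s, (k+1)*window_s)`` starting at the first fix. Each
    non-empty window becomes a single fix at the arithmetic mean lon/lat
    with its timestamp at the window centre; empty windows produce nothing.
    Thins autocorrelated 5-s fixes before habitat statistics.

    Windows that straddle the antimeridian are averaged on a continuous
    longitude branch and wrapped back.
    """
    n = len(track)
    if track.meta.get("merged_window_s") == float(window_s):
        # already merged at this window: consecutive fixes are >= window_s
        # apart, so re-merging could only shift centre timestamps by half a
        # window; treat as a no-op instead (idempotence by provenance).
        return track
    if n == 0:
        return track.subset(np.array([], dtype=int))
    t = track.t_seconds
    k = np.floor((t - t[0]) / float(window_s)).astype(int)
    uniq = np.unique(k)
    times, lons, lats = [], [], []
    for kk in uniq:
        sel = k == kk
        lon_w = track.lon[sel]
        if lon_w.max() - lon_w.min() > 180.0:  # dateline-crossing window
            lon_w = np.where(lon_w < 0, lon_w + 360.0, lon_w)
        lon_c = float(np.mean(lon_w))
        if lon_c > 180.0:
            lon_c -= 360.0
        lons.append(lon_c)
        lats.append(float(np.mean(track.lat[sel])))
        times.append(t[0] + (kk + 0.5) * window_s)
    time = pd.to_datetime(np.round(np.asarray(times) * 1e9).astype("int64"), utc=True)
    return Track(track.id, time, lons, lats, regime=track.regime,
                 meta={**track.meta, "merged_window_s": float(window_s)})


@dataclass
class TrackSummary:
    """Trip-level summary: path length, maximum range from the colony, and
    convex-hull area of the visited region."""

    length_km: float
    furthest_km: float
    area_km2: float


def summarize_track(track: Track, colony: Tuple[float, float]) -> TrackSummary:
    """Summarise a trip relative to a colony location.

    length = sum of consecutive great-circle distances; furthest = maximum
    great-circle distance from the colony over fixes; area = planar convex
    hull of the fixes in a Lambert azimuthal equal-area projection centred
    on the colony (zero for fewer than three non-collinear fixes).
    """
    if len(track) == 0:
        raise ValueError("cannot summarise an empty track")
    if len(track) == 1:
        length = 0.0
        area = 0.0
    else:
        length = float(np.sum(haversine_m(track.lon[:-1], track.lat[:-1],
                                          track.lon[1:], track.lat[1:])))
        x, y = azimuthal_equal_area_xy(track.lon, track.lat, colony[0], colony[1])
        hull = MultiPoint(list(zip(np.atleast_1d(x), np.atleast_1d(y)))).convex_hull
        area = float(getattr(hull, "area", 0.0))
    furthest = float(np.max(haversine_m(colony[0], colony[1], track.lon, track.lat)))
    return TrackSummary(length_km=length / 1e3, furthest_km=furthest / 1e3,
                        area_km2=area / 1e6)
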