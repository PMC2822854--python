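"""Association between behaviour-classified locations and the seafloor.

The core idea: to ask whether a bird preferentially used particular depths,
compare the depths under its fixes with a null distribution of depths it
*could* have used. The null is built by rigidly rotating the whole track
about its origin (the colony / first fix) through fifteen 22.5-degree
steps — fifteen equally spaced rotations through 360 degrees. Rotation is
an isometry of the sphere about the origin, so every rotated replicate
preserves the track's internal structure (leg lengths, turning pattern)
while relocating it over different habitat. Locations over land are
excluded from the null pool.

Observed and null depth distributions are then compared with repeated
two-sample Kolmogorov-Smirnov tests on equally sized random subsamples of
the null pool (1000 runs by default), and occupancy of the 600-1000 m
shelf-break depth band is reported per behavioural class.

Depth here is positive-down: depth = -elevation, so the 600-1000 m band is
elevation in [-1000, -600] m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from ._geodesy import destination_point, haversine_m, initial_bearing_deg
from .track_io import RasterGrid, Track

SHELF_BREAK_BAND_M = (600.0, 1000.0)


# ---------------------------------------------------------------------------
# Raster sampling
# ---------------------------------------------------------------------------

def sample_raster_at(grid: RasterGrid, points) -> np.ndarray:
    """Nearest-cell raster values at (lon, lat) points.

    ``points`` is a sequence of (lon, lat) pairs or an (n, 2) array.
    Points exactly on a cell edge follow the floor convention of
    :meth:`RasterGrid.cell_index`. Masked (nodata) cells return NaN.
    A point outside the grid extent raises, naming the point.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lon, lat = pts[:, 0], pts[:, 1]
    inside = grid.contains(lon, lat)
    if not np.all(inside):
        i = int(np.flatnonzero(~inside)[0])
        raise ValueError(f"point (lon={lon[i]}, lat={lat[i]}) is outside the "
                         f"raster extent [{grid.west}, {grid.east}] x "
                         f"[{grid.south}, {grid.north}]")
    row, col = grid.cell_index(lon, lat)
    vals = grid.values[row, col]
    return np.ma.filled(vals, np.nan)


# ---------------------------------------------------------------------------
# Rotation null
# ---------------------------------------------------------------------------

@dataclass
class RotationNullConfig:
    """Rotation-null settings: by default fifteen 22.5-degree rotations
    (k * 22.5 for k = 1..15), i.e. every non-identity multiple of 22.5 in a
    full turn. ``origin`` defaults to the track's first fix."""

    n_angles: int = 15
    angle_step: float = 22.5
    origin: Optional[Tuple[float, float]] = None

    @property
    def angles(self) -> np.ndarray:
        return self.angle_step * np.arange(1, self.n_angles + 1)


def rotate_track(track: Track, angle: float, origin: Tuple[float, float]) -> Track:
    """Rigidly rotate a track about ``origin`` by ``angle`` degrees
    (positive clockwise, i.e. added to each fix's bearing from the origin).

    Each fix keeps its great-circle distance from the origin while its
    initial bearing from the origin shifts by ``angle``; timestamps and all
    other per-fix fields are unchanged. This is a rotation of the sphere
    about the axis through the origin, so inter-fix distances are preserved.
    """
    lon0, lat0 = origin
    d = haversine_m(lon0, lat0, track.lon, track.lat)
    brg = initial_bearing_deg(lon0, lat0, track.lon, track.lat)
    new_lon, new_lat = destination_point(lon0, lat0, brg + angle, d)
    out = track.subset(np.arange(len(track)))
    out.lon = np.atleast_1d(np.asarray(new_lon, dtype=float))
    out.lat = np.atleast_1d(np.asarray(new_lat, dtype=float))
    out.meta["rotation_deg"] = float(angle)
    return out


def observed_depth_samples(track: Track, grid: RasterGrid,
                           labels: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Depths under the observed fixes (positive-down metres), dropping
    land (elevation >= 0) and nodata cells. Optional per-fix behaviour
    labels are carried through."""
    return _depth_frame(track, grid, labels, source="OBSERVED", angle=0.0)


def build_rotation_null(track: Track, grid: RasterGrid,
                        cfg: Optional[RotationNullConfig] = None,
                        labels: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Pooled depth samples under all rotated replicates of a track.

    For each angle k * angle_step (k = 1..n_angles) the track is rotated
    about the origin and depths sampled under the rotated fixes. Land
    (elevation >= 0), nodata cells and rotated fixes falling outside the
    raster extent are dropped; drop counts are stored in ``.attrs``.
    Behaviour labels are carried over from the unrotated fixes.

    Returns a DataFrame with columns lon, lat, depth_m, label, source
    ("ROTATED"), angle_deg.
    """
    if len(track) == 0:
        raise ValueError("cannot build a rotation null from an empty track")
    cfg = cfg or RotationNullConfig()
    origin = cfg.origin if cfg.origin is not None else (float(track.lon[0]), float(track.lat[0]))
    frames = []
    n_outside = 0
    for angle in cfg.angles:
        rot = rotate_track(track, float(angle), origin)
        df = _depth_frame(rot, grid, labels, source="ROTATED", angle=float(angle))
        n_outside += df.attrs["n_outside_extent"]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_outside_extent"] = int(n_outside)
    out.attrs["n_angles"] = int(cfg.n_angles)
    return out


def _depth_frame(track: Track, grid: RasterGrid, labels, source: str,
                 angle: float) -> pd.DataFrame:
    lon, lat = track.lon, track.lat
    inside = grid.contains(lon, lat)
    lab = np.asarray(labels) if labels is not None else np.full(len(track), -1)
    if lab.shape != (len(track),):
        raise ValueError("labels must align with the track's fixes")
    elev = np.full(len(track), np.nan)
    if inside.any():
        elev[inside] = sample_raster_at(grid, np.column_stack([lon[inside], lat[inside]]))
    sea = inside & np.isfinite(elev) & (elev < 0.0)
    df = pd.DataFrame({
        "lon": lon[sea], "lat": lat[sea],
        "depth_m": -elev[sea],
        "label": lab[sea],
        "source": source,
        "angle_deg": angle,
    })
    df.attrs["n_outside_extent"] = int((~inside).sum())
    df.attrs["n_land_or_nodata"] = int((inside & ~sea).sum())
    return df


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov machinery
# ---------------------------------------------------------------------------

@dataclass
class KSResult:
    """Two-sample KS outcome: D is the supremum gap between the two ECDFs,
    p the asymptotic Kolmogorov p-value at effective n = n1 n2/(n1+n2)."""

    D: float
    p: float
    n1: int
    n2: int


def ks_two_sample(a, b) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup_x |ECDF_a(x) - ECDF_b(x)|, computed by an exact sweep over the
    pooled sample points; the p-value uses the asymptotic Kolmogorov
    survival function at sqrt(n1 n2 / (n1 + n2)) * D.
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / n1
    cdf_b = np.searchsorted(b, pooled, side="right") / n2
    D = float(np.max(np.abs(cdf_a - cdf_b)))
    en = n1 * n2 / (n1 + n2)
    p = float(np.clip(kolmogorov(np.sqrt(en) * D), 0.0, 1.0))
    return KSResult(D=D, p=p, n1=n1, n2=n2)


@dataclass
class RepeatedTestResult:
    """Outcome of repeatedly comparing the observed sample against equally
    sized random subsamples of the null pool.

    ``significant_overall`` summarises "significant in this many runs" as
    proportion-significant >= ``overall_threshold`` (default 0.95); the
    per-run results are retained for any other aggregation.
    """

    n_runs: int
    alpha: float
    D: np.ndarray
    p: np.ndarray
    prop_significant: float
    median_D: float
    median_p: float
    overall_threshold: float = 0.95
    seed: Optional[int] = None

    @property
    def significant_overall(self) -> bool:
        return self.prop_significant >= self.overall_threshold


def repeated_subsample_test(observed, null_pool, n_runs: int = 1000,
                            alpha: float = 0.05, seed: Optional[int] = None,
                            overall_threshold: float = 0.95) -> RepeatedTestResult:
    """KS-compare ``observed`` against ``n_runs`` equally sized random
    subsamples (drawn without replacement) of ``null_pool``.

    Requires the pool to be at least as large as the observed sample.
    Fully reproducible for a given seed.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    pool = np.asarray(null_pool, dtype=float).ravel()
    n = len(observed)
    if n == 0:
        raise ValueError("observed sample is empty")
    if len(pool) < n:
        raise ValueError(f"null pool ({len(pool)}) smaller than observed sample ({n})")
    rng = np.random.default_rng(seed)
    obs_sorted = np.sort(observed)
    D = np.empty(n_runs)
    p = np.empty(n_runs)
    for i in range(n_runs):
        sub = pool[rng.choice(len(pool), size=n, replace=False)]
        r = _ks_presorted(obs_sorted, np.sort(sub))
        D[i], p[i] = r
    prop = float(np.mean(p < alpha))
    return RepeatedTestResult(n_runs=n_runs, alpha=alpha, D=D, p=p,
                              prop_significant=prop,
                              median_D=float(np.median(D)),
                              median_p=float(np.median(p)),
                              overall_threshold=overall_threshold, seed=seed)


def _ks_presorted(a: np.ndarray, b: np.ndarray):
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    D = float(np.max(np.abs(np.searchsorted(a, pooled, side="right") / n1
                            - np.searchsorted(b, pooled, side="right") / n2)))
    en = n1 * n2 / (n1 + n2)
    return D, float(np.clip(kolmogorov(np.sqrt(en) * D), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Depth-band occupancy
# ---------------------------------------------------------------------------

def depth_band_occupancy(depths, band: Tuple[float, float] = SHELF_BREAK_BAND_M,
                         labels=None):
    """Fraction of depth samples inside the band (inclusive on both edges).

    With ``labels`` given, returns a dict mapping each label to the
    occupancy of its samples. Empty inputs yield NaN.
    """
    depths = np.asarray(depths, dtype=float).ravel()
    lo, hi = band
    if labels is None:
        if len(depths) == 0:
            return float("nan")
        return float(np.mean((depths >= lo) & (depths <= hi)))
    labels = np.asarray(labels).ravel()
    if labels.shape != depths.shape:
        raise ValueError("labels must align with depths")
    return {lab: depth_band_occupancy(depths[labels == lab], band)
            for lab in np.unique(labels)}
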