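"""Reading, validation and filtering of GPS tracks and bathymetry rasters.

Tracks are tables of *fixes* (time, lon, lat, optional satellite count and
quality flag) in WGS84 decimal degrees with UTC timestamps. Rasters are
regular lon/lat elevation grids, metres relative to sea level (negative =
depth), with a nodata mask.

Accuracy filtering follows standard GPS practice: a position solved with at
least four satellites ("3D fix") resolves altitude and is the higher
accuracy class; fixes below that are dropped before analysis.
"""

from __future__ import annotations

import enum
import io
import os
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd


class FixQuality(enum.Enum):
    """GPS solution quality class as reported by the receiver."""

    FIX3D = "FIX3D"
    FIX2D = "FIX2D"
    UNKNOWN = "UNKNOWN"


class Regime(enum.Enum):
    """Sampling regime of a deployment.

    CONTINUOUS_5S: continuous fixes at 5-s interval (high resolution).
    BURST_2H: a short burst of fixes every two hours (duty-cycled).
    """

    CONTINUOUS_5S = "CONTINUOUS_5S"
    BURST_2H = "BURST_2H"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Fix:
    """A single GPS observation."""

    time: pd.Timestamp
    lon: float
    lat: float
    n_sats: Optional[int] = None
    quality: FixQuality = FixQuality.UNKNOWN

    def __post_init__(self):
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if self.n_sats is not None and self.n_sats < 0:
            raise ValueError(f"negative satellite count {self.n_sats}")


class Track:
    """A time-ordered sequence of fixes for one deployment.

    Internally column-oriented (numpy arrays) for fast kinematics; the
    sequence protocol yields :class:`Fix` views. Timestamps are strictly
    increasing; duplicate timestamps are rejected at construction.

    Parameters
    ----------
    id : deployment identifier (e.g. the bird's ring number).
    time : array-like of UTC timestamps (anything ``pd.to_datetime`` accepts).
    lon, lat : WGS84 decimal degrees.
    n_sats : satellite counts; NaN where absent.
    quality : :class:`FixQuality` per fix.
    regime : sampling regime tag.
    states : optional per-fix true behavioural state labels (synthetic tracks).
    """

    def __init__(self, id: str, time, lon, lat, n_sats=None,
                 quality=None, regime: Regime = Regime.OTHER,
                 states=None, meta: Optional[dict] = None):
        t = pd.DatetimeIndex(pd.to_datetime(time, utc=True))
        n = len(t)
        self.id = str(id)
        self.time = t
        self.lon = np.asarray(lon, dtype=float)
        self.lat = np.asarray(lat, dtype=float)
        if self.lon.shape != (n,) or self.lat.shape != (n,):
            raise ValueError("time, lon and lat must have equal length")
        if n_sats is None:
            self.n_sats = np.full(n, np.nan)
        else:
            self.n_sats = np.asarray(n_sats, dtype=float)
        if quality is None:
            self.quality = np.array([FixQuality.UNKNOWN] * n, dtype=object)
        else:
            self.quality = np.asarray(
                [q if isinstance(q, FixQuality) else FixQuality(str(q)) for q in quality],
                dtype=object)
        self.regime = regime
        self.states = None if states is None else np.asarray(states)
        if self.states is not None and self.states.shape != (n,):
            raise ValueError("states must align with fixes")
        self.meta = dict(meta or {})
        self._validate()

    def _validate(self):
        if len(self) > 0:
            if np.any((self.lon < -180) | (self.lon > 180)):
                raise ValueError("longitude outside [-180, 180]")
            if np.any((self.lat < -90) | (self.lat > 90)):
                raise ValueError("latitude outside [-90, 90]")
        if len(self) > 1:
            dt = np.diff(self.time.asi8)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValueError(
                    f"track {self.id!r}: timestamps not strictly increasing at fix {i + 1}")

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.time)

    def __getitem__(self, i: int) -> Fix:
        ns = self.n_sats[i]
        return Fix(self.time[i], float(self.lon[i]), float(self.lat[i]),
                   None if np.isnan(ns) else int(ns), self.quality[i])

    def __iter__(self) -> Iterator[Fix]:
        return (self[i] for i in range(len(self)))

    @property
    def fixes(self) -> list:
        return list(self)

    @property
    def t_seconds(self) -> np.ndarray:
        """Timestamps as float seconds since the Unix epoch."""
        return self.time.asi8 / 1e9

    def subset(self, index) -> "Track":
        """New Track keeping fixes at the given boolean mask or index array."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Track(self.id, self.time[idx], self.lon[idx], self.lat[idx],
                     self.n_sats[idx], self.quality[idx], self.regime,
                     None if self.states is None else self.states[idx],
                     dict(self.meta))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "id": self.id,
            "time": self.time,
            "lon": self.lon,
            "lat": self.lat,
            "n_sats": self.n_sats,
            "quality": [q.value for q in self.quality],
        })
        if self.states is not None:
            df["state"] = self.states
        return df

    def __repr__(self) -> str:
        return (f"Track(id={self.id!r}, n_fixes={len(self)}, "
                f"regime={self.regime.value})")


@dataclass
class RasterGrid:
    """Regular geographic (lon/lat) grid of elevation values.

    Row 0 is the northernmost row (ESRI ASCII convention). ``values`` is a
    masked array in metres, negative below sea level. ``west``/``north``
    are the outer edges of the grid; the centre of cell (0, 0) is
    ``(west + dlon/2, north - dlat/2)``.
    """

    west: float
    north: float
    dlon: float
    dlat: float
    values: np.ma.MaskedArray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dlon <= 0 or self.dlat <= 0:
            raise ValueError("cell sizes must be positive")
        self.values = np.ma.masked_invalid(np.ma.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.dlon

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.dlat

    @property
    def origin(self) -> tuple:
        """Centre (lon, lat) of cell (0, 0)."""
        return (self.west + self.dlon / 2.0, self.north - self.dlat / 2.0)

    def cell_index(self, lon, lat):
        """(row, col) of the cell containing each point, by the floor
        convention: a point exactly on a shared edge belongs to the cell
        for which that edge is the lower bound of its index interval."""
        col = np.floor((np.asarray(lon, dtype=float) - self.west) / self.dlon).astype(int)
        row = np.floor((self.north - np.asarray(lat, dtype=float)) / self.dlat).astype(int)
        return row, col

    def contains(self, lon, lat):
        """Boolean mask of points inside the grid extent (east/south edges
        exclusive, matching the floor indexing convention)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= self.west) & (lon < self.east) & (lat > self.south) & (lat <= self.north)

    def cell_centres(self):
        """(lons, lats) 1-D arrays of cell-centre coordinates."""
        lons = self.west + (np.arange(self.ncols) + 0.5) * self.dlon
        lats = self.north - (np.arange(self.nrows) + 0.5) * self.dlat
        return lons, lats


# ---------------------------------------------------------------------------
# Track I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("time", "lon", "lat")


def read_track(path, format: str = None, id: Optional[str] = None,
               regime: Regime = Regime.OTHER) -> Track:
    """Read a track from a CSV fix table or a GPX 1.1 file.

    CSV needs named columns ``time``, ``lon``, ``lat``; ``id``, ``n_sats``
    and ``quality`` are optional. Rows are sorted by time; rows sharing a
    timestamp are collapsed to the first occurrence with a warning.

    Parameters
    ----------
    format : "csv" or "gpx"; inferred from the file extension when omitted.
    """
    path = os.fspath(path)
    if format is None:
        format = "gpx" if path.lower().endswith(".gpx") else "csv"
    format = format.lower()
    if format == "csv":
        return _read_track_csv(path, id=id, regime=regime)
    if format == "gpx":
        return _read_track_gpx(path, id=id, regime=regime)
    raise ValueError(f"unknown track format {format!r} (expected 'csv' or 'gpx')")


def _read_track_csv(path, id=None, regime=Regime.OTHER) -> Track:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no fix rows")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    time = pd.to_datetime(df["time"], utc=True, errors="coerce", format="ISO8601")
    bad = time.isna() & df["time"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: unparsable time {df['time'].iloc[row]!r} at row {row + 2}")
    for col in ("lon", "lat"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: unparsable {col} {df[col].iloc[row]!r} at row {row + 2}")
        df[col] = vals
    if time.isna().any() or df[["lon", "lat"]].isna().any().any():
        row = int(np.flatnonzero((time.isna() | df[["lon", "lat"]].isna().any(axis=1)).to_numpy())[0])
        raise ValueError(f"{path}: missing time/lon/lat value at row {row + 2}")

    df = df.assign(time=time)
    order = np.argsort(df["time"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    dup = df["time"].duplicated(keep="first")
    if dup.any():
        warnings.warn(f"{path}: collapsed {int(dup.sum())} duplicate-timestamp row(s), "
                      "keeping first occurrence", stacklevel=2)
        df = df.loc[~dup].reset_index(drop=True)

    n_sats = pd.to_numeric(df["n_sats"], errors="coerce").to_numpy() if "n_sats" in df else None
    quality = ([FixQuality(q) if isinstance(q, str) and q in FixQuality.__members__
                else FixQuality.UNKNOWN for q in df["quality"]]
               if "quality" in df else None)
    track_id = id if id is not None else (str(df["id"].iloc[0]) if "id" in df else os.path.basename(path))
    return Track(track_id, df["time"], df["lon"].to_numpy(), df["lat"].to_numpy(),
                 n_sats, quality, regime)


_GPX_NS = {"gpx": "http://www.topografix.com/GPX/1/1"}


def _read_track_gpx(path, id=None, regime=Regime.OTHER) -> Track:
    tree = ET.parse(path)
    pts = tree.getroot().findall(".//gpx:trkpt", _GPX_NS)
    if not pts:
        # fall back to namespace-free files
        pts = tree.getroot().findall(".//trkpt")
    if not pts:
        raise ValueError(f"{path}: no <trkpt> elements found")
    rows = []
    for i, pt in enumerate(pts):
        try:
            lat = float(pt.attrib["lat"])
            lon = float(pt.attrib["lon"])
        except (KeyError, ValueError) as e:
            raise ValueError(f"{path}: bad trkpt #{i + 1}: {e}") from None
        t_el = pt.find("gpx:time", _GPX_NS) if pt.find("gpx:time", _GPX_NS) is not None else pt.find("time")
        if t_el is None or not t_el.text:
            raise ValueError(f"{path}: trkpt #{i + 1} lacks a <time> element")
        sat_el = pt.find("gpx:sat", _GPX_NS) if pt.find("gpx:sat", _GPX_NS) is not None else pt.find("sat")
        fix_el = pt.find("gpx:fix", _GPX_NS) if pt.find("gpx:fix", _GPX_NS) is not None else pt.find("fix")
        n_sats = float(sat_el.text) if sat_el is not None and sat_el.text else np.nan
        q = FixQuality.UNKNOWN
        if fix_el is not None and fix_el.text:
            q = {"3d": FixQuality.FIX3D, "2d": FixQuality.FIX2D}.get(fix_el.text.strip().lower(),
                                                                     FixQuality.UNKNOWN)
        rows.append((t_el.text, lon, lat, n_sats, q))
    time = pd.to_datetime([r[0] for r in rows], utc=True)
    order = np.argsort(time.to_numpy(), kind="stable")
    rows = [rows[i] for i in order]
    time = time[order]
    keep = ~pd.Index(time).duplicated(keep="first")
    if not keep.all():
        warnings.warn(f"{path}: collapsed {int((~keep).sum())} duplicate-timestamp trkpt(s)",
                      stacklevel=2)
        rows = [r for r, k in zip(rows, keep) if k]
        time = time[keep]
    track_id = id if id is not None else os.path.basename(path)
    return Track(track_id, time,
                 [r[1] for r in rows], [r[2] for r in rows],
                 [r[3] for r in rows], [r[4] for r in rows], regime)


def write_track(track: Track, path) -> None:
    """Write a track as CSV with columns id,time,lon,lat,n_sats,quality.

    Floats are written with ``repr`` (shortest round-trip) precision and
    times as ISO-8601 UTC, so ``read_track(write_track(t))`` reproduces
    every field bit-identically.
    """
    with open(path, "w", newline="") as fh:
        fh.write("id,time,lon,lat,n_sats,quality\n")
        for i in range(len(track)):
            ns = track.n_sats[i]
            ns_s = "" if np.isnan(ns) else str(int(ns)) if float(ns).is_integer() else repr(ns)
            t = track.time[i].strftime("%Y-%m-%dT%H:%M:%S")
            frac = track.time[i].nanosecond + track.time[i].microsecond * 1000
            if frac:
                t += f".{frac:09d}".rstrip("0")
            fh.write(f"{track.id},{t}Z,{float(track.lon[i])!r},{float(track.lat[i])!r},"
                     f"{ns_s},{track.quality[i].value}\n")


def filter_fixes(track: Track, min_sats: int = 4) -> Track:
    """Drop low-accuracy fixes, keeping "3D fixes and higher".

    A fix is retained when its satellite count is ``>= min_sats`` *or* its
    quality flag is FIX3D (device logs may carry either field). Fixes with
    no satellite count and UNKNOWN quality are uninformative and dropped.
    Drop counts are recorded in ``result.meta['filter_report']``.

    Idempotent: filtering an already-filtered track is the identity.
    """
    has_sats = ~np.isnan(track.n_sats)
    good_sats = has_sats & (track.n_sats >= min_sats)
    is_3d = np.array([q is FixQuality.FIX3D for q in track.quality], dtype=bool)
    keep = good_sats | is_3d
    uninformative = ~has_sats & ~is_3d
    report = {
        "n_input": len(track),
        "n_kept": int(keep.sum()),
        "n_low_sats": int((~keep & has_sats).sum()),
        "n_uninformative": int((uninformative & ~keep).sum()),
        "min_sats": int(min_sats),
    }
    out = track.subset(keep)
    out.meta["filter_report"] = report
    return out


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def read_raster(path) -> RasterGrid:
    """Read a single-band regular lon/lat elevation grid.

    Supports the ESRI ASCII grid format (.asc: ncols/nrows/xll/cellsize
    header then row-major values, row 0 northernmost). Projected grids
    (coordinates outside geographic bounds) are rejected with instructions
    to reproject; GeoTIFF and other binary formats are rejected with
    instructions to convert (e.g. ``gdal_translate -of AAIGrid``).
    """
    path = os.fspath(path)
    with open(path, "rb") as fh:
        head = fh.read(6)
    if head[:4] in (b"II*\x00", b"MM\x00*"):
        raise ValueError(
            f"{path}: GeoTIFF input is not supported; convert to an ESRI ASCII "
            "grid in geographic (lon/lat WGS84) coordinates first "
            "(e.g. gdal_translate -of AAIGrid)")
    if not head.lstrip().lower().startswith(b"ncols"):
        raise ValueError(f"{path}: not an ESRI ASCII grid (expected 'ncols' header)")
    return _read_ascii_grid(path)


def _read_ascii_grid(path) -> RasterGrid:
    header = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "dx", "dy", "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
        else:
            data_start = i
            break
    else:
        data_start = len(lines)
    for key in ("ncols", "nrows"):
        if key not in header:
            raise ValueError(f"{path}: ASCII grid header missing {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if "cellsize" in header:
        dlon = dlat = header["cellsize"]
    elif "dx" in header and "dy" in header:
        dlon, dlat = header["dx"], header["dy"]
    else:
        raise ValueError(f"{path}: ASCII grid header missing cellsize")
    if dlon <= 0 or dlat <= 0:
        raise ValueError(f"{path}: non-positive cell size")
    if "xllcorner" in header:
        west = header["xllcorner"]
    elif "xllcenter" in header:
        west = header["xllcenter"] - dlon / 2.0
    else:
        raise ValueError(f"{path}: ASCII grid header missing xllcorner/xllcenter")
    if "yllcorner" in header:
        south = header["yllcorner"]
    elif "yllcenter" in header:
        south = header["yllcenter"] - dlat / 2.0
    else:
        raise ValueError(f"{path}: ASCII grid header missing yllcorner/yllcenter")
    north = south + nrows * dlat
    if not (-360.0 <= west and west + ncols * dlon <= 360.0 and -90.0 <= south and north <= 90.0):
        raise ValueError(
            f"{path}: grid coordinates lie outside geographic bounds; the raster "
            "appears to be in a projected CRS — reproject to lon/lat WGS84 first")
    values = np.loadtxt(io.StringIO("".join(lines[data_start:])), dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {values.shape} does not match header "
                         f"({nrows} rows x {ncols} cols)")
    masked = np.ma.masked_invalid(values)
    if "nodata_value" in header:
        masked = np.ma.masked_values(masked, header["nodata_value"], rtol=0, atol=0)
    return RasterGrid(west=west, north=north, dlon=dlon, dlat=dlat, values=masked,
                      meta={"path": path})


def write_raster(grid: RasterGrid, path, nodata: float = -9999.0) -> None:
    """Write a RasterGrid as an ESRI ASCII grid."""
    vals = grid.values.filled(nodata)
    if grid.dlon == grid.dlat:
        cell_lines = f"cellsize {grid.dlon!r}\n"
    else:
        cell_lines = f"dx {grid.dlon!r}\ndy {grid.dlat!r}\n"
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n"
                 f"nrows {grid.nrows}\n"
                 f"xllcorner {grid.west!r}\n"
                 f"yllcorner {grid.south!r}\n"
                 + cell_lines +
                 f"NODATA_value {nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
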