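"""Synthetic tracks and bathymetry with the structure the analysis assumes.

No deposited tracking data exist for the study system, so every stage of
the pipeline is exercised on simulated inputs that reproduce its key
statistical features:

* two movement modes — slow surface drift (natural-scale mean 0.83 m/s,
  variance 0.13) and fast flight (mean 10.20 m/s, variance 27.0, the large
  variance standing in for wind-driven ground-speed variation) — switched
  by a discrete-time Markov chain, with log-normal speeds and
  state-dependent heading persistence (tight in flight, loose in drift);
* the two field sampling regimes: continuous 5-s fixes, and short bursts
  of fixes every two hours;
* behaviour-dependent fix-acquisition probability (sitting birds acquire
  satellites more reliably than flying ones);
* a coastal bathymetry with land, a shallow shelf, a monotone shelf-break
  band containing every depth in 600-1000 m, and an abyssal plain.

All generators are bit-identically reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from ._geodesy import destination_point, initial_bearing_deg
from .movement_model import lognormal_params_from_moments
from .track_io import RasterGrid, Regime, Track

STATE_SLOW, STATE_FAST = 0, 1
_EPOCH0 = pd.Timestamp("2006-02-23T00:00:00Z")  # arbitrary austral-summer origin


@dataclass
class SimConfig:
    """Two-state movement simulation settings.

    Speed moments are natural-scale (m/s and (m/s)^2) log-normal moments.
    ``p_slow_to_fast``/``p_fast_to_slow`` are per-step switch
    probabilities; at the 5-s default step the defaults give mean bout
    lengths of ~17 min in either state. ``kappa_*`` are von Mises heading
    concentrations: flight holds its heading, drift wanders.
    """

    slow_mean: float = 0.83
    slow_var: float = 0.13
    fast_mean: float = 10.20
    fast_var: float = 27.0
    p_slow_to_fast: float = 0.005
    p_fast_to_slow: float = 0.005
    fix_interval_s: float = 5.0
    duration_s: float = 86_400.0
    kappa_slow: float = 0.5
    kappa_fast: float = 50.0
    seed: Optional[int] = None

    def __post_init__(self):
        if min(self.slow_mean, self.fast_mean) <= 0:
            raise ValueError("mode means must be positive")
        for p in (self.p_slow_to_fast, self.p_fast_to_slow):
            if not 0.0 <= p <= 1.0:
                raise ValueError("switch probabilities must lie in [0, 1]")


@dataclass
class BathyConfig:
    """Synthetic coastal bathymetry layout (all longitudes in degrees).

    West of ``coast_lon`` is land; eastward the seafloor deepens through a
    shallow shelf, a steep slope, the 600-1000 m shelf-break band (width
    ``band_width_deg``), and on to a flat abyssal plain. Depth varies with
    longitude only, so the band is a connected north-south strip.
    """

    west: float = 0.0
    south: float = -1.5
    ncols: int = 2400
    nrows: int = 1200
    cell_deg: float = 0.0025  # ~270 m, the scale of national bathymetry grids
    coast_lon: float = 1.0
    land_elev: float = 100.0
    shelf_depth: float = 150.0
    shelf_width_deg: float = 1.0
    slope_width_deg: float = 0.4
    band_width_deg: float = 0.6
    descent_width_deg: float = 0.5
    abyssal_depth: float = 2500.0
    noise_sd: float = 2.0
    seed: Optional[int] = None

    def __post_init__(self):
        if not (self.shelf_depth < 600.0 and self.abyssal_depth > 1000.0):
            raise ValueError("shelf depth must be < 600 m and abyssal depth > 1000 m")

    @property
    def band_west(self) -> float:
        """Western (600 m) edge of the shelf-break band."""
        return self.coast_lon + self.shelf_width_deg + self.slope_width_deg

    @property
    def band_east(self) -> float:
        """Eastern (1000 m) edge of the shelf-break band."""
        return self.band_west + self.band_width_deg


def make_shelf_bathymetry(cfg: Optional[BathyConfig] = None) -> RasterGrid:
    """Build the synthetic coastal elevation grid described by ``cfg``.

    The longitude profile is piecewise linear and monotone seaward of the
    coast; small seeded noise is added away from the shelf-break band so
    the band retains every depth in [600, 1000] m as a connected monotone
    strip. Deterministic for a given seed.
    """
    cfg = cfg or BathyConfig()
    lons = cfg.west + (np.arange(cfg.ncols) + 0.5) * cfg.cell_deg
    x = lons
    b0, b1 = cfg.band_west, cfg.band_east
    shelf_edge = cfg.coast_lon + cfg.shelf_width_deg
    elev_profile = np.piecewise(
        x,
        [x < cfg.coast_lon,
         (x >= cfg.coast_lon) & (x < shelf_edge),
         (x >= shelf_edge) & (x < b0),
         (x >= b0) & (x < b1),
         (x >= b1) & (x < b1 + cfg.descent_width_deg),
         x >= b1 + cfg.descent_width_deg],
        [lambda x: cfg.land_elev,
         lambda x: -cfg.shelf_depth * (x - cfg.coast_lon) / cfg.shelf_width_deg,
         lambda x: -cfg.shelf_depth - (600.0 - cfg.shelf_depth) * (x - shelf_edge) / cfg.slope_width_deg,
         lambda x: -600.0 - 400.0 * (x - b0) / cfg.band_width_deg,
         lambda x: -1000.0 - (cfg.abyssal_depth - 1000.0) * (x - b1) / cfg.descent_width_deg,
         lambda x: -cfg.abyssal_depth])
    values = np.tile(elev_profile, (cfg.nrows, 1))
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        noise = rng.normal(scale=cfg.noise_sd, size=values.shape)
        in_band = (x >= b0) & (x < b1)
        noise[:, in_band] = 0.0  # keep the band's exact 600-1000 m coverage
        values = values + noise
    north = cfg.south + cfg.nrows * cfg.cell_deg
    return RasterGrid(west=cfg.west, north=north, dlon=cfg.cell_deg,
                      dlat=cfg.cell_deg, values=np.ma.asarray(values),
                      meta={"synthetic": True, "seed": cfg.seed})


def _advance_great_circle(lon0, lat0, bearings_deg, distances_m):
    """Sequentially advance a position along per-step great circles.

    Returns (lon, lat) arrays of length len(bearings)+1 including the
    start. Scalar math in the loop (exact spherical destination formula);
    sequential because each step starts from the previous position.
    """
    import math
    R = 6_371_008.8
    n = len(bearings_deg)
    lon = np.empty(n + 1)
    lat = np.empty(n + 1)
    lon[0], lat[0] = lon0, lat0
    lam = math.radians(lon0)
    phi = math.radians(lat0)
    brg_rad = np.radians(np.asarray(bearings_deg, dtype=float))
    delta = np.asarray(distances_m, dtype=float) / R
    sin_d, cos_d = np.sin(delta), np.cos(delta)
    sin_b, cos_b = np.sin(brg_rad), np.cos(brg_rad)
    for i in range(n):
        sp, cp = math.sin(phi), math.cos(phi)
        s2 = sp * cos_d[i] + cp * sin_d[i] * cos_b[i]
        s2 = max(-1.0, min(1.0, s2))
        phi = math.asin(s2)
        lam += math.atan2(sin_b[i] * sin_d[i] * cp, cos_d[i] - sp * s2)
        lon[i + 1] = math.degrees(lam)
        lat[i + 1] = math.degrees(phi)
    lon = (lon + 180.0) % 360.0 - 180.0
    return lon, lat


def _state_chain(rng, n, p01, p10, initial):
    states = np.empty(n, dtype=int)
    u = rng.random(n)
    s = int(initial)
    for i in range(n):
        states[i] = s
        if s == STATE_SLOW:
            if u[i] < p01:
                s = STATE_FAST
        else:
            if u[i] < p10:
                s = STATE_SLOW
    return states


def simulate_two_state_track(cfg: SimConfig, start: Tuple[float, float],
                             seed: Optional[int] = None, id: str = "sim",
                             initial_state: int = STATE_FAST,
                             t0: pd.Timestamp = _EPOCH0) -> Track:
    """Simulate a two-state (drift/flight) correlated random walk.

    Discrete steps of ``fix_interval_s``: the behavioural state follows a
    two-state Markov chain; each step's speed is log-normal with the
    state's natural-scale moments; the heading performs a von Mises random
    walk with state-dependent concentration; the position advances along
    the great circle. True states are stored on the returned track
    (``track.states``), and every fix is tagged as a 3D fix.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_s / cfg.fix_interval_s)) + 1
    states = _state_chain(rng, n, cfg.p_slow_to_fast, cfg.p_fast_to_slow, initial_state)

    mu_s, s2_s = lognormal_params_from_moments(cfg.slow_mean, cfg.slow_var)
    mu_f, s2_f = lognormal_params_from_moments(cfg.fast_mean, cfg.fast_var)
    mu = np.where(states == STATE_SLOW, mu_s, mu_f)
    sd = np.sqrt(np.where(states == STATE_SLOW, s2_s, s2_f))
    speeds = np.exp(mu + sd * rng.standard_normal(n))

    kappa = np.where(states == STATE_SLOW, cfg.kappa_slow, cfg.kappa_fast)
    turns = np.degrees(rng.vonmises(0.0, kappa, size=n))
    heading0 = float(rng.uniform(0.0, 360.0))
    headings = (heading0 + np.cumsum(turns[:-1])) % 360.0

    lon, lat = _advance_great_circle(start[0], start[1], headings,
                                     speeds[:-1] * cfg.fix_interval_s)
    time = t0 + pd.to_timedelta(np.arange(n) * cfg.fix_interval_s, unit="s")
    regime = Regime.CONTINUOUS_5S if cfg.fix_interval_s == 5.0 else Regime.OTHER
    return Track(id, time, lon, lat, n_sats=np.full(n, 8.0),
                 quality=["FIX3D"] * n, regime=regime, states=states,
                 meta={"synthetic": True, "seed": seed})


def apply_duty_cycle(track: Track, mode: Regime,
                     burst_len_s: float = 60.0,
                     period_s: float = 7200.0) -> Track:
    """Subsample a high-resolution simulated track to a field duty cycle.

    ``CONTINUOUS_5S`` keeps fixes on a 5-s grid from the first fix;
    ``BURST_2H`` keeps ``burst_len_s`` of consecutive fixes at the start
    of every ``period_s`` window (burst length is a free choice of the
    logger configuration; 60 s default). Output fixes are a subset of the
    input fixes.
    """
    if len(track) == 0:
        return track
    rel = track.t_seconds - track.t_seconds[0]
    if mode is Regime.CONTINUOUS_5S:
        # keep fixes on the 5-s grid (tracks at coarser steps keep all)
        keep = np.isclose(rel % 5.0, 0.0) | np.isclose(rel % 5.0, 5.0)
    elif mode is Regime.BURST_2H:
        keep = (rel % period_s) < burst_len_s
    else:
        raise ValueError(f"unsupported duty-cycle mode {mode!r}")
    out = track.subset(keep)
    out.regime = mode
    return out


def apply_acquisition_bias(track: Track, p_fix,
                           seed: Optional[int] = None) -> Track:
    """Thin a simulated track by state-dependent fix-acquisition success.

    ``p_fix`` maps state (STATE_SLOW / STATE_FAST) to the independent
    probability that a fix in that state is actually acquired. Requires
    true-state labels on the track. Seeded and reproducible.
    """
    if track.states is None:
        raise ValueError("acquisition bias needs a track with true-state labels")
    rng = np.random.default_rng(seed)
    p = np.array([float(p_fix[int(s)]) for s in track.states])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("acquisition probabilities must lie in [0, 1]")
    keep = rng.random(len(track)) < p
    return track.subset(keep)


def simulate_shelf_foraging_track(bathy: BathyConfig, sim: SimConfig,
                                  seed: Optional[int] = None,
                                  n_bouts: int = 4,
                                  bout_duration_s: float = 3600.0,
                                  id: str = "forager") -> Track:
    """Simulate a central-place forager that drifts over the shelf-break.

    The bird alternates fast commuting legs with slow drift bouts, and the
    drift bouts are placed over the 600-1000 m shelf-break band of the
    bathymetry layout: it flies from a nearshore start to the band,
    drifts there for ``bout_duration_s`` (reflected at the band edges so
    it stays over shelf-break depths), relocates along the band, and
    finally commutes back. Speeds are drawn from the state distributions
    of ``sim``; states are recorded per fix. Used to exercise the
    classify -> sample -> rotation-null pipeline end-to-end with a known
    depth preference.
    """
    rng = np.random.default_rng(seed if seed is not None else sim.seed)
    dt = sim.fix_interval_s
    mu_s, s2_s = lognormal_params_from_moments(sim.slow_mean, sim.slow_var)
    mu_f, s2_f = lognormal_params_from_moments(sim.fast_mean, sim.fast_var)
    band_mid = 0.5 * (bathy.band_west + bathy.band_east)
    lat_mid = bathy.south + 0.5 * bathy.nrows * bathy.cell_deg
    lat_span = 0.35 * bathy.nrows * bathy.cell_deg

    lon = [bathy.coast_lon + 0.5 * bathy.shelf_width_deg]
    lat = [lat_mid]
    states = [STATE_FAST]

    def step(to_lon, to_lat, state):
        speed = float(np.exp((mu_f if state == STATE_FAST else mu_s)
                             + np.sqrt(s2_f if state == STATE_FAST else s2_s)
                             * rng.standard_normal()))
        brg = float(initial_bearing_deg(lon[-1], lat[-1], to_lon, to_lat))
        brg += rng.normal(scale=5.0 if state == STATE_FAST else 60.0)
        nlon, nlat = destination_point(lon[-1], lat[-1], brg, speed * dt)
        lon.append(float(nlon))
        lat.append(float(nlat))
        states.append(state)

    targets = [(band_mid, lat_mid + rng.uniform(-lat_span, lat_span))
               for _ in range(n_bouts)]
    for t_lon, t_lat in targets:
        # commute (fast) until within ~500 m of the bout target
        guard = 0
        while np.hypot(lon[-1] - t_lon, lat[-1] - t_lat) > 0.005 and guard < 50_000:
            step(t_lon, t_lat, STATE_FAST)
            guard += 1
        # drift bout (slow) held over the band by reflecting the target
        for _ in range(int(bout_duration_s / dt)):
            drift_target = (band_mid + rng.uniform(-0.3, 0.3) * (bathy.band_east - bathy.band_west),
                            lat[-1] + rng.uniform(-0.01, 0.01))
            step(*drift_target, STATE_SLOW)
    # commute home
    home = (bathy.coast_lon + 0.5 * bathy.shelf_width_deg, lat_mid)
    guard = 0
    while np.hypot(lon[-1] - home[0], lat[-1] - home[1]) > 0.005 and guard < 50_000:
        step(*home, STATE_FAST)
        guard += 1

    n = len(lon)
    time = _EPOCH0 + pd.to_timedelta(np.arange(n) * dt, unit="s")
    regime = Regime.CONTINUOUS_5S if dt == 5.0 else Regime.OTHER
    return Track(id, time, lon, lat, n_sats=np.full(n, 8.0),
                 quality=["FIX3D"] * n, regime=regime,
                 states=np.asarray(states), meta={"synthetic": True, "seed": seed})
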