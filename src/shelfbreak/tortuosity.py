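"""Path-unpredictability (entropy) profiling of high-resolution tracks.

Straight commuting flight is highly predictable: successive segments keep
nearly the same heading and speed, so the local distribution of
(turn angle, speed) collapses into a single histogram bin and its Shannon
entropy is near zero. Tortuous, area-restricted search spreads that
distribution over many bins and drives the entropy up. Scoring each fix by
the entropy of the (turn angle, speed) pairs in a sliding time window
therefore profiles where along a track the movement was unpredictable —
candidate foraging bouts — versus predictable commuting.

This is a self-contained, fully specified operator: a windowed Shannon
entropy (in bits) over a fixed 8 x 4 turn-angle x speed histogram, with
speed bins set by the track's own speed quartiles so the score is
scale-free across individuals. It reimplements the *role* of
spatio-temporal predictability scores from the machine-learning tracking
literature, not any specific published estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._geodesy import haversine_m, initial_bearing_deg, wrap_angle_deg
from .track_io import Track

MIN_PAIRS = 5  # fewer (turn, speed) pairs than this -> entropy undefined


def turn_angles(track: Track) -> np.ndarray:
    """Signed heading change at each interior fix, degrees in (-180, 180].

    Headings are initial great-circle bearings of consecutive segments,
    clockwise from north; the turn at fix i is the wrapped difference
    between the outgoing and incoming segment bearings, so right turns are
    positive and left turns negative. Requires at least 3 fixes.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 fixes to compute turn angles")
    brg = initial_bearing_deg(track.lon[:-1], track.lat[:-1],
                              track.lon[1:], track.lat[1:])
    return wrap_angle_deg(np.diff(brg))


@dataclass
class EntropyProfile:
    """Per-fix entropy profile of a track.

    ``entropy`` is NaN where fewer than ``MIN_PAIRS`` pairs fell in the
    window (``defined`` False there). ``category`` is 0 until
    :func:`categorize_entropy` assigns quantile categories 1..n.
    """

    time: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    entropy: np.ndarray
    n_pairs: np.ndarray
    defined: np.ndarray
    window_s: float
    n_bins: int
    category: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.category is None:
            self.category = np.zeros(len(self.entropy), dtype=int)

    @property
    def max_entropy_bits(self) -> float:
        return float(np.log2(self.n_bins))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "lon": self.lon, "lat": self.lat,
                             "entropy_bits": self.entropy, "n_pairs": self.n_pairs,
                             "defined": self.defined, "category": self.category})


def shannon_entropy_bits(counts) -> float:
    """Shannon entropy (bits) of a count histogram, 0 log 0 = 0."""
    c = np.asarray(counts, dtype=float).ravel()
    total = c.sum()
    if total <= 0:
        return float("nan")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def sliding_entropy(track: Track, window_s: float = 600.0,
                    angle_bins: int = 8, speed_bins: int = 4) -> EntropyProfile:
    """Windowed Shannon entropy of the (turn angle, speed) distribution.

    For every fix, the (turn angle, segment speed) pairs whose times fall
    within +/- window_s/2 of the fix are binned on a fixed
    ``angle_bins x speed_bins`` grid — angle bins uniform over (-180, 180],
    speed bins delimited by the track-wide speed quartiles (scale-free per
    individual) — and the entropy of the normalised histogram is the fix's
    score. Fixes with fewer than 5 pairs in the window are flagged
    undefined. Intended for high-resolution tracks (median fix interval
    <= 30 s); sparser tracks raise.
    """
    n = len(track)
    if n < 3:
        raise ValueError("need at least 3 fixes for an entropy profile")
    t = track.t_seconds
    dts = np.diff(t)
    if np.median(dts) > 30.0:
        raise ValueError("entropy profiling expects a high-resolution track "
                         "(median fix interval <= 30 s)")
    turns = turn_angles(track)                      # at interior fixes 1..n-2
    seg_d = haversine_m(track.lon[:-1], track.lat[:-1], track.lon[1:], track.lat[1:])
    speeds = seg_d / dts
    pair_speed = speeds[1:]                         # outgoing segment of fix i
    pair_t = t[1:-1]                                # pair timestamped at its fix

    angle_edges = np.linspace(-180.0, 180.0, angle_bins + 1)
    # nano-m/s rounding keeps float noise from scattering tied speeds
    # (e.g. a perfectly steady leg) across a quartile edge
    speeds = np.round(speeds, 9)
    pair_speed = np.round(pair_speed, 9)
    qs = np.quantile(speeds, np.linspace(0, 1, speed_bins + 1)[1:-1])
    a_idx = np.clip(np.digitize(turns, angle_edges, right=True) - 1, 0, angle_bins - 1)
    s_idx = np.searchsorted(qs, pair_speed, side="left")
    flat = a_idx * speed_bins + s_idx
    n_bins = angle_bins * speed_bins

    half = window_s / 2.0
    lo = np.searchsorted(pair_t, t - half, side="left")
    hi = np.searchsorted(pair_t, t + half, side="right")
    entropy = np.full(n, np.nan)
    n_pairs = hi - lo
    for i in range(n):
        if n_pairs[i] >= MIN_PAIRS:
            counts = np.bincount(flat[lo[i]:hi[i]], minlength=n_bins)
            entropy[i] = shannon_entropy_bits(counts)
    defined = np.isfinite(entropy)
    return EntropyProfile(time=track.time, lon=track.lon.copy(), lat=track.lat.copy(),
                          entropy=entropy, n_pairs=n_pairs.astype(int),
                          defined=defined, window_s=float(window_s), n_bins=n_bins)


def categorize_entropy(profile: EntropyProfile, n_categories: int = 5) -> EntropyProfile:
    """Assign each defined entropy value a quantile category 1..n within
    its own track's entropy distribution (monotone: higher entropy never
    gets a lower category). All-equal entropies collapse to category 1.
    Undefined fixes keep category 0.
    """
    vals = profile.entropy[profile.defined]
    if len(vals) < n_categories:
        raise ValueError(f"need at least {n_categories} defined entropy values")
    cat = np.zeros(len(profile.entropy), dtype=int)
    if np.ptp(vals) == 0.0:
        cat[profile.defined] = 1
    else:
        edges = np.quantile(vals, np.linspace(0, 1, n_categories + 1)[1:-1])
        cat[profile.defined] = np.searchsorted(edges, vals, side="left") + 1
    profile.category = cat
    return profile
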