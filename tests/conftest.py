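import numpy as np
import pandas as pd
import pytest

from shelfbreak.movement_model import MixtureModel, lognormal_params_from_moments
from shelfbreak.track_io import Track

T0 = pd.Timestamp("2006-02-23T00:00:00Z")


def make_track(lons, lats, dt_s=5.0, times=None, **kw):
    """Build a Track from coordinates with evenly spaced (or explicit) times."""
    n = len(lons)
    if times is None:
        times = T0 + pd.to_timedelta(np.arange(n) * dt_s, unit="s")
    return Track(kw.pop("id", "test"), times, lons, lats, **kw)


@pytest.fixture
def petrel_model():
    """Two-component speed model built directly from the reported mode
    moments (slow 0.83 m/s var 0.13, fast 10.20 m/s var 27.0), equal
    weights — the reference model for classification tests."""
    mu_s, s2_s = lognormal_params_from_moments(0.83, 0.13)
    mu_f, s2_f = lognormal_params_from_moments(10.20, 27.0)
    return MixtureModel(K=2, weights=[0.5, 0.5], mu=[mu_s, mu_f],
                        sigma2=[s2_s, s2_f], loglik_trace=[0.0], n_obs=0)


def draw_mode_speeds(rng, n, weights=(0.5, 0.5),
                     modes=((0.83, 0.13), (10.20, 27.0))):
    """Draw n speeds from the two-mode log-normal generator."""
    comp = rng.random(n) < weights[0]
    out = np.empty(n)
    for k, (mean, var) in enumerate(modes):
        mu, s2 = lognormal_params_from_moments(mean, var)
        sel = comp if k == 0 else ~comp
        out[sel] = np.exp(mu + np.sqrt(s2) * rng.standard_normal(int(sel.sum())))
    return out
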