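"""Behavioural speed model: Gaussian mixture on log speeds, fitted by EM.

Over-ground speeds of a foraging procellariiform separate into a slow mode
(sitting on the water and drifting, ~1 m/s) and a fast mode (flight,
~10 m/s). A K-component Gaussian mixture on *log* speed captures this:
working in log space keeps all probability mass on positive speeds and
makes both modes near-symmetric. On the natural (m/s) scale each component
is therefore log-normal, and mode summaries are reported via the exact
log-normal moment map.

Speeds of exactly 0 m/s are artefacts of the receiver's velocity solution
and are dropped (with a count) before the log transform.

Classification assigns each speed to the component under which it is most
likely (maximum posterior). Posterior ties break to the slower component:
misclassifying rest as flight would inflate apparent foraging range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .kinematics import ClusterSummary

SLOW, FAST = 0, 1  # component indices after sorting by mean

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureModel:
    """Fitted K-component Gaussian mixture on log speed.

    ``weights``, ``mu`` and ``sigma2`` are index-aligned and sorted by
    ``mu`` ascending, so component 0 is always the slow mode.
    """

    K: int
    weights: np.ndarray
    mu: np.ndarray          # log-scale means
    sigma2: np.ndarray      # log-scale variances
    loglik_trace: np.ndarray
    n_obs: int
    n_zeros_dropped: int = 0
    seed: Optional[int] = None
    converged: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)
        if not (len(self.weights) == len(self.mu) == len(self.sigma2) == self.K):
            raise ValueError("weights, mu, sigma2 must all have length K")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sigma2 <= 0):
            raise ValueError("component variances must be positive")

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def to_dict(self) -> dict:
        return {"K": self.K, "weights": self.weights.tolist(),
                "mu": self.mu.tolist(), "sigma2": self.sigma2.tolist(),
                "n_obs": self.n_obs, "n_zeros_dropped": self.n_zeros_dropped,
                "loglik": self.loglik, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(K=int(d["K"]), weights=d["weights"], mu=d["mu"],
                   sigma2=d["sigma2"], loglik_trace=[d.get("loglik", np.nan)],
                   n_obs=int(d.get("n_obs", 0)),
                   n_zeros_dropped=int(d.get("n_zeros_dropped", 0)),
                   seed=d.get("seed"))


@dataclass
class Classification:
    """Maximum-posterior assignment of one speed observation."""

    label: int                 # component index; 0 = SLOW, K-1 fastest
    posterior: np.ndarray      # per-component posterior probabilities

    @property
    def name(self) -> str:
        if len(self.posterior) == 2:
            return "SLOW" if self.label == SLOW else "FAST"
        return f"COMPONENT_{self.label}"


@dataclass
class ModeSummary:
    """Natural-scale (m/s) mean and variance per component."""

    means: np.ndarray
    variances: np.ndarray


def lognormal_params_from_moments(mean: float, variance: float):
    """Invert the log-normal moment map: natural-scale (mean, variance) ->
    log-scale (mu, sigma2)."""
    if mean <= 0 or variance < 0:
        raise ValueError("natural-scale mean must be > 0 and variance >= 0")
    sigma2 = float(np.log1p(variance / mean ** 2))
    mu = float(np.log(mean) - sigma2 / 2.0)
    return mu, sigma2


def _prepare_speeds(speeds, K: int):
    x = np.asarray(speeds, dtype=float).ravel()
    n_zeros = int(np.sum(x == 0.0))
    x = x[x > 0.0]
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValueError("speeds must be finite and non-negative")
    if len(x) < 2 * K:
        raise ValueError(f"need at least {2 * K} positive speeds to fit K={K}")
    return np.log(x), n_zeros


def _log_component_densities(logx: np.ndarray, mu, sigma2):
    # (n, K) log N(logx; mu_k, sigma2_k)
    d = logx[:, None] - np.asarray(mu)[None, :]
    s2 = np.asarray(sigma2)[None, :]
    return -0.5 * (d * d / s2 + np.log(s2) + _LOG_2PI)


def fit_mixture_em(speeds: Sequence[float], K: int = 2, seed: Optional[int] = None,
                   tol: float = 1e-8, max_iter: int = 500,
                   n_restarts: int = 1) -> MixtureModel:
    """Fit a K-component Gaussian mixture to log-transformed speeds by EM.

    Initialisation is a deterministic K-quantile split of the sorted log
    speeds (each chunk supplies one component's mean, variance and weight);
    ``seed`` only matters when ``n_restarts > 1``, in which case restarts
    2..n jitter the initial means and the best log-likelihood wins.
    Iteration stops when the relative change in log-likelihood falls below
    ``tol`` or after ``max_iter`` iterations. The per-iteration
    log-likelihood trace is recorded and is non-decreasing (EM guarantee).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    logx, n_zeros = _prepare_speeds(speeds, K)
    if np.ptp(logx) == 0.0:
        raise ValueError("all speeds are equal: mixture variance is degenerate")

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, int(n_restarts))):
        mu0, s20, w0 = _quantile_init(logx, K)
        if restart > 0:
            mu0 = mu0 + rng.normal(scale=np.sqrt(np.mean(s20)), size=K)
        fit = _em(logx, w0, mu0, s20, tol=tol, max_iter=max_iter)
        if best is None or fit[3][-1] > best[3][-1]:
            best = fit
    w, mu, s2, trace, converged = best
    order = np.argsort(mu)
    return MixtureModel(K=K, weights=w[order], mu=mu[order], sigma2=s2[order],
                        loglik_trace=np.asarray(trace), n_obs=len(logx),
                        n_zeros_dropped=n_zeros, seed=seed, converged=converged)


def _quantile_init(logx: np.ndarray, K: int):
    xs = np.sort(logx)
    chunks = np.array_split(xs, K)
    mu = np.array([c.mean() for c in chunks])
    overall = logx.var()
    s2 = np.array([max(c.var(), 1e-3 * overall, 1e-12) for c in chunks])
    w = np.array([len(c) for c in chunks], dtype=float)
    return mu, s2, w / w.sum()


def _em(logx, w, mu, s2, tol, max_iter):
    n = len(logx)
    trace = []
    converged = False
    var_floor = max(1e-10 * logx.var(), 1e-12)
    for _ in range(max_iter):
        # E step
        log_joint = np.log(w)[None, :] + _log_component_densities(logx, mu, s2)
        log_norm = logsumexp(log_joint, axis=1)
        loglik = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])
        trace.append(loglik)
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp * logx[:, None]).sum(axis=0) / nk
        d = logx[:, None] - mu[None, :]
        s2 = np.maximum((resp * d * d).sum(axis=0) / nk, var_floor)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
    # final log-likelihood under the last M-step parameters
    log_joint = np.log(w)[None, :] + _log_component_densities(logx, mu, s2)
    trace.append(float(logsumexp(log_joint, axis=1).sum()))
    return w, mu, s2, trace, converged


def log_posteriors(model: MixtureModel, speeds) -> np.ndarray:
    """(n, K) array of log posterior probabilities for positive speeds."""
    x = np.asarray(speeds, dtype=float).ravel()
    if np.any(x <= 0):
        raise ValueError("speeds must be positive (log transform undefined at 0)")
    log_joint = np.log(model.weights)[None, :] + _log_component_densities(
        np.log(x), model.mu, model.sigma2)
    return log_joint - logsumexp(log_joint, axis=1)[:, None]


def classify(model: MixtureModel, speed: float) -> Classification:
    """Assign a speed to the mixture component most likely to have
    generated it. Exact posterior ties go to the slower component."""
    post = np.exp(log_posteriors(model, [float(speed)]))[0]
    best = post.max()
    label = int(np.flatnonzero(post == best)[0])  # ties -> lowest index = slowest
    return Classification(label=label, posterior=post)


def classify_speeds(model: MixtureModel, speeds) -> np.ndarray:
    """Vectorised maximum-posterior labels for an array of positive speeds
    (ties to the slower component)."""
    lp = log_posteriors(model, speeds)
    # argmax takes the lowest index on exact ties, i.e. the slower component
    return np.argmax(lp, axis=1)


def classify_cluster(model: MixtureModel, cluster: ClusterSummary) -> Optional[Classification]:
    """Classify a burst cluster by its representative (median) speed.

    Clusters flagged with an undefined speed return ``None`` and are
    excluded from behavioural proportions.
    """
    if not cluster.defined or not np.isfinite(cluster.speed):
        return None
    return classify(model, cluster.speed)


def classify_clusters(model: MixtureModel, clusters: Sequence[ClusterSummary]):
    """Classify every defined cluster; returns (labels, n_excluded) where
    labels align with the defined clusters in order."""
    labels = []
    n_excluded = 0
    for c in clusters:
        r = classify_cluster(model, c)
        if r is None:
            n_excluded += 1
        else:
            labels.append(r.label)
    return np.asarray(labels, dtype=int), n_excluded


def class_proportions(labels: np.ndarray, K: int = 2) -> np.ndarray:
    """Fraction of locations in each behavioural class."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        return np.full(K, np.nan)
    return np.bincount(labels, minlength=K) / len(labels)


def natural_scale_summary(model: MixtureModel) -> ModeSummary:
    """Per-component natural-scale moments via the exact log-normal map:
    mean = exp(mu + sigma2/2), variance = (exp(sigma2) - 1) exp(2 mu + sigma2)."""
    mean = np.exp(model.mu + model.sigma2 / 2.0)
    var = np.expm1(model.sigma2) * np.exp(2.0 * model.mu + model.sigma2)
    return ModeSummary(means=mean, variances=var)


def mixture_pdf(model: MixtureModel, speeds) -> np.ndarray:
    """Mixture density on the natural speed scale (a log-normal mixture);
    integrates to 1 over (0, inf)."""
    v = np.asarray(speeds, dtype=float)
    out = np.zeros_like(v, dtype=float)
    pos = v > 0
    logv = np.log(v[pos])
    dens = np.exp(_log_component_densities(logv, model.mu, model.sigma2))
    out[pos] = (dens * model.weights[None, :]).sum(axis=1) / v[pos]
    return out
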