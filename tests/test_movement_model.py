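"""EM mixture fitting on log speeds, classification, natural-scale moments."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from shelfbreak import synthetic_data as syn
from shelfbreak.kinematics import ClusterSummary, compute_speeds, segment_clusters
from shelfbreak.movement_model import (MixtureModel, classify, classify_cluster,
                                       classify_clusters, class_proportions,
                                       classify_speeds, fit_mixture_em,
                                       lognormal_params_from_moments,
                                       log_posteriors, mixture_pdf,
                                       natural_scale_summary)
from shelfbreak.track_io import Regime

from conftest import draw_mode_speeds


class TestFitMixtureEM:
    def test_single_component_matches_closed_form(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(1.0, 0.4, 500))
        m = fit_mixture_em(x, K=1)
        logs = np.log(x)
        assert m.mu[0] == pytest.approx(logs.mean(), abs=1e-8)
        assert m.sigma2[0] == pytest.approx(logs.var(), rel=1e-6)
        assert m.weights[0] == 1.0

    def test_recovers_two_mode_means(self):
        rng = np.random.default_rng(42)
        speeds = draw_mode_speeds(rng, 5000)
        m = fit_mixture_em(speeds, K=2, seed=0)
        modes = natural_scale_summary(m)
        assert modes.means[0] == pytest.approx(0.83, rel=0.05)
        assert modes.means[1] == pytest.approx(10.20, rel=0.05)

    def test_loglik_trace_non_decreasing(self):
        rng = np.random.default_rng(5)
        for n in (50, 500):
            m = fit_mixture_em(draw_mode_speeds(rng, n), K=2, seed=0)
            assert np.all(np.diff(m.loglik_trace) >= -1e-9)

    def test_zero_speeds_dropped_and_counted(self):
        rng = np.random.default_rng(1)
        speeds = np.concatenate([draw_mode_speeds(rng, 200), np.zeros(7)])
        m = fit_mixture_em(speeds, K=2, seed=0)
        assert m.n_zeros_dropped == 7
        assert m.n_obs == 200

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError, match="equal"):
            fit_mixture_em(np.full(100, 3.0), K=2)
        with pytest.raises(ValueError, match="K"):
            fit_mixture_em([1.0, 2.0, 3.0, 4.0], K=0)
        with pytest.raises(ValueError, match="at least"):
            fit_mixture_em([1.0, 2.0, 3.0], K=2)

    def test_agrees_with_sklearn_reference(self):
        # independent EM implementation as oracle on the same sample
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(9)
        speeds = draw_mode_speeds(rng, 4000)
        ours = fit_mixture_em(speeds, K=2, seed=0)
        ref = GaussianMixture(n_components=2, covariance_type="full",
                              tol=1e-8, max_iter=500, n_init=3,
                              random_state=0).fit(np.log(speeds)[:, None])
        ref_mu = np.sort(ref.means_.ravel())
        ref_s2 = ref.covariances_.ravel()[np.argsort(ref.means_.ravel())]
        assert np.allclose(ours.mu, ref_mu, atol=5e-3)
        assert np.allclose(ours.sigma2, ref_s2, rtol=5e-2)


class TestClassification:
    def test_mode_speeds_classify_to_their_modes(self, petrel_model):
        assert classify(petrel_model, 0.83).name == "SLOW"
        assert classify(petrel_model, 10.20).name == "FAST"

    def test_posteriors_sum_to_one(self, petrel_model):
        c = classify(petrel_model, 3.0)
        assert c.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert c.label == int(np.argmax(c.posterior))

    def test_decision_boundary_tie_breaks_slow(self, petrel_model):
        lp = lambda v: np.diff(log_posteriors(petrel_model, [v])[0])[0]
        boundary = brentq(lp, 0.9, 9.0, xtol=1e-14)
        just_below, just_above = boundary * (1 - 1e-9), boundary * (1 + 1e-9)
        assert classify(petrel_model, just_below).name == "SLOW"
        assert classify(petrel_model, just_above).name == "FAST"
        # exactly equal posteriors (to float resolution) -> slow component
        c = classify(petrel_model, boundary)
        if c.posterior[0] == c.posterior[1]:
            assert c.name == "SLOW"

    def test_nonpositive_speed_rejected(self, petrel_model):
        with pytest.raises(ValueError):
            classify(petrel_model, 0.0)
        with pytest.raises(ValueError):
            classify(petrel_model, -1.0)

    def test_label_permutation_invariance(self, petrel_model):
        perm = MixtureModel(K=2, weights=petrel_model.weights[::-1],
                            mu=petrel_model.mu[::-1],
                            sigma2=petrel_model.sigma2[::-1],
                            loglik_trace=[0.0], n_obs=0)
        speeds = np.array([0.3, 0.83, 2.0, 5.0, 10.2, 20.0])
        ours = classify_speeds(petrel_model, speeds)
        # permuted component order: label k in one model is label K-1-k in the other
        theirs = 1 - classify_speeds(perm, speeds)
        assert np.array_equal(ours, theirs)

    def test_cluster_classification_and_proportions(self, petrel_model):
        import pandas as pd
        t = pd.Timestamp("2006-01-01", tz="UTC")
        mk = lambda speed, defined: ClusterSummary(0, t, t, 0.0, 0.0, speed,
                                                   2 if defined else 1, defined)
        assert classify_cluster(petrel_model, mk(0.9, True)).name == "SLOW"
        assert classify_cluster(petrel_model, mk(np.nan, False)) is None
        clusters = [mk(0.9, True), mk(11.0, True), mk(0.5, True), mk(np.nan, False)]
        labels, n_excluded = classify_clusters(petrel_model, clusters)
        assert n_excluded == 1
        props = class_proportions(labels)
        assert props[0] == pytest.approx(2 / 3)
        assert props.sum() == pytest.approx(1.0)


class TestNaturalScale:
    def test_standard_lognormal_limits(self):
        m = MixtureModel(K=1, weights=[1.0], mu=[0.0], sigma2=[1e-12],
                         loglik_trace=[0.0], n_obs=0)
        s = natural_scale_summary(m)
        assert s.means[0] == pytest.approx(1.0, abs=1e-9)
        assert s.variances[0] == pytest.approx(0.0, abs=1e-9)

    def test_moment_map_round_trip(self):
        for mean, var in [(0.83, 0.13), (10.20, 27.0), (1.0, 0.01)]:
            mu, s2 = lognormal_params_from_moments(mean, var)
            m = MixtureModel(K=1, weights=[1.0], mu=[mu], sigma2=[s2],
                             loglik_trace=[0.0], n_obs=0)
            s = natural_scale_summary(m)
            assert s.means[0] == pytest.approx(mean, abs=1e-10)
            assert s.variances[0] == pytest.approx(var, abs=1e-10)

    def test_mixture_density_integrates_to_one(self, petrel_model):
        total, err = quad(lambda v: mixture_pdf(petrel_model, v), 0, np.inf,
                          limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestAcquisitionBiasMediation:
    def test_high_res_model_beats_biased_refit(self):
        """Classifying sparse, acquisition-biased data with the model fitted
        on the complete high-resolution track estimates the mode means
        better (on average) than refitting the mixture on the biased sparse
        sample itself."""
        truth = np.array([0.83, 10.20])
        err_highres, err_refit = [], []
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            cfg = syn.SimConfig(duration_s=12 * 3600.0, seed=None)
            track = syn.simulate_two_state_track(cfg, (2.7, -0.3), seed=2000 + rep)
            sparse = syn.apply_duty_cycle(track, Regime.BURST_2H, burst_len_s=60.0)
            biased = syn.apply_acquisition_bias(sparse, {0: 0.95, 1: 0.4},
                                                seed=3000 + rep)
            hi_speeds = compute_speeds(track, max_dt=30.0)["speed"].to_numpy()
            hi_model = fit_mixture_em(hi_speeds, K=2, seed=0)
            err_highres.append(np.abs(natural_scale_summary(hi_model).means - truth))
            try:
                lo_speeds = compute_speeds(biased, max_dt=30.0)["speed"].to_numpy()
                lo_model = fit_mixture_em(lo_speeds, K=2, seed=0)
                err_refit.append(np.abs(natural_scale_summary(lo_model).means - truth))
            except ValueError:
                # biased sample too small/degenerate to refit at all
                err_refit.append(np.array([np.inf, np.inf]))
        mean_hi = np.mean([e.mean() for e in err_highres])
        finite = [e.mean() for e in err_refit if np.all(np.isfinite(e))]
        mean_lo = np.mean(finite) if finite else np.inf
        assert len(err_highres) == n_rep
        assert mean_hi < mean_lo
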