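"""Gaussian HMM core: forward likelihood, Viterbi, stationary law, EM fitting."""

from __future__ import annotations

import numpy as np
import pytest

import gazehmm as g
from gazehmm.hmm import _forward_backward, _log_emissions

from conftest import brute_force_loglik, brute_force_viterbi, random_hmm


class TestLogLikelihood:
    def test_single_fixation_at_unit_gaussian_mode(self):
        hmm = g.SubjectHMM(prior=[1.0], transition=[[1.0]],
                           rois=[g.GaussianROI([0, 0], np.eye(2))])
        ll = g.log_likelihood(np.array([[0.0, 0.0]]), hmm)
        assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_degenerate_chain_reduces_to_emission_sum(self):
        """prior (1,0) with identity transitions pins the path to state 1."""
        rois = [g.GaussianROI([0, 0], np.eye(2)),
                g.GaussianROI([50, 50], np.eye(2))]
        hmm = g.SubjectHMM(prior=[1.0, 0.0], transition=np.eye(2), rois=rois)
        xy = np.array([[0.0, 1.0], [2.0, -1.0], [0.5, 0.5]])
        expected = float(np.sum(rois[0].logpdf(xy)))
        assert g.log_likelihood(xy, hmm) == pytest.approx(expected, abs=1e-10)

    def test_matches_path_enumeration_on_toy_model(self, toy_hmm):
        rng = np.random.default_rng(0)
        xy = rng.normal(0, 4, size=(3, 2))
        assert g.log_likelihood(xy, toy_hmm) == pytest.approx(
            brute_force_loglik(xy, toy_hmm), abs=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("t", [1, 2, 4, 6])
    def test_matches_path_enumeration_random_instances(self, k, t):
        rng = np.random.default_rng(1000 * k + t)
        for _ in range(3):
            hmm = random_hmm(rng, k)
            xy = rng.normal(0, 6, size=(t, 2))
            assert g.log_likelihood(xy, hmm) == pytest.approx(
                brute_force_loglik(xy, hmm), abs=1e-9)

    def test_invariant_under_state_relabelling(self):
        rng = np.random.default_rng(5)
        hmm = random_hmm(rng, 3)
        xy = rng.normal(0, 5, size=(8, 2))
        for perm in ([1, 2, 0], [2, 1, 0]):
            assert g.log_likelihood(xy, hmm.permuted(perm)) == pytest.approx(
                g.log_likelihood(xy, hmm), abs=1e-9)

    def test_matches_hmmlearn_reference(self, toy_hmm):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                   init_params="")
        ref.startprob_ = toy_hmm.prior
        ref.transmat_ = toy_hmm.transition
        ref.means_ = toy_hmm.means()
        ref.covars_ = np.array([r.cov for r in toy_hmm.rois])
        rng = np.random.default_rng(2)
        xy = rng.normal(2, 5, size=(20, 2))
        assert g.log_likelihood(xy, toy_hmm) == pytest.approx(ref.score(xy), abs=1e-8)

    def test_empty_sequence_rejected(self, toy_hmm):
        with pytest.raises(g.InputError):
            g.log_likelihood(np.empty((0, 2)), toy_hmm)


class TestViterbi:
    def test_single_state_all_labels_zero(self):
        hmm = g.SubjectHMM(prior=[1.0], transition=[[1.0]],
                           rois=[g.GaussianROI([0, 0], np.eye(2))])
        assert np.array_equal(g.viterbi_states(np.zeros((5, 2)), hmm), np.zeros(5, int))

    def test_fixation_at_far_roi_mean_gets_that_label(self):
        rois = [g.GaussianROI([0, 0], np.eye(2)), g.GaussianROI([100, 0], np.eye(2))]
        hmm = g.SubjectHMM(prior=[0.5, 0.5],
                           transition=[[0.5, 0.5], [0.5, 0.5]], rois=rois)
        labels = g.viterbi_states(np.array([[100.0, 0.0]]), hmm)
        assert labels.tolist() == [1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_enumeration(self, toy_hmm, seed):
        rng = np.random.default_rng(seed)
        xy = rng.normal(3, 5, size=(4, 2))
        assert tuple(g.viterbi_states(xy, toy_hmm)) == brute_force_viterbi(xy, toy_hmm)


class TestStationaryDistribution:
    def test_symmetric_two_state_chain(self):
        pi = g.stationary_distribution(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert pi == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_period_two_chain_limiting_average(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        pi = g.stationary_distribution(a, prior=np.array([1.0, 0.0]))
        assert pi == pytest.approx([0.5, 0.5], abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_matches_left_eigenvector_oracle(self, k):
        rng = np.random.default_rng(k)
        a = rng.dirichlet(np.ones(k) * 2, size=k)  # irreducible w.h.p.
        evals, evecs = np.linalg.eig(a.T)
        lead = np.argmin(np.abs(evals - 1.0))
        pi_ref = np.real(evecs[:, lead])
        pi_ref = pi_ref / pi_ref.sum()
        pi = g.stationary_distribution(a)
        assert pi == pytest.approx(pi_ref, abs=1e-6)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestFitting:
    def test_single_tight_gaussian_selects_one_state(self):
        rng = np.random.default_rng(0)
        xy = rng.multivariate_normal([300.0, 400.0], np.diag([100.0, 100.0]), size=500)
        hmm = g.fit_subject_hmm(xy, k_range=(1, 2, 3), n_restarts=5, seed=0)
        assert hmm.n_states == 1
        assert np.linalg.norm(hmm.rois[0].mean - [300, 400]) < 2.0

    def test_two_state_parameter_recovery(self):
        a_true = np.array([[0.9, 0.1], [0.1, 0.9]])
        means_true = np.array([[400.0, 500.0], [1400.0, 500.0]])
        rng = np.random.default_rng(7)
        s, xs = 0, []
        for _ in range(500):
            xs.append(rng.multivariate_normal(means_true[s], np.diag([400.0, 400.0])))
            s = int(rng.choice(2, p=a_true[s]))
        hmm = g.fit_subject_hmm(np.array(xs), k_range=(1, 2, 3), n_restarts=5, seed=1)
        assert hmm.n_states == 2
        order = np.argsort([r.mean[0] for r in hmm.rois])
        hmm = hmm.permuted(order.tolist())
        assert np.abs(hmm.prior - [1.0, 0.0]).max() <= 0.05
        assert np.abs(hmm.transition - a_true).max() <= 0.05
        for i in range(2):
            assert np.linalg.norm(hmm.rois[i].mean - means_true[i]) <= 5.0

    def test_fit_is_normalized_and_deterministic(self, small_cohort):
        seq = small_cohort.sequences[0]
        m1 = g.fit_subject_hmm(seq, k_range=(1, 2, 3), n_restarts=3, seed=5)
        m2 = g.fit_subject_hmm(seq, k_range=(1, 2, 3), n_restarts=3, seed=5)
        assert m1.prior.sum() == pytest.approx(1.0, abs=1e-9)
        assert m1.transition.sum(axis=1) == pytest.approx(np.ones(m1.n_states), abs=1e-9)
        assert np.array_equal(m1.prior, m2.prior)
        assert np.array_equal(m1.transition, m2.transition)

    def test_short_sequence_caps_n_states(self, caplog):
        xy = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0], [1.0, 2.0]])
        hmm = g.fit_subject_hmm(xy, k_range=(2, 3, 4), n_restarts=2, seed=0)
        assert hmm.n_states <= 1  # 4 fixations support at most K=1 (T >= 3K)

    def test_em_objective_is_monotone(self, small_cohort):
        """Per-iteration EM log-likelihood never decreases beyond 1e-8."""
        xy = small_cohort.sequences[1].xy
        k = 2
        means = xy[:k].copy()
        covs = np.repeat(np.cov(xy.T)[None, :, :], k, axis=0)
        prior = np.full(k, 1.0 / k)
        transition = np.full((k, k), 0.5)
        from gazehmm.hmm import _floor_cov
        covs = np.array([_floor_cov(c, 25.0) for c in covs])
        lls = []
        for _ in range(40):
            rois = [g.GaussianROI(means[j], covs[j]) for j in range(k)]
            log_b = _log_emissions(xy, rois)
            ll, gamma, xi = _forward_backward(prior, transition, log_b)
            lls.append(ll)
            prior = gamma[0] / gamma[0].sum()
            transition = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-12)
            w = np.maximum(gamma.sum(axis=0), 1e-12)
            new_means = (gamma.T @ xy) / w[:, None]
            for j in range(k):
                d = xy - new_means[j]
                covs[j] = _floor_cov((gamma[:, j, None] * d).T @ d / w[j], 25.0)
            means = new_means
        diffs = np.diff(lls)
        assert diffs.min() > -1e-8

    def test_recovery_error_shrinks_with_sequence_length(self):
        """Transition estimation error at T=1000 <= error at T=100 (20 replicates)."""
        a_true = np.array([[0.8, 0.2], [0.3, 0.7]])
        means_true = np.array([[0.0, 0.0], [800.0, 0.0]])

        def mean_err(t, base_seed):
            errs = []
            for rep in range(20):
                rng = np.random.default_rng(base_seed + rep)
                s, xs = 0, []
                for _ in range(t):
                    xs.append(rng.multivariate_normal(means_true[s], 900 * np.eye(2)))
                    s = int(rng.choice(2, p=a_true[s]))
                hmm = g.fit_subject_hmm(np.array(xs), k_range=(2,), n_restarts=3, seed=rep)
                order = np.argsort([r.mean[0] for r in hmm.rois])
                hmm = hmm.permuted(order.tolist())
                errs.append(np.abs(hmm.transition - a_true).mean())
            return float(np.mean(errs))

        assert mean_err(1000, 50) <= mean_err(100, 50)
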