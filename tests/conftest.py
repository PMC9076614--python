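from __future__ import annotations

import numpy as np
import pytest

import gazehmm as g


@pytest.fixture(scope="session")
def layout():
    return g.StimulusLayout()


@pytest.fixture(scope="session")
def toy_hmm():
    """Small 2-state HMM with asymmetric dynamics for oracle comparisons."""
    rois = [g.GaussianROI([0.0, 0.0], np.eye(2)),
            g.GaussianROI([10.0, 5.0], [[2.0, 0.5], [0.5, 1.0]])]
    return g.SubjectHMM(prior=[0.3, 0.7],
                        transition=[[0.6, 0.4], [0.2, 0.8]], rois=rois)


@pytest.fixture(scope="session")
def small_cohort():
    """8 + 8 subject synthetic cohort, shared across tests (read-only)."""
    spec = g.CohortSpec(n_explorative=8, n_focused=8, seed=13)
    return g.generate_cohort(spec)


def random_hmm(rng: np.random.Generator, k: int, spread: float = 8.0) -> g.SubjectHMM:
    """A random valid K-state Gaussian HMM for property sweeps."""
    prior = rng.dirichlet(np.ones(k))
    transition = np.vstack([rng.dirichlet(np.ones(k)) for _ in range(k)])
    rois = []
    for _ in range(k):
        mean = rng.uniform(-spread, spread, size=2)
        a = rng.uniform(0.5, 2.0, size=(2, 2))
        cov = a @ a.T + 0.5 * np.eye(2)
        rois.append(g.GaussianROI(mean, cov))
    return g.SubjectHMM(prior=prior, transition=transition, rois=rois)


def brute_force_loglik(xy: np.ndarray, hmm: g.SubjectHMM) -> float:
    """logsumexp over all K^T hidden paths of log path probability + emissions."""
    from itertools import product

    from scipy.special import logsumexp

    path_logs = []
    T = xy.shape[0]
    with np.errstate(divide="ignore"):
        lp = np.log(hmm.prior)
        la = np.log(hmm.transition)
    for path in product(range(hmm.n_states), repeat=T):
        s = lp[path[0]]
        for a, b in zip(path, path[1:]):
            s += la[a, b]
        for t, st in enumerate(path):
            s += float(hmm.rois[st].logpdf(xy[t:t + 1])[0])
        path_logs.append(s)
    return float(logsumexp(path_logs))


def brute_force_viterbi(xy: np.ndarray, hmm: g.SubjectHMM) -> tuple:
    """Argmax over all hidden paths of log path probability + emissions."""
    from itertools import product

    best, best_path = -np.inf, None
    T = xy.shape[0]
    with np.errstate(divide="ignore"):
        lp = np.log(hmm.prior)
        la = np.log(hmm.transition)
    for path in product(range(hmm.n_states), repeat=T):
        s = lp[path[0]]
        for a, b in zip(path, path[1:]):
            s += la[a, b]
        for t, st in enumerate(path):
            s += float(hmm.rois[st].logpdf(xy[t:t + 1])[0])
        if s > best:
            best, best_path = s, path
    return best_path
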