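"""Gaussian-emission hidden Markov models over fixation sequences.

This is the data-driven ROI method: each subject's regions of interest are
2D Gaussians (hidden-state emissions), identified from that subject's own
fixation distribution, and gaze dynamics are a first-order Markov chain over
the hidden ROIs. Fitting is maximum-likelihood EM (Baum-Welch) with
multiple seeded initializations and BIC model selection over the number of
states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .types import FittingError, FixationSequence, GaussianROI, InputError, SubjectHMM

logger = logging.getLogger(__name__)

__all__ = [
    "log_likelihood",
    "viterbi_states",
    "stationary_distribution",
    "fit_subject_hmm",
    "FitConfig",
]

#: Minimum emission-covariance eigenvalue, px^2. Fixation scatter below ~5 px
#: is eye-tracker jitter, not a meaningful ROI; the floor also prevents
#: likelihood blow-up on near-duplicate fixations.
COV_FLOOR_PX2 = 25.0

#: Post-EM probability floors. ML estimates from one (or a few) sequences can
#: collapse prior/transition entries to exactly 0, which makes downstream
#: log-likelihood comparisons blow up (-inf-scale penalties for a single
#: unmodelled first fixation). Flooring the *reported* model keeps EM itself
#: a pure maximum-likelihood ascent while bounding those penalties.
PRIOR_FLOOR = 1e-2
TRANS_FLOOR = 1e-3


def _floor_probs(prior: np.ndarray, transition: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    prior = np.maximum(prior, PRIOR_FLOOR)
    prior = prior / prior.sum()
    transition = np.maximum(transition, TRANS_FLOOR)
    transition = transition / transition.sum(axis=1, keepdims=True)
    return prior, transition


def _as_xy(seq) -> np.ndarray:
    if isinstance(seq, FixationSequence):
        xy = seq.xy
    else:
        xy = np.atleast_2d(np.asarray(seq, dtype=float))
    if xy.shape[0] == 0:
        raise InputError("fixation sequence must have length >= 1")
    return xy


def _log_emissions(xy: np.ndarray, rois: Sequence[GaussianROI]) -> np.ndarray:
    """(T, K) matrix of per-state log emission densities."""
    return np.column_stack([roi.logpdf(xy) for roi in rois])


def log_likelihood(seq, hmm: SubjectHMM) -> float:
    """Log-probability (nats) of a fixation sequence under an HMM.

    Computed by the forward algorithm in log space, so it is finite for any
    positive-definite emission covariances.
    """
    xy = _as_xy(seq)
    log_b = _log_emissions(xy, hmm.rois)
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.prior)
        log_a = np.log(hmm.transition)
    log_alpha = log_pi + log_b[0]
    for t in range(1, xy.shape[0]):
        log_alpha = logsumexp(log_alpha[:, None] + log_a, axis=0) + log_b[t]
    return float(logsumexp(log_alpha))


def viterbi_states(seq, hmm: SubjectHMM) -> np.ndarray:
    """Most-probable hidden-state path (0-based ROI labels per fixation)."""
    xy = _as_xy(seq)
    log_b = _log_emissions(xy, hmm.rois)
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.prior)
        log_a = np.log(hmm.transition)
    T, K = log_b.shape
    delta = log_pi + log_b[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + log_a
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(K)] + log_b[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def stationary_distribution(transition: np.ndarray, prior: np.ndarray | None = None,
                            t_lim: int = 1000, burn_in: int | None = None) -> np.ndarray:
    """Limiting time-average of state occupancy.

    Averages pi . A^t over t = burn_in .. t_lim-1 (burn_in defaults to
    t_lim/2). The time-average (Cesaro) limit is well defined even for
    periodic or reducible chains; discarding the transient makes the result
    exact to machine precision for ergodic chains while an even-length
    window still averages out period-2 oscillations exactly. ``prior``
    defaults to uniform.
    """
    a = np.asarray(transition, dtype=float)
    k = a.shape[0]
    if burn_in is None:
        burn_in = t_lim // 2
    v = np.full(k, 1.0 / k) if prior is None else np.asarray(prior, dtype=float).copy()
    for _ in range(burn_in):
        v = v @ a
    acc = np.zeros(k)
    for _ in range(t_lim - burn_in):
        acc += v
        v = v @ a
    pi_star = acc / (t_lim - burn_in)
    return pi_star / pi_star.sum()


# ---------------------------------------------------------------------------
# Baum-Welch fitting


@dataclass(frozen=True)
class FitConfig:
    """Tunables for per-subject HMM fitting."""

    k_range: tuple[int, ...] = (1, 2, 3, 4)
    n_restarts: int = 20
    max_iter: int = 200
    tol: float = 1e-6
    cov_floor_px2: float = COV_FLOOR_PX2


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, floor)
    return evecs @ np.diag(evals) @ evecs.T


def _forward_backward(pi, a, log_b):
    """Scaled forward-backward (Rabiner-style). Returns (ll, gamma, xi_sum).

    Emissions arrive in log space and are max-shifted per time step before
    exponentiation, so arbitrarily small densities are handled; per-step
    normalization keeps the recursions in range.
    """
    T, K = log_b.shape
    shift = log_b.max(axis=1)
    b = np.exp(log_b - shift[:, None])  # row max = 1

    alpha_hat = np.empty((T, K))
    c = np.empty(T)
    v = pi * b[0]
    c[0] = v.sum()
    alpha_hat[0] = v / c[0]
    for t in range(1, T):
        v = (alpha_hat[t - 1] @ a) * b[t]
        c[t] = v.sum()
        alpha_hat[t] = v / c[t]
    ll = float(np.sum(np.log(c)) + np.sum(shift))

    beta_hat = np.empty((T, K))
    beta_hat[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        w = b[t + 1] * beta_hat[t + 1]
        xi_sum += (alpha_hat[t][:, None] * a * w[None, :]) / c[t + 1]
        beta_hat[t] = (a @ w) / c[t + 1]

    gamma = alpha_hat * beta_hat
    gamma /= gamma.sum(axis=1, keepdims=True)
    return ll, gamma, xi_sum


def _n_free_params(k: int) -> int:
    # prior (K-1) + transition K(K-1) + means 2K + symmetric 2x2 covariances 3K
    return (k - 1) + k * (k - 1) + 2 * k + 3 * k


def _em_one_restart(obs: list[np.ndarray], k: int, rng: np.random.Generator,
                    cfg: FitConfig) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One EM run. Returns (ll, prior, transition, means, covs)."""
    x = np.vstack(obs)
    n = x.shape[0]
    if k == 1:
        means = x.mean(axis=0, keepdims=True)
    else:
        seed = int(rng.integers(0, 2**31 - 1))
        means, _ = kmeans_plusplus(x, n_clusters=k, random_state=seed)
    base_cov = np.cov(x.T) if n > 1 else np.eye(2)
    base_cov = _floor_cov(np.atleast_2d(base_cov) / max(k, 1), cfg.cov_floor_px2)
    covs = np.repeat(base_cov[None, :, :], k, axis=0)
    prior = np.full(k, 1.0 / k)
    transition = np.full((k, k), 0.3 / max(k - 1, 1))
    np.fill_diagonal(transition, 0.7 if k > 1 else 1.0)
    transition /= transition.sum(axis=1, keepdims=True)

    prev_ll = -np.inf
    ll = -np.inf
    for _ in range(cfg.max_iter):
        rois = [GaussianROI(means[j], covs[j]) for j in range(k)]
        ll = 0.0
        g0 = np.zeros(k)
        gsum = np.zeros(k)
        gx = np.zeros((k, 2))
        gxx = np.zeros((k, 2, 2))
        xi_tot = np.zeros((k, k))
        for xy in obs:
            log_b = _log_emissions(xy, rois)
            ll_i, gamma, xi = _forward_backward(prior, transition, log_b)
            ll += ll_i
            g0 += gamma[0]
            gsum += gamma.sum(axis=0)
            gx += gamma.T @ xy
            for j in range(k):
                d = xy - means[j]
                gxx[j] += (gamma[:, j, None] * d).T @ d
            xi_tot += xi
        if ll < prev_ll - 1e-8:
            logger.debug("EM objective decreased by %.3g", prev_ll - ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < cfg.tol * (1.0 + abs(ll)):
            break
        prev_ll = ll

        # M-step
        prior = g0 / g0.sum()
        row = xi_tot.sum(axis=1, keepdims=True)
        transition = np.where(row > 1e-12, xi_tot / np.maximum(row, 1e-12),
                              np.full((k, k), 1.0 / k))
        transition /= transition.sum(axis=1, keepdims=True)
        w = np.maximum(gsum, 1e-12)
        new_means = gx / w[:, None]
        new_covs = np.empty_like(covs)
        for j in range(k):
            # gxx was accumulated around the OLD mean; recentre to the new one
            shift = new_means[j] - means[j]
            scatter = gxx[j] / w[j] - np.outer(shift, shift)
            new_covs[j] = _floor_cov(scatter, cfg.cov_floor_px2)
        means, covs = new_means, new_covs
    return ll, prior, transition, means, covs


def _fit_for_k(obs: list[np.ndarray], k: int, rng: np.random.Generator,
               cfg: FitConfig) -> SubjectHMM | None:
    best = None
    best_ll = -np.inf
    for _ in range(cfg.n_restarts):
        try:
            ll, prior, transition, means, covs = _em_one_restart(obs, k, rng, cfg)
        except np.linalg.LinAlgError:
            continue
        if np.isfinite(ll) and ll > best_ll:  # strict: lowest restart index wins ties
            best_ll = ll
            best = (ll, prior, transition, means, covs)
    if best is None:
        return None
    ll, prior, transition, means, covs = best
    prior, transition = _floor_probs(prior, transition)
    t_total = sum(len(o) for o in obs)
    score = ll - 0.5 * _n_free_params(k) * np.log(t_total)
    rois = [GaussianROI(means[j], covs[j]) for j in range(k)]
    hmm = SubjectHMM(prior=prior, transition=transition, rois=rois,
                     fit_score=score, n_fixations=t_total)
    # report states by descending stationary occupancy (prominence)
    pi_star = stationary_distribution(hmm.transition, hmm.prior)
    order = np.argsort(-pi_star, kind="stable")
    return hmm.permuted(order.tolist())


def fit_subject_hmm(sequences, k_range: Iterable[int] = (1, 2, 3, 4),
                    n_restarts: int = 20, seed: int | None = 0,
                    config: FitConfig | None = None) -> SubjectHMM:
    """Fit a Gaussian-emission HMM to one subject's fixation data.

    Parameters
    ----------
    sequences
        A single :class:`FixationSequence` (or (T, 2) array), or a list of
        them to pool (used when fitting representative group models).
    k_range
        Candidate numbers of hidden states (ROIs). The returned model
        maximizes BIC-penalized log-likelihood ``LL - p/2 * ln T``.
    n_restarts
        Seeded k-means++-style initializations per candidate K.
    seed
        Seed for the restart stream; fixing it makes the fit deterministic.

    Returns
    -------
    SubjectHMM
        Best model across K, states ordered by descending stationary mass.
    """
    if isinstance(sequences, (FixationSequence, np.ndarray)):
        sequences = [sequences]
    obs = [_as_xy(s) for s in sequences]
    t_total = sum(len(o) for o in obs)
    cfg = config or FitConfig()
    cfg = FitConfig(k_range=tuple(sorted(set(int(k) for k in k_range))),
                    n_restarts=int(n_restarts), max_iter=cfg.max_iter,
                    tol=cfg.tol, cov_floor_px2=cfg.cov_floor_px2)
    if any(k < 1 for k in cfg.k_range):
        raise InputError("k_range entries must be >= 1")
    k_max_feasible = max(t_total // 3, 1)
    ks = [k for k in cfg.k_range if k <= k_max_feasible]
    if not ks:
        logger.warning("sequence too short for requested K; capping at K=%d", k_max_feasible)
        ks = [k_max_feasible]
    elif len(ks) < len(cfg.k_range):
        logger.warning("capping K at %d for %d fixations", max(ks), t_total)

    rng = np.random.default_rng(seed)
    best: SubjectHMM | None = None
    for k in ks:
        hmm = _fit_for_k(obs, k, rng, cfg)
        if hmm is not None and (best is None or hmm.fit_score > best.fit_score):
            best = hmm
    if best is None:
        raise FittingError(
            f"all restarts degenerate (T={t_total}, k_range={cfg.k_range})")
    return best
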