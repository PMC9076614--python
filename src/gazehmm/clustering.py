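"""Clustering subject HMMs into representative eye-movement patterns.

Subjects' individual HMMs are grouped by the similarity of their ROIs and
ROI sequences. Each cluster is summarised by a representative HMM refit on
the pooled fixation sequences of its members; subjects are then reassigned
to the representative giving their data the highest per-fixation
log-likelihood, and the loop repeats until assignments stabilise.

Two derived per-subject measures:

* the E-F (explorative-focused) scale, (L1 - L2) / (|L1| + |L2|) with L1/L2
  the data log-likelihoods under the Pattern-1/Pattern-2 representatives —
  positive values mean the subject's gaze resembles the explorative pattern;
* overall entropy, the stationary entropy rate of the subject's hidden ROI
  chain — higher values mean less regular, less predictable gaze.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hmm import FitConfig, fit_subject_hmm, log_likelihood, stationary_distribution
from .types import FixationSequence, InputError, StimulusLayout, SubjectHMM

logger = logging.getLogger(__name__)

__all__ = ["ef_scale", "overall_entropy", "switching_probability",
           "cluster_hmms", "PatternClustering"]


def ef_scale(l1: float, l2: float) -> float:
    """Explorative-focused scale: (L1 - L2) / (|L1| + |L2|), in [-1, 1].

    L1 and L2 are a subject's data log-likelihoods under the Pattern-1
    (explorative) and Pattern-2 (focused) representative models. Positive
    values mean the data are better explained by Pattern 1.
    """
    denom = abs(l1) + abs(l2)
    if denom == 0.0:
        logger.warning("ef_scale undefined for L1 = L2 = 0; returning 0")
        return 0.0
    return float(np.clip((l1 - l2) / denom, -1.0, 1.0))


def overall_entropy(hmm_or_transition, prior: np.ndarray | None = None) -> float:
    """Stationary entropy rate of the hidden ROI chain, in nats.

    H = -sum_i pi*_i sum_j A_ij ln A_ij with pi* the limiting time-average
    occupancy and 0 ln 0 = 0. Bounded by 0 <= H <= ln K; 0 for deterministic
    transitions. Higher entropy means more random, less consistent gaze.
    """
    if isinstance(hmm_or_transition, SubjectHMM):
        a = hmm_or_transition.transition
        prior = hmm_or_transition.prior
    else:
        a = np.asarray(hmm_or_transition, dtype=float)
    pi_star = stationary_distribution(a, prior)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(a > 0, np.log(np.maximum(a, 1e-300)), 0.0)
    row_h = -np.sum(a * logs, axis=1)
    return float(max(np.dot(pi_star, row_h), 0.0))


def switching_probability(hmm: SubjectHMM, layout: StimulusLayout) -> float:
    """Stationary probability of a between-image (cross-midline) transition."""
    sides = np.array([layout.side_of(roi.mean[0]) for roi in hmm.rois])
    cross = sides[:, None] != sides[None, :]
    pi_star = stationary_distribution(hmm.transition, hmm.prior)
    return float(np.sum(pi_star[:, None] * hmm.transition * cross))


@dataclass
class PatternClustering:
    """Result of clustering subject HMMs into representative patterns.

    ``loglik[i, c]`` is subject i's raw data log-likelihood under the
    representative of cluster c; assignments maximize the per-fixation
    (length-normalized) log-likelihood. For two clusters, ``ef`` holds each
    subject's E-F scale; cluster 0 is Pattern 1 (explorative by the
    between-image-switching orientation rule, when a layout is given).
    """

    representatives: list[SubjectHMM]
    assignment: np.ndarray
    loglik: np.ndarray
    subject_ids: list[str]
    ef: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = True
    switch_prob: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def _per_fix_ll_matrix(models, sequences) -> np.ndarray:
    """M[a, b] = per-fixation log-likelihood of sequence b under model a."""
    n = len(models)
    m = np.empty((n, len(sequences)))
    for a, model in enumerate(models):
        for b, seq in enumerate(sequences):
            m[a, b] = log_likelihood(seq, model) / len(seq)
    return m


def _kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 100) -> np.ndarray:
    """Plain alternating k-medoids on a precomputed distance matrix."""
    n = dist.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    labels = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                # re-seed an empty cluster with the point farthest from its medoid
                worst = int(np.argmax(dist[np.arange(n), medoids[labels]]))
                new_medoids[c] = worst
                continue
            within = dist[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(np.argmin(within))]
        new_labels = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_labels, labels) and np.array_equal(new_medoids, medoids):
            break
        medoids, labels = new_medoids, new_labels
    return labels


def cluster_hmms(subject_models: list[SubjectHMM],
                 subject_sequences: list[FixationSequence],
                 n_clusters: int = 2, n_init: int = 4, seed: int | None = 0,
                 layout: StimulusLayout | None = None,
                 max_iter: int = 50,
                 rep_fit_config: FitConfig | None = None) -> PatternClustering:
    """Cluster subjects' HMMs into representative eye-movement patterns.

    Initialization is k-medoids on a symmetrized per-fixation log-likelihood
    distance between subject models; refinement alternates refitting each
    representative HMM on its members' pooled sequences with reassignment by
    per-fixation log-likelihood. The best of ``n_init`` seeded starts (by
    total normalized log-likelihood) is returned.

    When ``layout`` is given, clusters are oriented so Pattern 1 (index 0)
    is the representative with the higher between-image switching
    probability — the explorative pattern.
    """
    n = len(subject_models)
    if n != len(subject_sequences):
        raise InputError("need one sequence per subject model")
    if n < n_clusters:
        raise InputError(f"need at least {n_clusters} subjects, got {n}")
    rep_cfg = rep_fit_config or FitConfig(n_restarts=5)
    rng = np.random.default_rng(seed)

    # symmetrized likelihood distance between subject models
    m_self = _per_fix_ll_matrix(subject_models, subject_sequences)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = (m_self[i, i] - m_self[j, i]) + (m_self[j, j] - m_self[i, j])
            dist[i, j] = dist[j, i] = max(d, 0.0)

    best: PatternClustering | None = None
    best_score = -np.inf
    for init_idx in range(n_init):
        labels = _kmedoids(dist, n_clusters, rng)
        reps: list[SubjectHMM] = [None] * n_clusters  # type: ignore[list-item]
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            for c in range(n_clusters):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    # re-seed with the subject worst explained by its current cluster
                    per_fix = np.array([
                        log_likelihood(subject_sequences[i],
                                       reps[labels[i]]) / len(subject_sequences[i])
                        if reps[labels[i]] is not None else np.inf
                        for i in range(n)])
                    worst = int(np.argmin(per_fix))
                    logger.warning("empty cluster %d re-seeded with subject %d", c, worst)
                    labels[worst] = c
                    members = np.array([worst])
                pooled = [subject_sequences[i] for i in members]
                reps[c] = fit_subject_hmm(pooled, k_range=rep_cfg.k_range,
                                          n_restarts=rep_cfg.n_restarts,
                                          seed=int(rng.integers(0, 2**31 - 1)),
                                          config=rep_cfg)
            ll_norm = _per_fix_ll_matrix(reps, subject_sequences)  # (C, n)
            new_labels = np.argmax(ll_norm.T, axis=1)  # argmax ties -> lowest index
            if np.array_equal(new_labels, labels):
                converged = True
                break
            labels = new_labels
        score = float(ll_norm[labels, np.arange(n)].sum())
        if score > best_score:
            best_score = score
            raw_ll = np.empty((n, n_clusters))
            for c in range(n_clusters):
                for i in range(n):
                    raw_ll[i, c] = ll_norm[c, i] * len(subject_sequences[i])
            best = PatternClustering(
                representatives=list(reps), assignment=labels.copy(),
                loglik=raw_ll,
                subject_ids=[s.subject_id for s in subject_sequences],
                n_iter=n_iter, converged=converged)

    assert best is not None
    # orientation: Pattern 1 = highest between-image switching (explorative)
    if layout is not None:
        sw = [switching_probability(r, layout) for r in best.representatives]
        order = list(np.argsort([-s for s in sw], kind="stable"))
        if order != list(range(n_clusters)):
            best.representatives = [best.representatives[c] for c in order]
            best.loglik = best.loglik[:, order]
            remap = np.empty(n_clusters, dtype=int)
            for new_c, old_c in enumerate(order):
                remap[old_c] = new_c
            best.assignment = remap[best.assignment]
        best.switch_prob = [switching_probability(r, layout) for r in best.representatives]
    if n_clusters == 2:
        best.ef = np.array([ef_scale(l1, l2) for l1, l2 in best.loglik])
    return best
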