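"""Fixed-ROI analysis: investigator-defined elliptical Gaussian ROIs.

Instead of learning person-specific ROIs, two teeth-focused elliptical ROIs
are fixed on the stimulus — ROI1 on the image without the midline diastema,
ROI2 on the image with it; the drawn ellipse is the 2-standard-deviation
contour of the corresponding 2D Gaussian. Every fixation is hard-classified
to the ROI with the highest Gaussian likelihood (no rejection class), and
each subject's gaze dynamics reduce to a first-fixation prior and a
bigram-count transition matrix. Gaze preference is the fraction of a
subject's fixations falling in ROI1 (the no-diastema image), tested
against the 50% no-preference point downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import ef_scale
from .types import (ConfigurationError, FixationSequence, GaussianROI,
                    InputError, StimulusLayout)

logger = logging.getLogger(__name__)

__all__ = ["FixedROISet", "FixedROISubjectResult", "classify_fixations",
           "estimate_transition", "gaze_preference", "cluster_fixed_roi",
           "default_tooth_rois", "FixedROIClustering"]


@dataclass
class FixedROISet:
    """Labelled fixed ROIs. By convention index 0 is ROI1 (no diastema)."""

    rois: list[GaussianROI]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.rois) < 2:
            raise ConfigurationError("a fixed ROI set needs at least 2 ROIs")
        if len(self.labels) != len(self.rois) or len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("ROI labels must be unique, one per ROI")

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @classmethod
    def from_ellipses(cls, ellipses: list[dict]) -> "FixedROISet":
        """Build from ellipse specs: dicts with center, semi-axes a/b, theta_rad.

        The ellipse is read as the 2-SD contour of the ROI's Gaussian.
        """
        rois, labels = [], []
        for i, e in enumerate(ellipses):
            rois.append(GaussianROI.from_ellipse(
                e["center"], e["a"], e["b"], e.get("theta_rad", 0.0)))
            labels.append(e.get("label", f"ROI{i + 1}"))
        return cls(rois=rois, labels=labels)


def default_tooth_rois(layout: StimulusLayout) -> FixedROISet:
    """Two mouth-region ellipses, one per image, centred on the tooth area.

    ROI1 is on the no-diastema image (left hemifield in the default layout),
    ROI2 on the diastema image. Sizes are proportional to the image regions.
    """
    def tooth_center(rect):
        cx, _ = rect.center
        return (cx, rect.y0 + 0.68 * (rect.y1 - rect.y0))

    no_dia = (layout.left_image_region if layout.diastema_side == "right"
              else layout.right_image_region)
    dia = (layout.right_image_region if layout.diastema_side == "right"
           else layout.left_image_region)
    a = 0.22 * (no_dia.x1 - no_dia.x0)
    b = 0.12 * (no_dia.y1 - no_dia.y0)
    return FixedROISet(
        rois=[GaussianROI.from_ellipse(tooth_center(no_dia), a, b),
              GaussianROI.from_ellipse(tooth_center(dia), a, b)],
        labels=["ROI1", "ROI2"])


def classify_fixations(seq, roi_set: FixedROISet) -> np.ndarray:
    """Assign each fixation to the ROI with the highest Gaussian log-density.

    Equal mixing weights; ties break to the lowest ROI index. Returns 0-based
    labels (0 = ROI1).
    """
    if isinstance(seq, FixationSequence):
        xy = seq.xy
    else:
        xy = np.atleast_2d(np.asarray(seq, dtype=float))
    if xy.shape[0] == 0:
        raise InputError("cannot classify an empty sequence")
    dens = np.column_stack([roi.logpdf(xy) for roi in roi_set.rois])
    return np.argmax(dens, axis=1)  # np.argmax breaks ties toward lower index


def estimate_transition(labels, n_rois: int | None = None) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Count-based prior and transition matrix from a label sequence.

    Returns (prior, transition, uniform_rows): prior is the one-hot indicator
    of the first label; transition row i is the normalized count of i->j
    bigrams; rows for unvisited ROIs are set uniform and their indices
    reported in ``uniform_rows``.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size < 2:
        raise InputError("need >= 2 fixations to estimate a transition matrix")
    k = int(n_rois) if n_rois is not None else int(labels.max()) + 1
    prior = np.zeros(k)
    prior[labels[0]] = 1.0
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    rowsum = counts.sum(axis=1)
    uniform_rows = [int(i) for i in np.flatnonzero(rowsum == 0)]
    if uniform_rows:
        logger.debug("unvisited ROI rows %s set to uniform", uniform_rows)
    transition = np.where(rowsum[:, None] > 0,
                          counts / np.maximum(rowsum[:, None], 1.0),
                          np.full((k, k), 1.0 / k))
    return prior, transition, uniform_rows


def gaze_preference(labels, roi_index: int = 0) -> float:
    """Fraction of fixations classified into ``roi_index`` (default ROI1)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise InputError("cannot compute gaze preference of an empty label sequence")
    return float(np.mean(labels == roi_index))


@dataclass
class FixedROISubjectResult:
    """Per-subject fixed-ROI summary."""

    subject_id: str
    labels: np.ndarray
    prior: np.ndarray
    transition: np.ndarray
    gaze_preference: float
    uniform_rows: list[int] = field(default_factory=list)

    @classmethod
    def from_sequence(cls, seq: FixationSequence,
                      roi_set: FixedROISet) -> "FixedROISubjectResult":
        labels = classify_fixations(seq, roi_set)
        prior, transition, uniform_rows = estimate_transition(labels, roi_set.n_rois)
        return cls(subject_id=seq.subject_id, labels=labels, prior=prior,
                   transition=transition,
                   gaze_preference=gaze_preference(labels),
                   uniform_rows=uniform_rows)


@dataclass
class FixedROIClustering:
    """Clustering of fixed-ROI transition behaviour.

    Representatives are pooled first-fixation priors and pooled bigram-count
    transition matrices. Cluster 0 is the explorative pattern (higher mean
    off-diagonal switching); for two clusters ``ef`` holds the E-F scale of
    each subject's label sequence under the two representatives.
    """

    rep_priors: list[np.ndarray]
    rep_transitions: list[np.ndarray]
    assignment: np.ndarray
    loglik: np.ndarray
    subject_ids: list[str]
    ef: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = True


_EVAL_EPS = 1e-9  # smoothing for log-evaluation of count-based models only


def _labels_loglik(labels: np.ndarray, prior: np.ndarray, transition: np.ndarray) -> float:
    p = np.maximum(prior, _EVAL_EPS)
    a = np.maximum(transition, _EVAL_EPS)
    ll = np.log(p[labels[0]])
    if labels.size > 1:
        ll += float(np.sum(np.log(a[labels[:-1], labels[1:]])))
    return float(ll)


def _pooled_model(members: list[FixedROISubjectResult], k: int) -> tuple[np.ndarray, np.ndarray]:
    prior = np.zeros(k)
    counts = np.zeros((k, k))
    for r in members:
        prior[r.labels[0]] += 1.0
        np.add.at(counts, (r.labels[:-1], r.labels[1:]), 1.0)
    prior /= prior.sum()
    rowsum = counts.sum(axis=1)
    transition = np.where(rowsum[:, None] > 0,
                          counts / np.maximum(rowsum[:, None], 1.0),
                          np.full((k, k), 1.0 / k))
    return prior, transition


def _mean_offdiag(transition: np.ndarray) -> float:
    k = transition.shape[0]
    return float(np.mean(transition.sum(axis=1) - np.diag(transition))) if k > 1 else 0.0


def cluster_fixed_roi(subject_results: list[FixedROISubjectResult],
                      n_clusters: int = 2, n_init: int = 4,
                      seed: int | None = 0, max_iter: int = 50) -> FixedROIClustering:
    """Cluster subjects by their between-ROI transition behaviour.

    Same refit/reassign loop as the data-driven clustering, with emissions
    frozen at the fixed ROI set: representatives are pooled-count priors and
    transition matrices; subjects are reassigned by per-fixation
    log-likelihood of their label sequence. Cluster 0 ("explorative") is the
    representative with the higher mean off-diagonal switching probability.
    """
    n = len(subject_results)
    if n < n_clusters:
        raise InputError(f"need at least {n_clusters} subjects, got {n}")
    k = subject_results[0].prior.shape[0]
    rng = np.random.default_rng(seed)

    # symmetrized likelihood distance between subjects' own count models
    def perfix(r_model: FixedROISubjectResult, r_data: FixedROISubjectResult) -> float:
        return _labels_loglik(r_data.labels, r_model.prior, r_model.transition) / r_data.labels.size

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = (perfix(subject_results[i], subject_results[i]) - perfix(subject_results[j], subject_results[i])
                 + perfix(subject_results[j], subject_results[j]) - perfix(subject_results[i], subject_results[j]))
            dist[i, j] = dist[j, i] = max(d, 0.0)

    from .clustering import _kmedoids  # shared initializer

    best: FixedROIClustering | None = None
    best_score = -np.inf
    for _ in range(n_init):
        labels = _kmedoids(dist, n_clusters, rng)
        priors = [np.full(k, 1.0 / k)] * n_clusters
        transitions = [np.full((k, k), 1.0 / k)] * n_clusters
        converged = False
        n_iter = 0
        ll_norm = np.zeros((n, n_clusters))
        for n_iter in range(1, max_iter + 1):
            for c in range(n_clusters):
                members = [subject_results[i] for i in np.flatnonzero(labels == c)]
                if not members:
                    worst = int(np.argmin(ll_norm[np.arange(n), labels]))
                    logger.warning("empty cluster %d re-seeded with subject %d", c, worst)
                    labels[worst] = c
                    members = [subject_results[worst]]
                priors[c], transitions[c] = _pooled_model(members, k)
            for i, r in enumerate(subject_results):
                for c in range(n_clusters):
                    ll_norm[i, c] = _labels_loglik(r.labels, priors[c],
                                                   transitions[c]) / r.labels.size
            new_labels = np.argmax(ll_norm, axis=1)
            if np.array_equal(new_labels, labels):
                converged = True
                break
            labels = new_labels
        score = float(ll_norm[np.arange(n), labels].sum())
        if score > best_score:
            best_score = score
            raw = ll_norm * np.array([[r.labels.size] for r in subject_results])
            best = FixedROIClustering(
                rep_priors=[p.copy() for p in priors],
                rep_transitions=[t.copy() for t in transitions],
                assignment=labels.copy(), loglik=raw,
                subject_ids=[r.subject_id for r in subject_results],
                n_iter=n_iter, converged=converged)

    assert best is not None
    order = list(np.argsort([-_mean_offdiag(t) for t in best.rep_transitions],
                            kind="stable"))
    if order != list(range(n_clusters)):
        best.rep_priors = [best.rep_priors[c] for c in order]
        best.rep_transitions = [best.rep_transitions[c] for c in order]
        best.loglik = best.loglik[:, order]
        remap = np.empty(n_clusters, dtype=int)
        for new_c, old_c in enumerate(order):
            remap[old_c] = new_c
        best.assignment = remap[best.assignment]
    if n_clusters == 2:
        best.ef = np.array([ef_scale(l1, l2) for l1, l2 in best.loglik])
    return best
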