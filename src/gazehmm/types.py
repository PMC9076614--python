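"""Domain types for eye-movement analysis with hidden Markov models.

Coordinates are screen pixels with the origin at the top-left corner,
x increasing rightward and y downward. Times are integer milliseconds
from stimulus onset. Pupil diameters are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "InputError",
    "FittingError",
    "FixationRecord",
    "FixationSequence",
    "PupilSample",
    "SubjectMeta",
    "Rect",
    "StimulusLayout",
    "GaussianROI",
    "SubjectHMM",
]


class ConfigurationError(ValueError):
    """A configuration (dialect, column mapping, spec) is invalid."""


class InputError(ValueError):
    """Input data violate a precondition (empty file, empty sequence...)."""


class FittingError(RuntimeError):
    """Model fitting failed on every attempted initialization."""


@dataclass(frozen=True)
class FixationRecord:
    """One fixation: where gaze rested, when, and for how long."""

    subject_id: str
    onset_ms: int
    duration_ms: int
    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise InputError(f"onset_ms must be >= 0, got {self.onset_ms}")
        if self.duration_ms <= 0:
            raise InputError(f"duration_ms must be > 0, got {self.duration_ms}")
        if not (math.isfinite(self.x_px) and math.isfinite(self.y_px)):
            raise InputError("fixation coordinates must be finite")


@dataclass
class FixationSequence:
    """Time-ordered fixations of one subject/trial: the HMM observation sequence."""

    subject_id: str
    records: list[FixationRecord]

    def __post_init__(self) -> None:
        onsets = [r.onset_ms for r in self.records]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise InputError(f"fixation onsets not nondecreasing for {self.subject_id}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        """(T, 2) array of fixation positions in pixels."""
        return np.array([[r.x_px, r.y_px] for r in self.records], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class PupilSample:
    """One pupil-diameter sample.

    ``valid`` is False for blinks and tracker dropouts; invalid samples are
    retained in the trace (the cleaning stage masks them). ``on_stimulus``
    marks whether gaze was on the image region at this sample.
    """

    t_ms: int
    diameter_mm: float
    valid: bool = True
    on_stimulus: bool = True

    def __post_init__(self) -> None:
        if self.valid and not (math.isfinite(self.diameter_mm) and self.diameter_mm > 0):
            raise InputError(
                f"valid pupil sample must have positive finite diameter, got {self.diameter_mm}"
            )

    @classmethod
    def from_raw(cls, t_ms: int, diameter_mm: float, valid: bool = True,
                 on_stimulus: bool = True) -> "PupilSample":
        """Build a sample, demoting non-physical diameters to invalid."""
        if not (math.isfinite(diameter_mm) and diameter_mm > 0):
            valid = False
        return cls(t_ms=t_ms, diameter_mm=float(diameter_mm), valid=valid,
                   on_stimulus=on_stimulus)


AGE_GROUPS = ("2.6-3.5", "3.6-4.5", "4.6-5.5")


@dataclass(frozen=True)
class SubjectMeta:
    """Cohort metadata: role, gender, age stratum, pre-task activity outcome."""

    subject_id: str
    role: str  # "child" | "educator"
    gender: str  # "male" | "female"
    age_group: str | None = None  # one of AGE_GROUPS for children, None for educators
    activity: str = "none"  # "complete" | "incomplete" | "none"

    def __post_init__(self) -> None:
        if self.role not in ("child", "educator"):
            raise ConfigurationError(f"unknown role {self.role!r}")
        if self.gender not in ("male", "female"):
            raise ConfigurationError(f"unknown gender {self.gender!r}")
        if self.role == "child":
            if self.age_group not in AGE_GROUPS:
                raise ConfigurationError(f"children need an age_group, got {self.age_group!r}")
            if self.activity not in ("complete", "incomplete"):
                raise ConfigurationError("children need activity complete|incomplete")
        else:
            if self.age_group is not None:
                raise ConfigurationError("educators have no age_group")
            if self.activity != "none":
                raise ConfigurationError("educators have activity 'none'")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in pixel coordinates (x0 <= x1, y0 <= y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ConfigurationError(f"degenerate rectangle {self}")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))


@dataclass(frozen=True)
class StimulusLayout:
    """Two side-by-side face images on one screen.

    By convention the image with the midline diastema sits in the right
    hemifield; ``diastema_side`` records which side it actually is.
    """

    screen_w_px: int = 1920
    screen_h_px: int = 1080
    left_image_region: Rect = field(default_factory=lambda: Rect(160, 240, 880, 840))
    right_image_region: Rect = field(default_factory=lambda: Rect(1040, 240, 1760, 840))
    diastema_side: str = "right"

    def __post_init__(self) -> None:
        if self.diastema_side not in ("left", "right"):
            raise ConfigurationError("diastema_side must be 'left' or 'right'")
        l, r = self.left_image_region, self.right_image_region
        if l.x1 > r.x0:
            raise ConfigurationError("image regions must be disjoint (left before right)")
        for rect in (l, r):
            if rect.x0 < 0 or rect.y0 < 0 or rect.x1 > self.screen_w_px or rect.y1 > self.screen_h_px:
                raise ConfigurationError("image region outside the screen")

    @property
    def midline_x(self) -> float:
        """Vertical boundary separating the two image hemifields."""
        return 0.5 * (self.left_image_region.x1 + self.right_image_region.x0)

    def side_of(self, x: float) -> str:
        return "left" if x < self.midline_x else "right"


class GaussianROI:
    """A region of interest modelled as a 2D Gaussian (hidden-state emission).

    Parameters
    ----------
    mean : array-like, shape (2,)
        ROI centre in pixels.
    cov : array-like, shape (2, 2)
        Symmetric positive-definite covariance in px^2.
    """

    __slots__ = ("mean", "cov", "_chol", "_logdet")

    def __init__(self, mean, cov):
        self.mean = np.asarray(mean, dtype=float).reshape(2)
        cov = np.asarray(cov, dtype=float).reshape(2, 2)
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ConfigurationError("covariance must be symmetric")
        self.cov = 0.5 * (cov + cov.T)
        try:
            self._chol = np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("covariance must be positive definite") from exc
        self._logdet = 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    def __repr__(self) -> str:
        return f"GaussianROI(mean={self.mean.tolist()}, cov={self.cov.tolist()})"

    def __eq__(self, other) -> bool:
        return (isinstance(other, GaussianROI)
                and np.array_equal(self.mean, other.mean)
                and np.array_equal(self.cov, other.cov))

    def logpdf(self, points: np.ndarray) -> np.ndarray:
        """Log density at each row of ``points`` (N, 2) -> (N,)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        diff = pts - self.mean
        # solve L z = diff^T; Mahalanobis = |z|^2
        z = np.linalg.solve(self._chol, diff.T)
        maha = np.sum(z * z, axis=0)
        return -np.log(2.0 * np.pi) - 0.5 * self._logdet - 0.5 * maha

    @classmethod
    def from_ellipse(cls, center, semi_axis_a: float, semi_axis_b: float,
                     theta_rad: float = 0.0) -> "GaussianROI":
        """Build from a drawn ellipse taken as the 2-standard-deviation contour.

        The ellipse semi-axes therefore equal two standard deviations along the
        principal directions: cov = R diag((a/2)^2, (b/2)^2) R^T.
        """
        if semi_axis_a <= 0 or semi_axis_b <= 0:
            raise ConfigurationError("ellipse semi-axes must be positive")
        c, s = math.cos(theta_rad), math.sin(theta_rad)
        rot = np.array([[c, -s], [s, c]])
        cov = rot @ np.diag([(semi_axis_a / 2.0) ** 2, (semi_axis_b / 2.0) ** 2]) @ rot.T
        return cls(center, cov)

    def ellipse_2sd(self) -> tuple[np.ndarray, float, float, float]:
        """2-SD contour as (center, semi_axis_a, semi_axis_b, theta_rad)."""
        evals, evecs = np.linalg.eigh(self.cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        theta = math.atan2(evecs[1, 0], evecs[0, 0])
        # an axis direction is defined modulo pi; report theta in (-pi/2, pi/2]
        if theta <= -math.pi / 2:
            theta += math.pi
        elif theta > math.pi / 2:
            theta -= math.pi
        return self.mean.copy(), 2.0 * math.sqrt(evals[0]), 2.0 * math.sqrt(evals[1]), theta


_STOCH_ATOL = 1e-9


@dataclass
class SubjectHMM:
    """A fitted hidden Markov model for one subject (or a representative group model).

    Hidden states are ROIs; ``prior`` is the probability the fixation sequence
    starts in each ROI and ``transition`` the row-stochastic matrix of moving
    from the previously viewed ROI to the current one.
    """

    prior: np.ndarray
    transition: np.ndarray
    rois: list[GaussianROI]
    fit_score: float = float("nan")
    n_fixations: int = 0

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float).reshape(-1)
        self.transition = np.asarray(self.transition, dtype=float)
        k = self.prior.shape[0]
        if self.transition.shape != (k, k):
            raise ConfigurationError("transition must be K x K matching the prior")
        if len(self.rois) != k:
            raise ConfigurationError("need one GaussianROI per hidden state")
        if np.any(self.prior < -_STOCH_ATOL) or np.any(self.transition < -_STOCH_ATOL):
            raise ConfigurationError("probabilities must be nonnegative")
        if abs(self.prior.sum() - 1.0) > _STOCH_ATOL:
            raise ConfigurationError(f"prior sums to {self.prior.sum()}, expected 1")
        rowsums = self.transition.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > _STOCH_ATOL):
            raise ConfigurationError(f"transition rows sum to {rowsums}, expected 1")

    @property
    def n_states(self) -> int:
        return self.prior.shape[0]

    def means(self) -> np.ndarray:
        return np.array([roi.mean for roi in self.rois])

    def permuted(self, perm: Sequence[int]) -> "SubjectHMM":
        """Relabel hidden states by ``perm`` (new index i <- old index perm[i])."""
        perm = list(perm)
        idx = np.asarray(perm)
        return SubjectHMM(
            prior=self.prior[idx],
            transition=self.transition[np.ix_(idx, idx)],
            rois=[self.rois[i] for i in perm],
            fit_score=self.fit_score,
            n_fixations=self.n_fixations,
        )
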