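"""Synthetic cohorts of fixation sequences and pupil traces.

Emulates a single ~10 s viewing trial of two side-by-side face images (the
image with a midline diastema in the right hemifield) by subjects drawn
from two archetype gaze patterns:

* explorative — broad ROIs around the circumoral regions plus one spanning
  both images, with frequent between-image switching;
* focused — tight tooth-region ROIs with long dwells before switching.

Each subject is a jittered realization of their archetype's generative HMM
(Dirichlet-resampled transition rows, Gaussian-perturbed ROI means, scaled
covariances): the analysis presumes individual differences around group
patterns, so the generator produces them. Pupil traces have a ~3 mm
baseline, a slow smooth dilation toward a target percentage increase, and
blink artefacts inserted as runs of invalid samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import (ConfigurationError, FixationRecord, FixationSequence,
                    GaussianROI, PupilSample, StimulusLayout, SubjectMeta,
                    AGE_GROUPS)

__all__ = ["ArchetypeSpec", "PupilParams", "CohortSpec", "Cohort",
           "default_explorative", "default_focused",
           "generate_subject_sequence", "generate_pupil_trace",
           "generate_cohort"]


@dataclass
class ArchetypeSpec:
    """Generative HMM archetype plus per-subject jitter scales."""

    name: str
    prior: np.ndarray
    transition: np.ndarray
    rois: list[GaussianROI]
    fixations_per_trial: tuple[int, int] = (15, 35)
    jitter_mean_px: float = 20.0
    jitter_cov_log: float = 0.10
    jitter_transition_conc: float = 60.0

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        k = self.prior.shape[0]
        if abs(self.prior.sum() - 1.0) > 1e-9:
            raise ConfigurationError("archetype prior must sum to 1")
        if self.transition.shape != (k, k):
            raise ConfigurationError("transition must be K x K")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("transition rows must sum to 1")
        if len(self.rois) != k:
            raise ConfigurationError("need one ROI per state")
        lo, hi = self.fixations_per_trial
        if not (1 <= lo <= hi):
            raise ConfigurationError("fixations_per_trial must be a valid range")

    @property
    def n_states(self) -> int:
        return self.prior.shape[0]


def default_explorative(layout: StimulusLayout | None = None) -> ArchetypeSpec:
    """Explorative archetype: one broad both-images ROI + two circumoral ROIs.

    Starting in the broad ROI the gaze stays there; from either circumoral
    ROI it dwells (0.63) or switches to the matching region of the other
    image (0.37), i.e. frequent between-image transits.
    """
    layout = layout or StimulusLayout()
    lcx, _ = layout.left_image_region.center
    rcx, _ = layout.right_image_region.center
    cy = 0.55 * layout.screen_h_px
    return ArchetypeSpec(
        name="explorative",
        prior=[0.42, 0.28, 0.30],
        transition=[[1.00, 0.00, 0.00],
                    [0.00, 0.63, 0.37],
                    [0.00, 0.37, 0.63]],
        rois=[GaussianROI((0.5 * (lcx + rcx), 0.5 * layout.screen_h_px),
                          np.diag([380.0 ** 2, 180.0 ** 2])),
              GaussianROI((lcx, cy), np.diag([130.0 ** 2, 100.0 ** 2])),
              GaussianROI((rcx, cy), np.diag([130.0 ** 2, 100.0 ** 2]))])


def default_focused(layout: StimulusLayout | None = None) -> ArchetypeSpec:
    """Focused archetype: two tight tooth ROIs with long dwells.

    ROI order matches the fixed-ROI convention: state 0 on the no-diastema
    image, state 1 on the diastema image; self-transitions 0.83 / 0.75.
    """
    layout = layout or StimulusLayout()

    def tooth(rect):
        cx, _ = rect.center
        return (cx, rect.y0 + 0.68 * (rect.y1 - rect.y0))

    no_dia = (layout.left_image_region if layout.diastema_side == "right"
              else layout.right_image_region)
    dia = (layout.right_image_region if layout.diastema_side == "right"
           else layout.left_image_region)
    cov = np.diag([45.0 ** 2, 28.0 ** 2])
    return ArchetypeSpec(
        name="focused",
        prior=[0.51, 0.49],
        transition=[[0.83, 0.17],
                    [0.25, 0.75]],
        rois=[GaussianROI(tooth(no_dia), cov), GaussianROI(tooth(dia), cov)])


def _jitter_archetype(arch: ArchetypeSpec, rng: np.random.Generator):
    """One subject's realized (prior, transition, rois) around the archetype."""
    k = arch.n_states
    transition = np.empty_like(arch.transition)
    for i in range(k):
        row = arch.transition[i]
        support = row > 0
        if support.sum() <= 1 or arch.jitter_transition_conc <= 0:
            transition[i] = row
        else:
            alpha = arch.jitter_transition_conc * row[support]
            transition[i] = 0.0
            transition[i, support] = rng.dirichlet(alpha)
    rois = []
    for roi in arch.rois:
        mean = roi.mean + rng.normal(0.0, arch.jitter_mean_px, size=2)
        scale = float(np.exp(rng.normal(0.0, arch.jitter_cov_log)))
        rois.append(GaussianROI(mean, roi.cov * scale))
    return arch.prior.copy(), transition, rois


def _sample_sequence(subject_id: str, prior, transition, rois, n_fix: int,
                     rng: np.random.Generator, trial_ms: int,
                     duration_range=(100, 600)) -> tuple[FixationSequence, list[int]]:
    k = prior.shape[0]
    states: list[int] = []
    records: list[FixationRecord] = []
    onset = 0
    state = int(rng.choice(k, p=prior))
    for _ in range(n_fix):
        if onset >= trial_ms:
            break
        duration = int(rng.integers(duration_range[0], duration_range[1] + 1))
        duration = min(duration, trial_ms - onset)
        x, y = rng.multivariate_normal(rois[state].mean, rois[state].cov)
        records.append(FixationRecord(subject_id=subject_id, onset_ms=onset,
                                      duration_ms=duration,
                                      x_px=float(x), y_px=float(y)))
        states.append(state)
        onset += duration
        state = int(rng.choice(k, p=transition[state]))
    return FixationSequence(subject_id=subject_id, records=records), states


def generate_subject_sequence(archetype: ArchetypeSpec, seed,
                              subject_id: str = "s000",
                              trial_ms: int = 10_000,
                              jitter: bool = True) -> FixationSequence:
    """Sample one subject's fixation sequence from an archetype.

    A hidden path is drawn from the (possibly jittered) prior/transition;
    each fixation position is drawn from the current state's Gaussian ROI;
    onsets are cumulative with durations uniform in [100, 600] ms, truncated
    to the trial window. Same seed, same sequence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if jitter:
        prior, transition, rois = _jitter_archetype(archetype, rng)
    else:
        prior, transition, rois = archetype.prior, archetype.transition, archetype.rois
    lo, hi = archetype.fixations_per_trial
    n_fix = int(rng.integers(lo, hi + 1))
    seq, _ = _sample_sequence(subject_id, prior, transition, rois, n_fix, rng,
                              trial_ms)
    return seq


@dataclass
class PupilParams:
    """Pupil-trace generator parameters."""

    sample_hz: float = 60.0
    baseline_mm: float = 3.0
    response_mean_pct: float = 11.5
    response_sd_pct: float = 3.0
    blink_rate_hz: float = 0.2
    blink_ms: tuple[int, int] = (100, 300)
    noise_sd_mm: float = 0.002
    ramp_start_ms: int = 300
    ramp_end_ms: int = 2500


def generate_pupil_trace(response_percent: float, seed,
                         params: PupilParams | None = None,
                         trial_ms: int = 10_000,
                         off_stimulus_ms: tuple[int, int] | None = None) -> list[PupilSample]:
    """Generate a pupil trace whose binned response recovers ``response_percent``.

    The trace is flat at baseline for the first 300 ms, then dilates along a
    smoothstep ramp to a plateau at ``baseline * (1 + response/100)``, so the
    maximum 300 ms bin mean exceeds baseline by the requested percentage
    before artefact injection. Blinks are Poisson-placed runs of invalid
    samples; ``off_stimulus_ms`` marks a window where gaze left the image.
    """
    p = params or PupilParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(trial_ms * p.sample_hz / 1000.0))
    t_ms = np.round(np.arange(n) * 1000.0 / p.sample_hz).astype(int)

    u = np.clip((t_ms - p.ramp_start_ms) / max(p.ramp_end_ms - p.ramp_start_ms, 1), 0.0, 1.0)
    shape = u * u * (3.0 - 2.0 * u)  # smoothstep
    diam = p.baseline_mm * (1.0 + response_percent / 100.0 * shape)
    diam = diam + rng.normal(0.0, p.noise_sd_mm, size=n)

    valid = np.ones(n, dtype=bool)
    n_blinks = int(rng.poisson(p.blink_rate_hz * trial_ms / 1000.0))
    for _ in range(n_blinks):
        start = float(rng.uniform(0, trial_ms))
        dur = float(rng.uniform(*p.blink_ms))
        valid &= ~((t_ms >= start) & (t_ms < start + dur))

    on_stim = np.ones(n, dtype=bool)
    if off_stimulus_ms is not None:
        a, b = off_stimulus_ms
        on_stim &= ~((t_ms >= a) & (t_ms < b))

    return [PupilSample.from_raw(int(t_ms[i]),
                                 float(diam[i]) if valid[i] else 0.0,
                                 valid=bool(valid[i]),
                                 on_stimulus=bool(on_stim[i]))
            for i in range(n)]


@dataclass
class CohortSpec:
    """Cohort composition and generator settings."""

    n_explorative: int = 20
    n_focused: int = 20
    n_educators_explorative: int = 0
    n_educators_focused: int = 0
    seed: int = 0
    trial_ms: int = 10_000
    layout: StimulusLayout = field(default_factory=StimulusLayout)
    pupil: PupilParams = field(default_factory=PupilParams)
    explorative: ArchetypeSpec | None = None
    focused: ArchetypeSpec | None = None

    def __post_init__(self) -> None:
        if self.n_explorative + self.n_focused < 1:
            raise ConfigurationError("cohort needs at least one subject")
        if self.explorative is None:
            self.explorative = default_explorative(self.layout)
        if self.focused is None:
            self.focused = default_focused(self.layout)


@dataclass
class Cohort:
    """An in-memory synthetic dataset plus its ground-truth manifest."""

    sequences: list[FixationSequence]
    pupil: dict[str, list[PupilSample]]
    meta: list[SubjectMeta]
    truth: dict
    spec: CohortSpec


def _realized_switch_prob(prior, transition, rois, layout: StimulusLayout) -> float:
    from .hmm import stationary_distribution
    sides = np.array([layout.side_of(r.mean[0]) for r in rois])
    cross = sides[:, None] != sides[None, :]
    pi_star = stationary_distribution(transition, prior)
    return float(np.sum(pi_star[:, None] * transition * cross))


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full cohort: fixations, pupil traces, metadata, truth manifest.

    Deterministic in ``spec.seed``: two runs with the same spec produce
    byte-identical CSV outputs. The truth manifest records each subject's
    archetype label, realized HMM parameters, realized between-image
    switching probability, and target pupil response.
    """
    rng = np.random.default_rng(spec.seed)
    roster: list[tuple[str, ArchetypeSpec, str]] = []
    for i in range(spec.n_explorative):
        roster.append((f"c{i + 1:03d}", spec.explorative, "child"))
    for i in range(spec.n_focused):
        roster.append((f"c{spec.n_explorative + i + 1:03d}", spec.focused, "child"))
    n_children = len(roster)
    for i in range(spec.n_educators_explorative):
        roster.append((f"e{i + 1:03d}", spec.explorative, "educator"))
    for i in range(spec.n_educators_focused):
        roster.append((f"e{spec.n_educators_explorative + i + 1:03d}",
                       spec.focused, "educator"))

    sequences: list[FixationSequence] = []
    pupil: dict[str, list[PupilSample]] = {}
    meta: list[SubjectMeta] = []
    truth_subjects = {}
    child_idx = 0
    for sid, arch, role in roster:
        prior, transition, rois = _jitter_archetype(arch, rng)
        lo, hi = arch.fixations_per_trial
        n_fix = int(rng.integers(lo, hi + 1))
        seq, states = _sample_sequence(sid, prior, transition, rois, n_fix, rng,
                                       spec.trial_ms)
        sequences.append(seq)

        resp = float(max(rng.normal(spec.pupil.response_mean_pct,
                                    spec.pupil.response_sd_pct), 0.0))
        pupil[sid] = generate_pupil_trace(resp, rng, spec.pupil, spec.trial_ms)

        if role == "child":
            meta.append(SubjectMeta(
                subject_id=sid, role="child",
                gender="male" if child_idx % 2 == 0 else "female",
                age_group=AGE_GROUPS[child_idx % 3],
                activity="complete" if (child_idx // 2) % 2 == 0 else "incomplete"))
            child_idx += 1
        else:
            meta.append(SubjectMeta(subject_id=sid, role="educator",
                                    gender="male" if child_idx % 2 == 0 else "female"))

        truth_subjects[sid] = {
            "archetype": arch.name,
            "role": role,
            "prior": prior.tolist(),
            "transition": transition.tolist(),
            "roi_means": [r.mean.tolist() for r in rois],
            "roi_covs": [r.cov.tolist() for r in rois],
            "states": states,
            "switch_prob": _realized_switch_prob(prior, transition, rois, spec.layout),
            "pupil_response_pct": resp,
            "n_fixations": len(seq),
        }

    truth = {
        "seed": spec.seed,
        "n_children": n_children,
        "n_educators": len(roster) - n_children,
        "archetypes": {
            spec.explorative.name: {
                "prior": spec.explorative.prior.tolist(),
                "transition": spec.explorative.transition.tolist()},
            spec.focused.name: {
                "prior": spec.focused.prior.tolist(),
                "transition": spec.focused.transition.tolist()},
        },
        "subjects": truth_subjects,
    }
    cohort = Cohort(sequences=sequences, pupil=pupil, meta=meta, truth=truth,
                    spec=spec)
    if out_dir is not None:
        from . import io as gio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gio.write_fixations(sequences, out / "fixations.csv")
        gio.write_pupil(pupil, out / "pupil.csv")
        gio.write_meta(meta, out / "meta.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return cohort
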