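"""Event-related pupillometry: cleaning, 300 ms binning, percentage response.

The pupillary response to the stimulus is summarised as the percentage
increase of mean pupil diameter over a baseline: diameters are averaged in
300 ms intervals time-locked to stimulus onset across the 10 s presentation,
the first interval is the baseline, and the response is
100 * (max bin mean - baseline) / baseline. Blinks, tracker dropouts and
abrupt diameter jumps are masked before averaging; a subject is excluded
when gaze left the image for three or more consecutive intervals (the
baseline is then unreliable) or the baseline interval itself is invalid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import PupilSample

__all__ = ["PupilResponse", "clean_and_bin", "exclusion_check", "pupil_response"]


@dataclass
class PupilResponse:
    """Binned pupil trace and its baseline-relative percentage increase."""

    subject_id: str
    bin_means: np.ndarray        # NaN for invalid bins
    bin_valid: np.ndarray        # bool per bin
    baseline_mm: float = float("nan")
    max_mm: float = float("nan")
    percent_increase: float = float("nan")
    excluded: bool = False
    reason: str | None = None
    n_samples_dropped: int = 0
    bin_samples: list[list[float]] = field(default_factory=list)


def _sample_valid_mask(samples: list[PupilSample], delta_mm_max: float) -> np.ndarray:
    """Per-sample usability: tracker-valid, on stimulus, physical, no jumps.

    The jump rule compares each sample to the previous usable one and marks
    outliers from blinks or large head movements (|delta| > delta_mm_max).
    """
    n = len(samples)
    ok = np.zeros(n, dtype=bool)
    prev = None
    for i, s in enumerate(samples):
        usable = (s.valid and s.on_stimulus and math.isfinite(s.diameter_mm)
                  and s.diameter_mm > 0)
        if usable and prev is not None and abs(s.diameter_mm - prev) > delta_mm_max:
            usable = False
        if usable:
            prev = s.diameter_mm
        ok[i] = usable
    return ok


def exclusion_check(bin_valid: np.ndarray, max_invalid_run: int = 3) -> tuple[bool, str | None]:
    """Apply the trial-level exclusion rule to per-bin validity flags.

    Excluded if the first (baseline) bin is invalid, or if ``max_invalid_run``
    or more consecutive bins are invalid anywhere in the trial.
    """
    bin_valid = np.asarray(bin_valid, dtype=bool)
    if bin_valid.size == 0:
        return True, "no_valid_data"
    if not bin_valid[0]:
        return True, "baseline_invalid"
    run = 0
    for v in bin_valid:
        run = 0 if v else run + 1
        if run >= max_invalid_run:
            return True, f"gaze_off_{max_invalid_run}_consecutive_bins"
    return False, None


def pupil_response(bin_means: np.ndarray) -> float:
    """Percentage increase: 100 * (max bin mean - first bin mean) / first bin mean.

    The maximum is over all valid bins including the baseline, so the value
    is never negative.
    """
    bin_means = np.asarray(bin_means, dtype=float)
    baseline = bin_means[0]
    max_mm = float(np.nanmax(bin_means))
    return 100.0 * (max_mm - baseline) / baseline


def clean_and_bin(samples: list[PupilSample], subject_id: str = "",
                  bin_ms: int = 300, trial_ms: int = 10_000,
                  delta_mm_max: float = 0.5,
                  bin_invalid_frac: float = 0.5) -> PupilResponse:
    """Clean a pupil trace, average in fixed bins, and compute the response.

    Invalid samples (tracker-flagged, off-stimulus, non-physical, or jumping
    by more than ``delta_mm_max`` mm from the previous usable sample) are
    excluded from bin means; a bin is invalid when more than
    ``bin_invalid_frac`` of its samples are invalid or it has no samples.
    The trailing partial bin is dropped. Subjects failing
    :func:`exclusion_check` get ``excluded=True`` and NaN response fields.
    """
    n_bins = trial_ms // bin_ms
    in_trial = [s for s in samples if 0 <= s.t_ms < n_bins * bin_ms]
    ok = _sample_valid_mask(in_trial, delta_mm_max)
    n_dropped = int(len(in_trial) - ok.sum())

    bin_values: list[list[float]] = [[] for _ in range(n_bins)]
    bin_totals = np.zeros(n_bins, dtype=int)
    for s, usable in zip(in_trial, ok):
        b = s.t_ms // bin_ms
        bin_totals[b] += 1
        if usable:
            bin_values[b].append(s.diameter_mm)

    bin_means = np.full(n_bins, np.nan)
    bin_valid = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        if bin_totals[b] == 0:
            continue
        frac_invalid = 1.0 - len(bin_values[b]) / bin_totals[b]
        if frac_invalid <= bin_invalid_frac and bin_values[b]:
            bin_means[b] = float(np.mean(bin_values[b]))
            bin_valid[b] = True

    resp = PupilResponse(subject_id=subject_id, bin_means=bin_means,
                         bin_valid=bin_valid, n_samples_dropped=n_dropped,
                         bin_samples=bin_values)
    if not bin_valid.any():
        resp.excluded, resp.reason = True, "no_valid_data"
        return resp
    resp.excluded, resp.reason = exclusion_check(bin_valid)
    if not resp.excluded:
        resp.baseline_mm = float(bin_means[0])
        resp.max_mm = float(np.nanmax(bin_means))
        resp.percent_increase = pupil_response(bin_means)
    return resp
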