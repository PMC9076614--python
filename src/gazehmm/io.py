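"""Reading and writing the canonical delimited-text formats.

One CSV dialect for everything an eye-tracker export pipeline produces:
fixations (subject, onset, duration, x, y), pupil traces (subject, time,
diameter, validity, on-stimulus flag) and subject metadata. Column names
are configurable through a mapping so renamed vendor exports can be read
without rewriting files. Fitted models and clusterings serialize to JSON
and to a human-readable report mirroring the prior/transition/ellipse
tables used to present HMM eye-movement patterns.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (ConfigurationError, FixationRecord, FixationSequence,
                    GaussianROI, InputError, PupilSample, SubjectMeta,
                    SubjectHMM)

logger = logging.getLogger(__name__)

__all__ = [
    "FIXATION_COLUMNS", "PUPIL_COLUMNS",
    "read_fixations", "write_fixations",
    "read_pupil", "write_pupil",
    "read_meta", "write_meta",
    "hmm_to_dict", "hmm_from_dict", "save_models", "load_models",
    "write_hmm_report",
]

#: Canonical column names; a dialect config may remap logical -> actual names.
FIXATION_COLUMNS = {"subject": "subject_id", "onset": "onset_ms",
                    "duration": "duration_ms", "x": "x_px", "y": "y_px"}
PUPIL_COLUMNS = {"subject": "subject_id", "t": "t_ms", "diameter": "diameter_mm",
                 "valid": "valid", "on_stimulus": "on_stimulus"}


def _load_table(path, columns: dict, required: list[str], delimiter: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty input file: {path}") from exc
    if df.shape[0] == 0:
        raise InputError(f"no data rows in {path}")
    missing = [columns[k] for k in required if columns[k] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path} is missing mandatory column(s) {missing}; present: {list(df.columns)}")
    return df


def read_fixations(path, columns: dict | None = None,
                   delimiter: str = ",") -> list[FixationSequence]:
    """Read a fixation CSV into one time-ordered sequence per subject.

    Rows with non-finite coordinates are dropped and counted in the log.
    """
    cols = {**FIXATION_COLUMNS, **(columns or {})}
    df = _load_table(path, cols, ["subject", "onset", "duration", "x", "y"], delimiter)
    c = cols
    n_before = len(df)
    xy_ok = np.isfinite(pd.to_numeric(df[c["x"]], errors="coerce")) \
        & np.isfinite(pd.to_numeric(df[c["y"]], errors="coerce"))
    df = df[xy_ok]
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("dropped %d fixation row(s) with non-finite coordinates", n_dropped)
    if df.empty:
        raise InputError(f"no usable fixation rows in {path}")

    sequences = []
    for sid, grp in df.groupby(c["subject"], sort=True):
        grp = grp.sort_values(c["onset"], kind="stable")
        records = [FixationRecord(subject_id=str(sid),
                                  onset_ms=int(r[c["onset"]]),
                                  duration_ms=int(r[c["duration"]]),
                                  x_px=float(r[c["x"]]), y_px=float(r[c["y"]]))
                   for _, r in grp.iterrows()]
        sequences.append(FixationSequence(subject_id=str(sid), records=records))
    return sequences


def write_fixations(sequences: list[FixationSequence], path) -> None:
    rows = [{"subject_id": r.subject_id, "onset_ms": r.onset_ms,
             "duration_ms": r.duration_ms, "x_px": r.x_px, "y_px": r.y_px}
            for seq in sequences for r in seq.records]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_pupil(path, columns: dict | None = None,
               delimiter: str = ",") -> dict[str, list[PupilSample]]:
    """Read a pupil CSV into per-subject sample lists.

    Diameters that are non-finite or <= 0 mm are flagged invalid but the
    samples are retained (the cleaning stage needs the timeline intact).
    Missing ``valid``/``on_stimulus`` columns default to all-true.
    """
    cols = {**PUPIL_COLUMNS, **(columns or {})}
    df = _load_table(path, cols, ["subject", "t", "diameter"], delimiter)
    c = cols
    has_valid = c["valid"] in df.columns
    has_onstim = c["on_stimulus"] in df.columns
    out: dict[str, list[PupilSample]] = {}
    for sid, grp in df.groupby(c["subject"], sort=True):
        grp = grp.sort_values(c["t"], kind="stable")
        samples = []
        for _, r in grp.iterrows():
            d = float(r[c["diameter"]])
            valid = bool(r[c["valid"]]) if has_valid else True
            if not (math.isfinite(d) and d > 0):
                valid = False
            samples.append(PupilSample.from_raw(
                t_ms=int(r[c["t"]]), diameter_mm=d, valid=valid,
                on_stimulus=bool(r[c["on_stimulus"]]) if has_onstim else True))
        out[str(sid)] = samples
    return out


def write_pupil(pupil: dict[str, list[PupilSample]], path) -> None:
    rows = [{"subject_id": sid, "t_ms": s.t_ms, "diameter_mm": s.diameter_mm,
             "valid": s.valid, "on_stimulus": s.on_stimulus}
            for sid, samples in pupil.items() for s in samples]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_meta(path, delimiter: str = ",") -> list[SubjectMeta]:
    df = _load_table(path, {"subject": "subject_id"}, ["subject"], delimiter)
    metas = []
    for _, r in df.iterrows():
        age = r.get("age_group")
        if age is not None and (pd.isna(age) or age == ""):
            age = None
        metas.append(SubjectMeta(subject_id=str(r["subject_id"]),
                                 role=str(r["role"]), gender=str(r["gender"]),
                                 age_group=age if age is None else str(age),
                                 activity=str(r.get("activity", "none"))))
    return metas


def write_meta(meta: list[SubjectMeta], path) -> None:
    rows = [{"subject_id": m.subject_id, "role": m.role, "gender": m.gender,
             "age_group": m.age_group if m.age_group is not None else "",
             "activity": m.activity} for m in meta]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model (de)serialization


def hmm_to_dict(hmm: SubjectHMM) -> dict:
    return {
        "n_states": hmm.n_states,
        "prior": hmm.prior.tolist(),
        "transition": hmm.transition.tolist(),
        "roi_means": [r.mean.tolist() for r in hmm.rois],
        "roi_covs": [r.cov.tolist() for r in hmm.rois],
        "fit_score": hmm.fit_score,
        "n_fixations": hmm.n_fixations,
    }


def hmm_from_dict(d: dict) -> SubjectHMM:
    rois = [GaussianROI(m, c) for m, c in zip(d["roi_means"], d["roi_covs"])]
    return SubjectHMM(prior=np.array(d["prior"]),
                      transition=np.array(d["transition"]), rois=rois,
                      fit_score=float(d.get("fit_score", float("nan"))),
                      n_fixations=int(d.get("n_fixations", 0)))


def save_models(models: dict[str, SubjectHMM], path) -> None:
    with open(path, "w") as fh:
        json.dump({sid: hmm_to_dict(m) for sid, m in models.items()},
                  fh, indent=1, sort_keys=True)


def load_models(path) -> dict[str, SubjectHMM]:
    with open(path) as fh:
        raw = json.load(fh)
    return {sid: hmm_from_dict(d) for sid, d in raw.items()}


# ---------------------------------------------------------------------------
# human-readable report


def _format_hmm(hmm: SubjectHMM, title: str) -> list[str]:
    k = hmm.n_states
    names = [f"ROI{i + 1}" for i in range(k)]
    lines = [title, "-" * len(title)]
    lines.append("Priors:   " + "  ".join(
        f"{n}={p:.2f}" for n, p in zip(names, hmm.prior)))
    lines.append("Transition matrix (rows: from, columns: to):")
    lines.append("        " + "".join(f"{n:>8}" for n in names))
    for i in range(k):
        lines.append(f"{names[i]:>8}" + "".join(
            f"{hmm.transition[i, j]:8.2f}" for j in range(k)))
    lines.append("ROIs (2D Gaussians; ellipse = 2-SD contour):")
    for i, roi in enumerate(hmm.rois):
        center, a, b, theta = roi.ellipse_2sd()
        lines.append(
            f"  {names[i]}: mean=({center[0]:.2f}, {center[1]:.2f})  "
            f"cov=[[{roi.cov[0, 0]:.2f}, {roi.cov[0, 1]:.2f}], "
            f"[{roi.cov[1, 0]:.2f}, {roi.cov[1, 1]:.2f}]]  "
            f"ellipse: a={a:.2f} b={b:.2f} theta={math.degrees(theta):.2f} deg")
    return lines


def write_hmm_report(model_or_clustering, path) -> None:
    """Write a structured text report of an HMM or a pattern clustering.

    Lists priors, the transition matrix (rows labelled by ROI), ROI means
    and covariances, and 2-SD ellipse parameters; numbers rounded to two
    decimals, the precision at which such tables are customarily presented.
    """
    from .clustering import PatternClustering

    lines: list[str] = []
    if isinstance(model_or_clustering, SubjectHMM):
        lines += _format_hmm(model_or_clustering, "Hidden Markov model")
    elif isinstance(model_or_clustering, PatternClustering):
        cl = model_or_clustering
        for c, rep in enumerate(cl.representatives):
            name = f"Pattern {c + 1}" + (" (explorative)" if c == 0 and cl.n_clusters == 2
                                         else " (focused)" if c == 1 and cl.n_clusters == 2
                                         else "")
            lines += _format_hmm(rep, f"Representative model — {name}")
            lines.append("")
        lines.append("Subject assignments:")
        for i, sid in enumerate(cl.subject_ids):
            ef = f"  E-F={cl.ef[i]:+.2f}" if cl.ef is not None else ""
            lines.append(f"  {sid}: Pattern {int(cl.assignment[i]) + 1}{ef}")
    else:
        raise ConfigurationError(
            f"cannot report object of type {type(model_or_clustering).__name__}")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write report to {path}: {exc}") from exc
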