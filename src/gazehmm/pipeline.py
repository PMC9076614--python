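"""End-to-end analysis pipeline.

Orchestrates the full chain on a cohort (synthetic or loaded from the
canonical CSVs): per-subject HMM fitting, clustering into representative
patterns with E-F scale and overall entropy, the fixed-ROI variant with
gaze-preference tests against 50%, pupillary responses, and the group
comparisons (pattern x gender x age x activity). Emits a machine-readable
results bundle plus a human-readable report; everything is deterministic
under a fixed seed and config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as gio
from .clustering import cluster_hmms, overall_entropy
from .config import DEFAULT_CONFIG, merge_config
from .fixedroi import FixedROISet, FixedROISubjectResult, cluster_fixed_roi, default_tooth_rois
from .hmm import FitConfig, fit_subject_hmm
from .pupil import clean_and_bin
from .stats import (fixation_heatmap, one_sample_t, one_way_anova, pearson_r,
                    two_sample_t)
from .synthetic import CohortSpec, generate_cohort
from .types import ConfigurationError, InputError, StimulusLayout

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _safe(fn, *args, **kwargs):
    """Run a statistical comparison, returning None when a group is too small."""
    try:
        return fn(*args, **kwargs).as_dict()
    except InputError as exc:
        logger.info("comparison skipped: %s", exc)
        return None


def _group_comparisons(values: dict[str, float], meta_by_id: dict) -> dict:
    """Pattern-agnostic gender / activity / age comparisons of one measure."""
    def vals(pred):
        return [v for sid, v in values.items()
                if sid in meta_by_id and pred(meta_by_id[sid]) and np.isfinite(v)]

    by_age = [vals(lambda m, a=a: m.age_group == a)
              for a in ("2.6-3.5", "3.6-4.5", "4.6-5.5")]
    out = {
        "gender": _safe(two_sample_t, vals(lambda m: m.gender == "male"),
                        vals(lambda m: m.gender == "female"), "pooled"),
        "activity": _safe(two_sample_t, vals(lambda m: m.activity == "complete"),
                          vals(lambda m: m.activity == "incomplete"), "pooled"),
    }
    if all(len(g) >= 2 for g in by_age):
        out["age"] = _safe(one_way_anova, by_age)
    else:
        out["age"] = None
    return out


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run the full analysis and return the results bundle.

    ``config`` follows :data:`gazehmm.config.DEFAULT_CONFIG`; when
    ``out_dir`` is given, the bundle, tables, the generated input CSVs and a
    text report are written there.
    """
    cfg = merge_config(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    layout = StimulusLayout()
    out = Path(out_dir) if out_dir is not None else None

    # --- inputs -----------------------------------------------------------
    if cfg.get("inputs"):
        paths = cfg["inputs"]
        sequences = gio.read_fixations(paths["fixations"])
        pupil_traces = gio.read_pupil(paths["pupil"])
        meta = gio.read_meta(paths["meta"])
        truth = None
    else:
        cohort_cfg = dict(cfg["cohort"])
        spec = CohortSpec(seed=seed, layout=layout, **cohort_cfg)
        cohort = generate_cohort(spec, out_dir=(out / "inputs") if out else None)
        sequences, pupil_traces, meta, truth = (cohort.sequences, cohort.pupil,
                                                cohort.meta, cohort.truth)
    if not sequences:
        raise ConfigurationError("empty cohort: nothing to analyse")
    meta_by_id = {m.subject_id: m for m in meta}
    subject_ids = [s.subject_id for s in sequences]

    # --- per-subject HMMs (data-driven ROIs) ------------------------------
    fit_cfg = cfg["fit"]
    models = {}
    for i, seq in enumerate(sequences):
        models[seq.subject_id] = fit_subject_hmm(
            seq, k_range=tuple(fit_cfg["k_range"]),
            n_restarts=int(fit_cfg["n_restarts"]), seed=seed + 1000 + i)
    entropy = {sid: overall_entropy(m) for sid, m in models.items()}

    # --- clustering into representative patterns --------------------------
    cl_cfg = cfg["cluster"]
    rep_cfg = FitConfig(k_range=tuple(fit_cfg["k_range"]),
                        n_restarts=int(cl_cfg["rep_n_restarts"]))
    clustering = cluster_hmms(
        [models[sid] for sid in subject_ids], sequences,
        n_clusters=int(cl_cfg["n_clusters"]), n_init=int(cl_cfg["n_init"]),
        seed=seed + 2000, layout=layout, rep_fit_config=rep_cfg)

    # --- fixed-ROI variant -------------------------------------------------
    fr_cfg = cfg["fixed_roi"]
    if fr_cfg.get("ellipses"):
        roi_set = FixedROISet.from_ellipses(fr_cfg["ellipses"])
    else:
        roi_set = default_tooth_rois(layout)
    fr_results = [FixedROISubjectResult.from_sequence(s, roi_set) for s in sequences]
    fr_clustering = cluster_fixed_roi(fr_results,
                                      n_clusters=int(cl_cfg["n_clusters"]),
                                      n_init=int(cl_cfg["n_init"]), seed=seed + 3000)
    gaze_pref = {r.subject_id: r.gaze_preference for r in fr_results}

    # --- pupillometry ------------------------------------------------------
    pp = cfg["pupil"]
    pupil_resp = {
        sid: clean_and_bin(samples, subject_id=sid, bin_ms=int(pp["bin_ms"]),
                           trial_ms=int(pp["trial_ms"]),
                           delta_mm_max=float(pp["delta_mm_max"]),
                           bin_invalid_frac=float(pp["bin_invalid_frac"]))
        for sid, samples in pupil_traces.items()}

    # --- group statistics ---------------------------------------------------
    ef = {sid: float(clustering.ef[i]) for i, sid in enumerate(subject_ids)} \
        if clustering.ef is not None else {}
    assign = {sid: int(clustering.assignment[i]) for i, sid in enumerate(subject_ids)}
    fr_assign = {sid: int(fr_clustering.assignment[i]) for i, sid in enumerate(subject_ids)}

    def of_pattern(values: dict, assignment: dict, pattern: int):
        return [values[sid] for sid in subject_ids
                if assignment[sid] == pattern and sid in values and np.isfinite(values[sid])]

    pupil_pct = {sid: r.percent_increase for sid, r in pupil_resp.items()
                 if not r.excluded}
    stats_block = {
        "ef_scale": _group_comparisons(ef, meta_by_id) if ef else None,
        "entropy": _group_comparisons(entropy, meta_by_id),
        "entropy_by_pattern": _safe(two_sample_t, of_pattern(entropy, assign, 0),
                                    of_pattern(entropy, assign, 1), "pooled"),
        "entropy_vs_ef": _safe(pearson_r, [entropy[sid] for sid in subject_ids],
                               [ef[sid] for sid in subject_ids]) if ef else None,
        "gaze_preference": {
            "by_pattern": _safe(two_sample_t, of_pattern(gaze_pref, fr_assign, 0),
                                of_pattern(gaze_pref, fr_assign, 1), "pooled"),
            "explorative_vs_50": _safe(one_sample_t,
                                       of_pattern(gaze_pref, fr_assign, 0), 0.5),
            "focused_vs_50": _safe(one_sample_t,
                                   of_pattern(gaze_pref, fr_assign, 1), 0.5),
            **_group_comparisons(gaze_pref, meta_by_id),
        },
        "pupil": {
            "by_pattern": _safe(two_sample_t, of_pattern(pupil_pct, assign, 0),
                                of_pattern(pupil_pct, assign, 1), "welch"),
            "by_pattern_male": _safe(
                two_sample_t,
                [v for sid, v in pupil_pct.items()
                 if assign.get(sid) == 0 and meta_by_id[sid].gender == "male"],
                [v for sid, v in pupil_pct.items()
                 if assign.get(sid) == 1 and meta_by_id[sid].gender == "male"], "welch"),
            "by_pattern_female": _safe(
                two_sample_t,
                [v for sid, v in pupil_pct.items()
                 if assign.get(sid) == 0 and meta_by_id[sid].gender == "female"],
                [v for sid, v in pupil_pct.items()
                 if assign.get(sid) == 1 and meta_by_id[sid].gender == "female"], "welch"),
        },
    }

    # --- heatmap ------------------------------------------------------------
    hm_cfg = cfg["heatmap"]
    density, _, _ = fixation_heatmap(sequences, layout,
                                     bandwidth_px=float(hm_cfg["bandwidth_px"]),
                                     grid_shape=tuple(hm_cfg["grid"]))

    bundle = {
        "seed": seed,
        "n_subjects": len(subject_ids),
        "per_subject": {
            sid: {
                "role": meta_by_id[sid].role if sid in meta_by_id else None,
                "n_states": models[sid].n_states,
                "pattern": assign[sid] + 1,
                "ef_scale": ef.get(sid),
                "entropy": entropy[sid],
                "pattern_fixed_roi": fr_assign[sid] + 1,
                "ef_scale_fixed_roi": (float(fr_clustering.ef[subject_ids.index(sid)])
                                       if fr_clustering.ef is not None else None),
                "gaze_preference": gaze_pref[sid],
                "pupil_percent_increase": (None if pupil_resp[sid].excluded
                                           else pupil_resp[sid].percent_increase),
                "pupil_excluded": pupil_resp[sid].excluded,
                "pupil_exclusion_reason": pupil_resp[sid].reason,
            } for sid in subject_ids},
        "patterns": {
            "data_driven": {
                "n_per_pattern": [int(np.sum(clustering.assignment == c))
                                  for c in range(clustering.n_clusters)],
                "switch_prob": clustering.switch_prob,
                "representatives": [gio.hmm_to_dict(r) for r in clustering.representatives],
            },
            "fixed_roi": {
                "n_per_pattern": [int(np.sum(fr_clustering.assignment == c))
                                  for c in range(len(fr_clustering.rep_priors))],
                "rep_priors": [p.tolist() for p in fr_clustering.rep_priors],
                "rep_transitions": [t.tolist() for t in fr_clustering.rep_transitions],
            },
        },
        "stats": stats_block,
        "truth_available": truth is not None,
    }

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "results.json", "w") as fh:
            json.dump(bundle, fh, indent=1, sort_keys=True)
        gio.save_models(models, out / "models.json")
        gio.write_hmm_report(clustering, out / "patterns_report.txt")
        np.savetxt(out / "heatmap.csv", density, delimiter=",", fmt="%.8e")
        _write_tables(out, bundle)
    return bundle


def _write_tables(out: Path, bundle: dict) -> None:
    import pandas as pd
    rows = [{"subject_id": sid, **vals} for sid, vals in bundle["per_subject"].items()]
    pd.DataFrame(rows).to_csv(out / "per_subject.csv", index=False,
                              float_format="%.6f")
    flat = []

    def walk(prefix, node):
        if node is None:
            return
        if isinstance(node, dict) and "statistic" in node:
            flat.append({"comparison": prefix, **{k: (json.dumps(v) if isinstance(v, list) else v)
                                                  for k, v in node.items()}})
        elif isinstance(node, dict):
            for k, v in node.items():
                walk(f"{prefix}.{k}" if prefix else k, v)

    walk("", bundle["stats"])
    pd.DataFrame(flat).to_csv(out / "comparisons.csv", index=False,
                              float_format="%.6f")
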