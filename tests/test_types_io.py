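"""Domain types, CSV dialect round trips, and the HMM text report."""

from __future__ import annotations

import numpy as np
import pytest

import gazehmm as g
from gazehmm import io as gio


class TestTypes:
    def test_fixation_record_validation(self):
        with pytest.raises(g.InputError):
            g.FixationRecord("s1", onset_ms=-1, duration_ms=100, x_px=0, y_px=0)
        with pytest.raises(g.InputError):
            g.FixationRecord("s1", onset_ms=0, duration_ms=0, x_px=0, y_px=0)
        with pytest.raises(g.InputError):
            g.FixationRecord("s1", onset_ms=0, duration_ms=100, x_px=np.nan, y_px=0)

    def test_sequence_requires_ordered_onsets(self):
        r1 = g.FixationRecord("s1", 500, 100, 1.0, 2.0)
        r2 = g.FixationRecord("s1", 100, 100, 1.0, 2.0)
        with pytest.raises(g.InputError):
            g.FixationSequence("s1", [r1, r2])

    def test_pupil_sample_demotes_nonphysical_diameters(self):
        s = g.PupilSample.from_raw(0, 0.0, valid=True)
        assert not s.valid
        s = g.PupilSample.from_raw(0, float("nan"), valid=True)
        assert not s.valid

    def test_subject_meta_role_invariants(self):
        with pytest.raises(g.ConfigurationError):
            g.SubjectMeta("s1", role="child", gender="male")  # child needs age group
        with pytest.raises(g.ConfigurationError):
            g.SubjectMeta("e1", role="educator", gender="female", age_group="2.6-3.5")
        g.SubjectMeta("e1", role="educator", gender="female")  # valid

    def test_layout_regions_must_be_disjoint(self):
        with pytest.raises(g.ConfigurationError):
            g.StimulusLayout(left_image_region=g.Rect(0, 0, 1000, 500),
                             right_image_region=g.Rect(900, 0, 1900, 500))

    def test_hmm_stochasticity_enforced(self):
        roi = g.GaussianROI([0, 0], np.eye(2))
        with pytest.raises(g.ConfigurationError):
            g.SubjectHMM(prior=[0.5, 0.4], transition=np.eye(2), rois=[roi, roi])
        with pytest.raises(g.ConfigurationError):
            g.SubjectHMM(prior=[0.5, 0.5], transition=[[0.9, 0.0], [0.5, 0.5]],
                         rois=[roi, roi])

    def test_covariance_must_be_positive_definite(self):
        with pytest.raises(g.ConfigurationError):
            g.GaussianROI([0, 0], [[1.0, 2.0], [2.0, 1.0]])


class TestFixationIO:
    def test_well_formed_single_subject(self, tmp_path):
        p = tmp_path / "fix.csv"
        p.write_text("subject_id,onset_ms,duration_ms,x_px,y_px\n"
                     "s1,0,200,10.0,20.0\ns1,200,150,11.0,21.0\ns1,350,300,12.0,22.0\n")
        seqs = gio.read_fixations(p)
        assert len(seqs) == 1 and len(seqs[0]) == 3
        assert seqs[0].records[2].x_px == 12.0

    def test_nan_coordinate_rows_dropped_and_logged(self, tmp_path, caplog):
        p = tmp_path / "fix.csv"
        rows = ["s1,%d,100,%s,5.0" % (i * 100, "nan" if i == 2 else "1.0")
                for i in range(5)]
        p.write_text("subject_id,onset_ms,duration_ms,x_px,y_px\n" + "\n".join(rows))
        with caplog.at_level("WARNING"):
            seqs = gio.read_fixations(p)
        assert len(seqs[0]) == 4
        assert any("dropped 1" in m for m in caplog.messages)

    def test_interleaved_subjects_sorted_within_subject(self, tmp_path):
        p = tmp_path / "fix.csv"
        p.write_text("subject_id,onset_ms,duration_ms,x_px,y_px\n"
                     "b,400,100,1,1\na,0,100,2,2\nb,0,100,3,3\na,300,100,4,4\n")
        seqs = gio.read_fixations(p)
        assert [s.subject_id for s in seqs] == ["a", "b"]
        for s in seqs:
            onsets = [r.onset_ms for r in s.records]
            assert onsets == sorted(onsets)

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "fix.csv"
        p.write_text("subject_id,onset_ms,x_px,y_px\ns1,0,1,2\n")
        with pytest.raises(g.ConfigurationError):
            gio.read_fixations(p)

    def test_empty_file_is_input_error(self, tmp_path):
        p = tmp_path / "fix.csv"
        p.write_text("")
        with pytest.raises(g.InputError):
            gio.read_fixations(p)

    def test_column_remapping_dialect(self, tmp_path):
        p = tmp_path / "fix.csv"
        p.write_text("Participant,Start,Dur,GazeX,GazeY\ns1,0,100,5,6\n")
        seqs = gio.read_fixations(p, columns={"subject": "Participant",
                                              "onset": "Start", "duration": "Dur",
                                              "x": "GazeX", "y": "GazeY"})
        assert seqs[0].records[0].x_px == 5.0

    def test_round_trip_identity(self, tmp_path, small_cohort):
        p = tmp_path / "fix.csv"
        gio.write_fixations(small_cohort.sequences, p)
        back = gio.read_fixations(p)
        assert len(back) == len(small_cohort.sequences)
        orig = {s.subject_id: s for s in small_cohort.sequences}
        total_in = sum(len(s) for s in small_cohort.sequences)
        total_out = sum(len(s) for s in back)
        assert total_in == total_out  # dropped (0) + retained == input rows
        for s in back:
            assert np.allclose(s.xy, orig[s.subject_id].xy, atol=1e-6)


class TestPupilIO:
    def test_zero_diameter_flagged_invalid_but_retained(self, tmp_path):
        p = tmp_path / "pupil.csv"
        p.write_text("subject_id,t_ms,diameter_mm\ns1,0,3.0\ns1,17,0.0\ns1,33,3.1\n")
        traces = gio.read_pupil(p)
        assert len(traces["s1"]) == 3
        assert [s.valid for s in traces["s1"]] == [True, False, True]

    def test_all_valid_trace(self, tmp_path):
        p = tmp_path / "pupil.csv"
        p.write_text("subject_id,t_ms,diameter_mm\ns1,0,3.0\ns1,17,3.1\n")
        assert all(s.valid for s in gio.read_pupil(p)["s1"])

    def test_round_trip_identity(self, tmp_path, small_cohort):
        p = tmp_path / "pupil.csv"
        gio.write_pupil(small_cohort.pupil, p)
        back = gio.read_pupil(p)
        assert set(back) == set(small_cohort.pupil)
        for sid, samples in back.items():
            orig = small_cohort.pupil[sid]
            assert len(samples) == len(orig)
            assert all(a.valid == b.valid and a.t_ms == b.t_ms
                       and a.diameter_mm == pytest.approx(b.diameter_mm, abs=1e-6)
                       for a, b in zip(samples, orig))


class TestMetaIO:
    def test_round_trip(self, tmp_path, small_cohort):
        p = tmp_path / "meta.csv"
        gio.write_meta(small_cohort.meta, p)
        back = gio.read_meta(p)
        assert back == small_cohort.meta


class TestModelSerialization:
    def test_hmm_json_round_trip(self, toy_hmm, tmp_path):
        p = tmp_path / "models.json"
        gio.save_models({"s1": toy_hmm}, p)
        back = gio.load_models(p)["s1"]
        assert np.allclose(back.prior, toy_hmm.prior)
        assert np.allclose(back.transition, toy_hmm.transition)
        assert np.allclose(back.rois[1].cov, toy_hmm.rois[1].cov)


class TestHMMReport:
    def test_one_state_model_prints_unit_probabilities(self, tmp_path):
        hmm = g.SubjectHMM(prior=[1.0], transition=[[1.0]],
                           rois=[g.GaussianROI([100, 200], 400 * np.eye(2))])
        p = tmp_path / "report.txt"
        gio.write_hmm_report(hmm, p)
        text = p.read_text()
        assert "ROI1=1.00" in text
        assert "1.00" in text.splitlines()[5]  # transition row

    def test_uniform_two_state_prints_halves(self, tmp_path):
        roi = g.GaussianROI([0, 0], np.eye(2) * 100)
        hmm = g.SubjectHMM(prior=[0.5, 0.5], transition=np.full((2, 2), 0.5),
                           rois=[roi, roi])
        p = tmp_path / "report.txt"
        gio.write_hmm_report(hmm, p)
        assert p.read_text().count("0.50") >= 6  # priors + all transition cells

    def test_clustering_report_lists_representatives_and_assignments(
            self, tmp_path, layout):
        spec = g.CohortSpec(n_explorative=2, n_focused=1, seed=2)
        cohort = g.generate_cohort(spec)
        models = [g.fit_subject_hmm(s, k_range=(1, 2), n_restarts=2, seed=i)
                  for i, s in enumerate(cohort.sequences)]
        cl = g.cluster_hmms(models, cohort.sequences, n_clusters=2, n_init=1,
                            seed=0, layout=layout,
                            rep_fit_config=g.FitConfig(k_range=(1, 2), n_restarts=2))
        p = tmp_path / "report.txt"
        gio.write_hmm_report(cl, p)
        text = p.read_text()
        assert text.count("Representative model") == 2
        for sid in cl.subject_ids:
            assert sid in text

    def test_unwritable_path_raises(self, toy_hmm, tmp_path):
        with pytest.raises(OSError):
            gio.write_hmm_report(toy_hmm, tmp_path / "missing_dir" / "r.txt")
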