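"""The 27 behavioral features and the 40-column baseline table."""

import numpy as np
import pandas as pd
import pytest

import gazecog as gc
from gazecog.events import EventKind, GazeEvent
from gazecog.features import (FEATURE_NAMES, average_eyes, fet_features,
                              mct_features, prt_features, prt_trial_eye,
                              st_features, vsst_features)
from gazecog.preprocess import MergedGaze

FS = 120.0


def fixation(onset, dur, centroid):
    n0, n1 = int(onset * FS), int((onset + dur) * FS)
    return GazeEvent(kind=EventKind.FIXATION, onset=onset, offset=onset + dur,
                     sample_range=(n0, n1), centroid=np.asarray(centroid))


def saccade(onset, dur, amp=10.0):
    n0, n1 = int(onset * FS), int((onset + dur) * FS)
    return GazeEvent(kind=EventKind.SACCADE, onset=onset, offset=onset + dur,
                     sample_range=(n0, n1), amplitude=amp,
                     mean_velocity=amp / dur, peak_velocity=1.9 * amp / dur,
                     latency=onset)


def merged_at(point, n):
    endpoint = np.tile(point, (n, 1))
    return MergedGaze(endpoint=endpoint, cyclopean_origin=np.zeros((n, 3)),
                      angular_velocity=np.zeros(n),
                      timestamps=np.arange(n) / FS)


class _FakeSeg:
    def __init__(self, dur):
        self.duration = dur
        self.n_samples = int(dur * FS)
        self.timestamps = np.arange(self.n_samples) / FS


class TestVSST:
    ROI = gc.ROISpec(center=np.array([0.0, 0.0, 1.5]), radius=0.15)

    def test_single_fixation_inside_roi(self):
        seg = _FakeSeg(8.0)
        gaze = merged_at([0, 0, 1.5], seg.n_samples)
        events = [fixation(0.0, 8.0, [0, 0, 1.5])]
        out = vsst_features(seg, events, gaze, self.ROI)
        assert out["vsst_fix_roi"] == pytest.approx(100.0)
        assert out["vsst_tf_roi"] == pytest.approx(0.0)
        assert out["vsst_tm_roi"] == pytest.approx(8.0)

    def test_two_equal_fixations_one_inside(self):
        seg = _FakeSeg(8.0)
        gaze = merged_at([0, 0, 1.5], seg.n_samples)
        events = [fixation(0.0, 2.0, [0.5, 0, 1.5]),
                  fixation(2.0, 2.0, [0, 0, 1.5])]
        out = vsst_features(seg, events, gaze, self.ROI)
        assert out["vsst_fix_roi"] == pytest.approx(50.0)

    def test_never_in_roi_caps_first_fixation_time(self):
        seg = _FakeSeg(8.0)
        gaze = merged_at([0.5, 0, 1.5], seg.n_samples)
        events = [fixation(0.0, 8.0, [0.5, 0, 1.5])]
        out = vsst_features(seg, events, gaze, self.ROI)
        assert out["vsst_tf_roi"] == pytest.approx(8.0)
        assert out["vsst_t_roi"] == 0.0

    def test_no_fixations_fallbacks(self):
        seg = _FakeSeg(8.0)
        gaze = merged_at([0, 0, 1.5], seg.n_samples)
        out = vsst_features(seg, [], gaze, self.ROI)
        assert out["vsst_fix_roi"] == 0.0
        assert out["vsst_tf_roi"] == pytest.approx(8.0)
        assert out["vsst_tm_roi"] == 0.0


class TestPupilBaseline:
    def test_constant_series(self):
        assert gc.pupil_baseline(np.full(10, 4.0)).mean == pytest.approx(4.0)

    def test_two_samples_unrolled(self):
        assert gc.pupil_baseline(np.array([2.0, 4.0])).mean == pytest.approx(3.0)

    def test_recursion_equals_arithmetic_mean(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(3, 5, size=481)
        assert gc.pupil_baseline(x).mean == pytest.approx(x.mean(), abs=1e-12)

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            gc.pupil_baseline(np.array([]))


class TestPRT:
    def test_constant_pupil_no_response(self):
        base = gc.pupil_baseline(np.full(480, 4.0))
        out = prt_trial_eye(np.full(120, 4.0), base)
        assert out["rd"] == 0.0 and out["vc_max"] == 0.0 and out["ac_max"] == 0.0
        assert out["t1"] == pytest.approx(1.0)

    def test_linear_ramp_kinematics(self):
        # 1 mm drop over 0.5 s then hold: Rd = 1, VCmax = 2 mm/s, T3 = 0.5 s
        pre = np.full(480, 4.0) + 1e-4 * np.sin(np.arange(480))
        base = gc.pupil_baseline(pre)
        n_ramp = int(0.5 * FS)
        window = np.concatenate([[4.0],
                                 4.0 - np.arange(1, n_ramp + 1) / n_ramp,
                                 np.full(int(0.5 * FS), 3.0)])
        out = prt_trial_eye(window, base)
        assert out["rd"] == pytest.approx(1.0, abs=1e-9)
        assert out["vc_max"] == pytest.approx(2.0, rel=0.02)
        assert out["t3"] == pytest.approx(0.5, abs=0.02)

    def test_trial_mean(self):
        t1 = {"ac_max": 1, "vc_max": 1, "rd": 0.8, "t1": 0.2, "t2": 0.1,
              "t3": 0.3}
        t2 = {"ac_max": 3, "vc_max": 2, "rd": 1.0, "t1": 0.3, "t2": 0.2,
              "t3": 0.5}
        out = prt_features([t1, t2])
        assert out["prt_rd"] == pytest.approx(0.9)
        assert out["prt_t1"] == pytest.approx(0.25)

    def test_eye_average(self):
        l = {"rd": 1.0}
        r = {"rd": 0.5}
        assert average_eyes(l, r)["rd"] == pytest.approx(0.75)


class TestST:
    def test_constant_latencies(self):
        trials = [[saccade(0.2, 0.05)] for _ in range(6)]
        out = st_features(trials, ["ps"] * 6)
        assert out["st_ls_ps"] == pytest.approx(0.2)

    def test_peak_velocity_is_global_max(self):
        evs = [saccade(0.2, 0.05), saccade(0.3, 0.05), saccade(0.25, 0.05)]
        for e, pv in zip(evs, (150.0, 300.0, 250.0)):
            e.peak_velocity = pv
        out = st_features([[e] for e in evs], ["as"] * 3)
        assert out["st_vmax_as"] == pytest.approx(300.0)

    def test_amplitude_mean(self):
        evs = [saccade(0.2, 0.05, amp=a) for a in (8.0, 10.0, 12.0)]
        out = st_features([[e] for e in evs], ["ps"] * 3)
        assert out["st_as_ps"] == pytest.approx(10.0)

    def test_condition_without_saccades_is_missing(self):
        out = st_features([[]], ["as"])
        assert np.isnan(out["st_ls_as"])
        assert np.isnan(out["st_ls_ps"])


class TestFET:
    def test_never_crossing_fallback(self):
        trial = gc.ExpressionTrial(val=np.zeros(600))
        i, t, l = gc.fet_trial(trial)
        assert (i, t) == (0.0, 0.0)
        assert l == pytest.approx(5.0)

    def test_constant_half_intensity(self):
        trial = gc.ExpressionTrial(val=np.full(600, 0.5))
        i, t, l = gc.fet_trial(trial)
        assert i == pytest.approx(0.5)
        assert t == pytest.approx(5.0)
        assert l == pytest.approx(0.0)

    def test_delayed_activation_hand_count(self):
        n_off = int(1.2 * FS)
        val = np.concatenate([np.zeros(n_off), np.full(600 - n_off, 0.8)])
        i, t, l = gc.fet_trial(gc.ExpressionTrial(val=val))
        assert l == pytest.approx(1.2, abs=1 / FS)
        assert t == pytest.approx(3.8, abs=1 / FS)

    def test_threshold_time_conservation(self):
        rng = np.random.default_rng(3)
        val = rng.uniform(0, 0.4, size=600)
        trial = gc.ExpressionTrial(val=val)
        _, t, _ = gc.fet_trial(trial)
        below = trial.dt * np.sum(val <= trial.theta)
        assert t + below == pytest.approx(600 * trial.dt)

    def test_invariant_to_subthreshold_tail(self):
        val = np.concatenate([np.zeros(120), np.full(480, 0.6)])
        with_tail = np.concatenate([val, np.full(100, 0.05)])
        assert gc.fet_trial(gc.ExpressionTrial(val=val)) == \
            gc.fet_trial(gc.ExpressionTrial(val=with_tail))

    def test_emotion_averaging(self):
        happy = [gc.ExpressionTrial(val=np.full(600, 0.5))]
        sad = [gc.ExpressionTrial(val=np.zeros(600))]
        out = fet_features(happy, sad)
        assert out["fet_i_happy"] == pytest.approx(0.5)
        assert out["fet_l_sad"] == pytest.approx(5.0)


class TestMCT:
    def test_trial_averaging(self):
        out = mct_features([(100.0, 1.0), (50.0, 2.0)])
        assert out["mct_aa"] == pytest.approx(75.0)
        assert out["mct_lc"] == pytest.approx(1.5)


class TestExtractAll:
    def test_complete_session_27_finite(self, one_subject):
        rec, truth = one_subject
        fv = gc.extract_all(rec, truth.rois)
        arr = fv.to_array()
        assert arr.shape == (27,)
        assert np.isfinite(arr).all()
        assert fv.missing == []

    def test_missing_fet_flags_six_features(self, one_subject):
        rec, truth = one_subject
        cut = rec.copy()
        cut.task_label = cut.task_label.copy()
        cut.task_label[cut.task_label == "FET"] = "NONE"
        fv = gc.extract_all(cut, truth.rois)
        assert len(fv.missing) == 6
        assert all(m.startswith("fet_") for m in fv.missing)

    def test_canonical_order_stable(self, one_subject):
        rec, truth = one_subject
        a = gc.extract_all(rec, truth.rois).to_array()
        b = gc.extract_all(rec, truth.rois).to_array()
        np.testing.assert_array_equal(a, b)
        assert FEATURE_NAMES[0] == "vsst_fix_roi"
        assert FEATURE_NAMES[-1] == "fet_l_sad"


class TestBaselineTable:
    def test_forty_columns(self, tiny_cohort):
        fvs = {r.subject_id: gc.extract_all(r, t.rois)
               for r, t in zip(tiny_cohort.sessions, tiny_cohort.truth)}
        covs = {c.subject_id: c for c in tiny_cohort.covariates}
        table = gc.assemble_baseline_table(fvs, covs)
        assert table.shape == (4, 41)  # 40 features + label
        assert "label" in table.columns

    def test_mismatched_subjects_rejected(self, tiny_cohort):
        fvs = {r.subject_id: gc.extract_all(r, t.rois)
               for r, t in zip(tiny_cohort.sessions[:1], tiny_cohort.truth[:1])}
        covs = {c.subject_id: c for c in tiny_cohort.covariates}
        with pytest.raises(ValueError):
            gc.assemble_baseline_table(fvs, covs)

    def test_median_impute_uses_training_split_only(self):
        df = pd.DataFrame({
            "f": [1.0, 3.0, np.nan, 100.0],
            "label": [0, 1, 0, 1],
        }, index=list("abcd"))
        out = gc.median_impute(df, pd.Index(["a", "b"]))
        assert out.loc["c", "f"] == pytest.approx(2.0)  # median of train only
        assert out.loc["d", "f"] == 100.0
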