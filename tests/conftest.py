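import numpy as np
import pytest

import gazecog as gc


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two subjects per group, default effect sizes, fixed seed."""
    return gc.generate_cohort(gc.CohortConfig(n_hc=2, n_cd=2, seed=11))


@pytest.fixture(scope="session")
def one_subject(tiny_cohort):
    return tiny_cohort.sessions[0], tiny_cohort.truth[0]


def make_recording(n=600, fs=120.0, task="VSST", trial=0, pupil=4.0,
                   gaze=None, fbs=None, openness=None, subject_id="T001"):
    """Hand-built minimal recording for unit tests."""
    t = np.arange(n) / fs
    gaze = np.tile([0.0, 0.0, 1.5], (n, 1)) if gaze is None else gaze
    fbs = np.zeros((n, 6)) if fbs is None else fbs
    op = np.ones(n) if openness is None else openness
    return gc.SessionRecording(
        subject_id=subject_id, group=gc.Group.HC, timestamps=t,
        eye_origin_left=np.tile([-0.032, 0, 0], (n, 1)),
        eye_origin_right=np.tile([0.032, 0, 0], (n, 1)),
        gaze_point=np.asarray(gaze, dtype=float),
        pupil_left=np.full(n, float(pupil)),
        pupil_right=np.full(n, float(pupil)),
        openness_left=np.asarray(op, dtype=float),
        openness_right=np.asarray(op, dtype=float),
        fbs=np.asarray(fbs, dtype=float),
        task_label=np.full(n, task, dtype=object).astype(str),
        trial_index=np.full(n, trial, dtype=int),
    )
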