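"""The 27 behavioral features across the five task paradigms.

Visual search (VSST): ROI fixation percentage, time to first ROI fixation,
total ROI dwell, median saccade amplitude, median ROI fixation duration.
Memory calculation (MCT): attention allocation and calculation latency.
Pupillary light reflex (PRT): constriction acceleration/velocity peaks,
diameter range, and the three latency components. Saccade task (ST):
latency, mean/peak velocity and amplitude for pro- and anti-saccades.
Facial expression (FET): intensity, supra-threshold duration and onset
latency for happy and sad.

ROI membership is a geometric sphere test on 3-D gaze endpoints (standing in
for engine-side ray casting); the radius is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventKind, GazeEvent, IVDTConfig, filter_anticipatory, \
    ivdt_segment, saccade_metrics
from .preprocess import MergedGaze, PreprocessConfig, merge_gaze, \
    preprocess_recording
from .session import Phase, SessionRecording, SubjectCovariates, Task, \
    TaskSegment, SAMPLING_RATE, segment_tasks

#: Canonical ordering of the 27 features (task blocks in paradigm order).
FEATURE_NAMES = [
    "vsst_fix_roi", "vsst_tf_roi", "vsst_t_roi", "vsst_sl", "vsst_tm_roi",
    "mct_aa", "mct_lc",
    "prt_ac_max", "prt_vc_max", "prt_rd", "prt_t1", "prt_t2", "prt_t3",
    "st_ls_ps", "st_ls_as", "st_vm_ps", "st_vm_as",
    "st_vmax_ps", "st_vmax_as", "st_as_ps", "st_as_as",
    "fet_i_happy", "fet_i_sad", "fet_t_happy", "fet_t_sad",
    "fet_l_happy", "fet_l_sad",
]

#: FBS channel indices (0-based) carrying each emotion's cheek intensities.
HAPPY_CHANNELS = (2, 4)  # left-cheek smile, right-cheek happy
SAD_CHANNELS = (3, 5)    # left-cheek sad, right-cheek sad


@dataclass
class ROISpec:
    """Spherical region of interest around a 3-D target position."""

    center: np.ndarray  # (3,) m
    radius: float = 0.15  # m

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return np.linalg.norm(pts - self.center, axis=-1) <= self.radius


@dataclass
class SessionROIs:
    """Target geometry needed to score a session's gaze behavior."""

    vsst_target: ROISpec
    mct_targets: list[ROISpec]         # per-trial moving-cluster target
    mct_correct_options: list[ROISpec]  # per-trial correct number option


@dataclass
class PupilBaseline:
    """Running-mean pupil baseline over the pre-stimulus span."""

    mean: float = 0.0   # mu_Tb, mm
    k: int = 0          # number of samples consumed
    sd: float = 0.0     # pre-stimulus spread, used for onset detection

    def update(self, value: float) -> None:
        # running-mean recursion mu <- k/(k+1) mu + 1/(k+1) x
        self.mean = self.k / (self.k + 1) * self.mean + value / (self.k + 1)
        self.k += 1


def pupil_baseline(series: np.ndarray) -> PupilBaseline:
    """Fold the pre-stimulus pupil samples through the running-mean recursion.

    The recursion is algebraically the cumulative arithmetic mean; it is kept
    in recursive form because that is how a streaming implementation updates.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty pre-stimulus span")
    b = PupilBaseline()
    for v in series:
        b.update(float(v))
    b.sd = float(series.std())
    return b


@dataclass
class ExpressionTrial:
    """One 5-s voluntary-expression phase: smoothed intensity plus timing."""

    val: np.ndarray       # emotion intensity series in [0, 1]
    dt: float = 1.0 / SAMPLING_RATE
    theta: float = 0.1    # activation threshold
    t0: float = 0.0       # instruction onset relative to the series start
    span: float = 5.0     # nominal phase duration, s


@dataclass
class FeatureVector:
    """The 27 named behavioral features; missing entries are NaN."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            self.values.setdefault(name, np.nan)
        extra = set(self.values) - set(FEATURE_NAMES)
        if extra:
            raise ValueError(f"unknown feature names: {sorted(extra)}")

    def to_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)

    @property
    def missing(self) -> list[str]:
        return [n for n in FEATURE_NAMES if not np.isfinite(self.values[n])]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# ---------------------------------------------------------------------------
# VSST

def vsst_features(search_seg: TaskSegment, events: list[GazeEvent],
                  gaze: MergedGaze, roi: ROISpec) -> dict[str, float]:
    """Score the 8-s search phase of the visual search task."""
    phase_dur = search_seg.duration
    t_onset = float(gaze.timestamps[0])
    fixations = [e for e in events if e.kind is EventKind.FIXATION]
    saccades = [e for e in events if e.kind is EventKind.SACCADE]
    in_roi = [f for f in fixations if roi.contains(f.centroid)[0]]
    total_fix = sum(f.duration for f in fixations)
    roi_fix = sum(f.duration for f in in_roi)
    fix_pct = 100.0 * roi_fix / total_fix if total_fix > 0 else 0.0
    tf_roi = min(in_roi, key=lambda f: f.onset).onset - t_onset if in_roi \
        else phase_dur
    intra_roi_sacc = 0.0
    for s in saccades:
        a, b = s.sample_range
        b = min(b, len(gaze) - 1)
        if roi.contains(gaze.endpoint[a])[0] and roi.contains(gaze.endpoint[b])[0]:
            intra_roi_sacc += s.duration
    t_roi = roi_fix + intra_roi_sacc
    sl = float(np.median([s.amplitude for s in saccades])) if saccades else 0.0
    tm_roi = float(np.median([f.duration for f in in_roi])) if in_roi else 0.0
    return {"vsst_fix_roi": fix_pct, "vsst_tf_roi": min(tf_roi, phase_dur),
            "vsst_t_roi": t_roi, "vsst_sl": sl, "vsst_tm_roi": tm_roi}


# ---------------------------------------------------------------------------
# MCT

def mct_trial(search_seg: TaskSegment, calc_seg: TaskSegment,
              search_gaze: MergedGaze, calc_events: list[GazeEvent],
              roi_target: ROISpec, roi_correct: ROISpec) -> tuple[float, float]:
    """One memory-calculation trial: (Aa %, Lc s).

    Aa is the per-sample dwell fraction on the tracked target during the
    search phase; Lc is the onset of the first fixation on the correct
    number option relative to the option onset, with the calculation-phase
    duration as fallback when the option is never fixated.
    """
    dwell = roi_target.contains(search_gaze.endpoint).mean()
    aa = 100.0 * float(dwell)
    calc_dur = calc_seg.duration
    t0 = float(calc_seg.timestamps[0]) if calc_seg.n_samples else 0.0
    hits = [e for e in calc_events
            if e.kind is EventKind.FIXATION and roi_correct.contains(e.centroid)[0]]
    lc = min(hits, key=lambda e: e.onset).onset - t0 if hits else calc_dur
    return aa, max(0.0, float(lc))


def mct_features(trials: list[tuple[float, float]]) -> dict[str, float]:
    aa = float(np.mean([t[0] for t in trials]))
    lc = float(np.mean([t[1] for t in trials]))
    return {"mct_aa": aa, "mct_lc": lc}


# ---------------------------------------------------------------------------
# PRT

def prt_trial_eye(pupil_window: np.ndarray, baseline: PupilBaseline,
                  dt: float = 1.0 / SAMPLING_RATE) -> dict[str, float]:
    """Pupillary light-reflex metrics for one eye in one stimulus window.

    Constriction onset is the first sample more than 3 pre-stimulus standard
    deviations below the baseline mean; velocity/acceleration peaks and the
    T2/T3 latencies are measured from that onset to maximum constriction.
    When no constriction is detectable the latencies fall back to the window
    length and the kinematic peaks to zero.
    """
    d = np.asarray(pupil_window, dtype=float)
    win_len = d.size * dt
    rd = float(d.max() - d.min())
    thr = baseline.mean - 3.0 * max(baseline.sd, 1e-6)
    below = np.nonzero(d < thr)[0]
    if below.size == 0:
        return {"t1": win_len, "t2": win_len, "t3": win_len,
                "vc_max": 0.0, "ac_max": 0.0, "rd": rd}
    onset = int(below[0])
    trough = int(np.argmin(d))
    if trough <= onset:
        trough = d.size - 1
    seg = d[onset:trough + 1]
    vel = np.abs(np.diff(seg)) / dt
    acc = np.abs(np.diff(seg, 2)) / dt ** 2 if seg.size > 2 else np.zeros(1)
    vc_max = float(vel.max()) if vel.size else 0.0
    ac_max = float(acc.max()) if acc.size else 0.0
    t2 = float(np.argmax(vel) + 1) * dt if vel.size else win_len
    return {"t1": onset * dt, "t2": t2, "t3": (trough - onset) * dt,
            "vc_max": vc_max, "ac_max": ac_max, "rd": rd}


def prt_features(trials: list[dict[str, float]]) -> dict[str, float]:
    """Average per-trial (already eye-averaged) PLR metrics over trials."""
    mean = lambda k: float(np.mean([t[k] for t in trials]))
    return {"prt_ac_max": mean("ac_max"), "prt_vc_max": mean("vc_max"),
            "prt_rd": mean("rd"), "prt_t1": mean("t1"),
            "prt_t2": mean("t2"), "prt_t3": mean("t3")}


def average_eyes(left: dict[str, float], right: dict[str, float],
                 ) -> dict[str, float]:
    return {k: 0.5 * (left[k] + right[k]) for k in left}


# ---------------------------------------------------------------------------
# ST

def st_features(trial_events: list[list[GazeEvent]],
                conditions: list[str]) -> dict[str, float]:
    """Aggregate saccade metrics per condition (PS / AS).

    ``trial_events`` holds, per trial, the admissible (non-anticipatory)
    saccades of the response window with latencies attached. Latency uses
    the first admissible saccade per trial; velocity and amplitude pool all
    effective saccades; the peak velocity is the condition-wide maximum.
    Conditions without a single admissible saccade yield NaN (imputed later
    for the tabular baselines).
    """
    out: dict[str, float] = {}
    for cond in ("ps", "as"):
        sel = [evs for evs, c in zip(trial_events, conditions) if c == cond]
        firsts = [min(evs, key=lambda e: e.latency) for evs in sel if evs]
        pooled = [e for evs in sel for e in evs]
        if not pooled:
            out.update({f"st_ls_{cond}": np.nan, f"st_vm_{cond}": np.nan,
                        f"st_vmax_{cond}": np.nan, f"st_as_{cond}": np.nan})
            continue
        out[f"st_ls_{cond}"] = float(np.mean([e.latency for e in firsts]))
        out[f"st_vm_{cond}"] = float(np.mean([e.mean_velocity for e in pooled]))
        out[f"st_vmax_{cond}"] = float(max(e.peak_velocity for e in pooled))
        out[f"st_as_{cond}"] = float(np.mean([e.amplitude for e in pooled]))
    return out


# ---------------------------------------------------------------------------
# FET

def fet_trial(trial: ExpressionTrial) -> tuple[float, float, float]:
    """(intensity, duration, latency) of one expression trial.

    Intensity is the mean over the phase, duration the sampling interval
    times the count of supra-threshold samples, latency the first crossing
    time (phase duration when the threshold is never exceeded). Samples
    beyond the nominal phase span are ignored, so trailing data cannot
    change any of the three outputs.
    """
    val = np.asarray(trial.val, dtype=float)
    n_span = int(round(trial.span / trial.dt))
    val = val[:n_span]
    n = val.size
    if n == 0:
        return 0.0, 0.0, trial.span
    intensity = float(val.mean())
    above = val > trial.theta
    duration = float(trial.dt * above.sum())
    if above.any():
        t_first = float(np.argmax(above)) * trial.dt
        latency = max(0.0, t_first - trial.t0)
    else:
        latency = trial.span
    return intensity, duration, latency


def fet_features(happy: list[ExpressionTrial], sad: list[ExpressionTrial],
                 ) -> dict[str, float]:
    out = {}
    for emo, trials in (("happy", happy), ("sad", sad)):
        scored = [fet_trial(t) for t in trials]
        out[f"fet_i_{emo}"] = float(np.mean([s[0] for s in scored]))
        out[f"fet_t_{emo}"] = float(np.mean([s[1] for s in scored]))
        out[f"fet_l_{emo}"] = float(np.mean([s[2] for s in scored]))
    return out


def emotion_intensity(fbs: np.ndarray, emotion: str) -> np.ndarray:
    """Left/right cheek channels of one emotion combined by their mean."""
    channels = HAPPY_CHANNELS if emotion == "happy" else SAD_CHANNELS
    return fbs[:, list(channels)].mean(axis=1)


# ---------------------------------------------------------------------------
# Orchestration

def extract_all(rec: SessionRecording, rois: SessionROIs,
                preprocess_cfg: PreprocessConfig | None = None,
                ivdt_cfg: IVDTConfig | None = None,
                theta: float = 0.1, min_latency: float = 0.1) -> FeatureVector:
    """Run preprocessing, event segmentation and all feature extractors.

    Features of a task missing from the recording stay NaN-flagged.
    """
    ivdt_cfg = ivdt_cfg or IVDTConfig()
    clean, _ = preprocess_recording(rec, preprocess_cfg)
    segments = segment_tasks(clean)
    by_task: dict[Task, list[TaskSegment]] = {}
    for seg in segments:
        by_task.setdefault(seg.task, []).append(seg)
    values: dict[str, float] = {}

    # VSST: single trial, search phase only
    search = [s for s in by_task.get(Task.VSST, []) if s.phase is Phase.SEARCH]
    if search:
        seg = search[0]
        gaze = merge_gaze(clean, seg.start, seg.stop)
        events = ivdt_segment(gaze, ivdt_cfg)
        values.update(vsst_features(seg, events, gaze, rois.vsst_target))

    # MCT: two trials; dwell during search, option fixation during calculation
    mct_segs = by_task.get(Task.MCT, [])
    trials = sorted({s.trial for s in mct_segs})
    mct_results = []
    for tr in trials:
        s_seg = next((s for s in mct_segs
                      if s.trial == tr and s.phase is Phase.SEARCH), None)
        c_seg = next((s for s in mct_segs
                      if s.trial == tr and s.phase is Phase.CALCULATE), None)
        if s_seg is None or c_seg is None or tr >= len(rois.mct_targets):
            continue
        s_gaze = merge_gaze(clean, s_seg.start, s_seg.stop)
        c_gaze = merge_gaze(clean, c_seg.start, c_seg.stop)
        c_events = ivdt_segment(c_gaze, ivdt_cfg)
        mct_results.append(mct_trial(s_seg, c_seg, s_gaze, c_events,
                                     rois.mct_targets[tr],
                                     rois.mct_correct_options[tr]))
    if mct_results:
        values.update(mct_features(mct_results))

    # PRT: per trial, baseline over the fixate phase, metrics in the stimulus
    # window, averaged over eyes then trials
    prt_segs = by_task.get(Task.PRT, [])
    prt_trials = []
    for tr in sorted({s.trial for s in prt_segs}):
        fix = next((s for s in prt_segs
                    if s.trial == tr and s.phase is Phase.FIXATE), None)
        stim = next((s for s in prt_segs
                     if s.trial == tr and s.phase is Phase.STIMULUS), None)
        if fix is None or stim is None:
            continue
        per_eye = []
        for chan in ("pupil_left", "pupil_right"):
            base = pupil_baseline(fix.channel(chan))
            per_eye.append(prt_trial_eye(stim.channel(chan), base))
        prt_trials.append(average_eyes(*per_eye))
    if prt_trials:
        values.update(prt_features(prt_trials))

    # ST: 12 trials (first half pro-, second half anti-saccades); events over
    # the whole trial, latency relative to the peripheral-target onset
    st_segs = by_task.get(Task.ST, [])
    st_trials = sorted({s.trial for s in st_segs})
    trial_events, conditions = [], []
    for tr in st_trials:
        parts = [s for s in st_segs if s.trial == tr]
        periph = next((s for s in parts if s.phase is Phase.PERIPHERAL), None)
        if periph is None:
            continue
        start = min(s.start for s in parts)
        stop = max(s.stop for s in parts)
        gaze = merge_gaze(clean, start, stop)
        events = ivdt_segment(gaze, ivdt_cfg)
        onset_t = clean.timestamps[periph.start]
        sacc = [e for e in events if e.kind is EventKind.SACCADE
                and e.onset >= onset_t]
        sacc = [saccade_metrics(e, gaze, onset_t) for e in sacc]
        sacc = filter_anticipatory(sacc, min_latency)
        trial_events.append(sacc)
        conditions.append("ps" if tr < len(st_trials) // 2 else "as")
    if trial_events:
        values.update(st_features(trial_events, conditions))

    # FET: trial 0 happy, trial 1 sad by convention
    fet_segs = [s for s in by_task.get(Task.FET, [])
                if s.phase is Phase.EXPRESSION]
    happy_trials, sad_trials = [], []
    for seg in sorted(fet_segs, key=lambda s: s.trial):
        emotion = "happy" if seg.trial == 0 else "sad"
        val = emotion_intensity(clean.fbs[seg.start:seg.stop], emotion)
        trial = ExpressionTrial(val=val, theta=theta, span=seg.duration)
        (happy_trials if emotion == "happy" else sad_trials).append(trial)
    if happy_trials and sad_trials:
        values.update(fet_features(happy_trials, sad_trials))

    return FeatureVector(values=values)


# ---------------------------------------------------------------------------
# Tabular assembly for the baseline classifiers

def assemble_baseline_table(features: dict[str, FeatureVector],
                            covariates: dict[str, SubjectCovariates],
                            ) -> pd.DataFrame:
    """27 behavioral features + age + sex + education + 10 MoCA-B items.

    Returns a 40-column design table indexed by subject with a ``label``
    column (CD = 1). Missing behavioral features stay NaN here; impute with
    training-split medians before fitting (:func:`median_impute`).
    """
    if set(features) != set(covariates):
        raise ValueError("mismatched subject sets between features and covariates")
    rows = {}
    for sid, fv in features.items():
        cov = covariates[sid]
        row = dict(zip(FEATURE_NAMES, fv.to_array()))
        row["age"] = cov.age
        row["sex"] = 1.0 if cov.sex == "F" else 0.0
        row["education"] = cov.education
        row.update({f"moca{i + 1}": cov.moca_sub[i] for i in range(10)})
        row["label"] = 1 if cov.group.value == "CD" else 0
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    assert df.shape[1] == 41  # 40 features + label
    return df


def median_impute(table: pd.DataFrame, train_index: pd.Index) -> pd.DataFrame:
    """Replace NaNs by the training-split median of each column."""
    out = table.copy()
    feature_cols = [c for c in out.columns if c != "label"]
    med = out.loc[train_index, feature_cols].median()
    out[feature_cols] = out[feature_cols].fillna(med)
    return out
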