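"""Synthetic multimodal cohort generator.

Emulates the raw session recordings the analysis pipeline expects — five
task paradigms at 120 Hz (facial channels natively 60 Hz, upsampled by
nearest neighbor), blinks, pupillary light-reflex dynamics, minimum-jerk
saccades and voluntary-expression ramps — together with per-subject
demographics/MoCA-B covariates and a ground-truth record of every injected
behavioral value. The study data themselves are private, so this generator
is the test bed for every downstream stage.

Group effects are injected as shifts of per-subject latent behavioral
targets (healthy-control mean, cognitive-decline mean, common SD). The
default magnitudes are chosen to be clinically plausible and large enough
that a 20-vs-20 rank test resolves each shifted feature; a null
configuration zeroes every shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .session import (FACIAL_RATE, SAMPLING_RATE, Group, SessionRecording,
                      SubjectCovariates, Task, upsample_facial,
                      write_covariates, write_session)
from .features import ROISpec, SessionROIs

FS = SAMPLING_RATE
DT = 1.0 / FS

#: latent behavioral targets: name -> (HC mean, CD mean, subject SD)
DEFAULT_EFFECTS: dict[str, tuple[float, float, float]] = {
    "vsst_tf_roi":   (0.80, 1.80, 0.35),   # s, time to first ROI fixation
    "vsst_fix_frac": (0.72, 0.52, 0.07),   # fraction of fixation time in ROI
    "vsst_fix_dur":  (0.75, 0.45, 0.09),   # s, ROI fixation duration
    "mct_aa_frac":   (0.70, 0.50, 0.07),   # dwell fraction on target
    "mct_lc":        (1.00, 2.00, 0.35),   # s, calculation latency
    "prt_t1":        (0.22, 0.33, 0.035),  # s, constriction latency
    "prt_rd":        (0.90, 0.55, 0.10),   # mm, constriction amplitude
    "prt_rise":      (0.30, 0.54, 0.06),   # s, constriction rise time
    "st_ls":         (0.20, 0.30, 0.030),  # s, saccade latency
    "st_amp_as":     (25.0, 19.0, 1.80),   # deg, anti-saccade amplitude
    "st_dur_scale":  (1.00, 1.30, 0.08),   # saccade slowing factor
    "fet_intensity": (0.55, 0.30, 0.07),   # plateau expression intensity
    "fet_latency":   (0.50, 1.50, 0.25),   # s, expression onset latency
    # pervasive dynamics: fixational drift (oculomotor instability) and
    # pupillary unrest (hippus), both altered with cognitive decline
    "gaze_drift":    (0.15, 0.40, 0.05),   # deg, stationary drift SD
    "hippus_amp":    (0.10, 0.04, 0.02),   # mm, slow pupil oscillation
    "head_sway":     (0.002, 0.005, 0.0008),  # m, postural sway SD
}

#: demographics per group: (age mean/sd), (education mean/sd),
#: (MoCA-B mean/sd), female fraction
DEMOGRAPHICS = {
    Group.HC: dict(age=(70.55, 9.01), edu=(9.45, 1.76),
                   moca=(25.20, 1.32), female=0.65),
    Group.CD: dict(age=(77.35, 11.17), edu=(8.85, 2.06),
                   moca=(18.35, 4.48), female=0.50),
}

MOCA_ITEM_MAX = np.array([5, 3, 3, 3, 2, 3, 3, 3, 2, 3])  # sums to 30

# scene geometry: targets live on the z = 1.5 m plane in front of the eyes
PLANE_Z = 1.5
EYE_HALF_SEP = 0.032
CENTER = np.array([0.0, 0.0, PLANE_Z])
VSST_OBJECTS = [(-0.5, 0.25), (0.0, 0.25), (0.5, 0.25),
                (-0.25, -0.25), (0.25, -0.25)]
MCT_TARGET = (0.30, 0.10)
MCT_OPTIONS = [(-0.45, -0.30), (-0.15, -0.30), (0.15, -0.30), (0.45, -0.30)]
MCT_AWAY = (-0.35, 0.30)
ST_OFFSET = 0.7
FET_PORTRAIT = (0.0, 0.10)
ROI_RADIUS = 0.15


@dataclass
class CohortConfig:
    n_hc: int = 20
    n_cd: int = 20
    seed: int = 0
    effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    gaze_jitter: float = 0.0025   # m on the target plane (~0.13 deg)
    pupil_noise: float = 0.015    # mm
    fbs_jitter: float = 0.01
    blink_rate: float = 10.0      # events / min
    gap_seconds: float = 2.0      # unlabeled recovery span between trials
    pupil_base: tuple[float, float] = (4.2, 0.35)  # mm mean/sd across subjects

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_cd) <= 0:
            raise ValueError("subject counts must be positive")
        for name, (a, b, sd) in self.effects.items():
            if not np.isfinite([a, b, sd]).all():
                raise ValueError(f"non-finite effect entry for {name}")

    def nulled(self) -> "CohortConfig":
        """Copy with every group shift removed (CD mean := HC mean)."""
        eff = {k: (hc, hc, sd) for k, (hc, cd, sd) in self.effects.items()}
        return replace(self, effects=eff)


@dataclass
class SubjectTruth:
    """Injected per-subject behavioral values and scoring geometry."""

    subject_id: str
    group: Group
    targets: dict[str, float]        # latent draws (generator scale)
    realized: dict[str, float]       # schedule-level realized quantities
    rois: SessionROIs
    blink_times: list[float] = field(default_factory=list)


@dataclass
class Cohort:
    sessions: list[SessionRecording]
    covariates: list[SubjectCovariates]
    truth: list[SubjectTruth]
    config: CohortConfig

    def labels(self) -> np.ndarray:
        return np.array([1 if s.group is Group.CD else 0 for s in self.sessions])

    def target_table(self):
        """Per-subject latent behavioral targets as a plain dict-of-lists."""
        import pandas as pd
        rows = [dict(subject_id=t.subject_id, group=t.group.value, **t.targets)
                for t in self.truth]
        return pd.DataFrame(rows).set_index("subject_id")


# ---------------------------------------------------------------------------
# small kinematic helpers

def _plane(p: tuple[float, float]) -> np.ndarray:
    return np.array([p[0], p[1], PLANE_Z])


def _minjerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    return 10 * u ** 3 - 15 * u ** 4 + 6 * u ** 5


def _smoothstep(t: np.ndarray, onset: float, rise: float) -> np.ndarray:
    """0 before onset, minimum-jerk ramp to 1 over ``rise`` seconds."""
    u = np.clip((t - onset) / max(rise, 1e-6), 0.0, 1.0)
    return _minjerk(u)


def _sacc_duration(amp_deg: float, scale: float) -> float:
    """Main-sequence-like duration: slower for larger amplitudes."""
    return (0.030 + 0.0025 * amp_deg) * scale


def _angle_between(p0: np.ndarray, p1: np.ndarray) -> float:
    d0, d1 = p0 / np.linalg.norm(p0), p1 / np.linalg.norm(p1)
    return float(np.degrees(np.arccos(np.clip(d0 @ d1, -1, 1))))


class _GazeScript:
    """Accumulates a piecewise fixation/saccade gaze trajectory."""

    def __init__(self, start: np.ndarray):
        self.pos = np.asarray(start, dtype=float)
        self.chunks: list[np.ndarray] = []

    def fixate(self, n: int) -> None:
        if n > 0:
            self.chunks.append(np.tile(self.pos, (n, 1)))

    def saccade_to(self, target: np.ndarray, n: int) -> None:
        target = np.asarray(target, dtype=float)
        if n <= 0:
            self.pos = target
            return
        u = (np.arange(1, n + 1)) / n
        prof = _minjerk(u)[:, None]
        self.chunks.append(self.pos + prof * (target - self.pos))
        self.pos = target

    def take(self) -> np.ndarray:
        out = np.concatenate(self.chunks) if self.chunks else np.zeros((0, 3))
        self.chunks = []
        return out


# ---------------------------------------------------------------------------
# per-task trajectory builders (each returns gaze samples for its trial and
# records realized quantities in ``real``)

def _build_vsst(rng, lat, real, rois, dur_scale) -> np.ndarray:
    """3 s memorize + 8 s search with scheduled ROI dwell pattern."""
    script = _GazeScript(CENTER)
    script.fixate(int(3.0 * FS))  # memorize: hold the sample object
    roi_c = rois.vsst_target.center
    others = [_plane(p) for p in VSST_OBJECTS
              if np.linalg.norm(_plane(p) - roi_c) > 1e-9]
    n_search = int(8.0 * FS)
    tf = lat["vsst_tf_roi"]
    d_roi = lat["vsst_fix_dur"]
    frac = lat["vsst_fix_frac"]
    # post-arrival in/out alternation achieving the target ROI time fraction
    r = np.clip(8.0 * frac / max(8.0 - tf, 0.5), 0.05, 0.95)
    d_out = np.clip(d_roi * (1 - r) / r, 0.20, 3.0)
    fixations: list[tuple[bool, float]] = []  # (in_roi, duration)
    t_cursor = 0.0
    k = 0
    while t_cursor < tf - 0.05:
        d = min(max(rng.normal(0.45, 0.08), 0.2), tf - t_cursor)
        fixations.append((False, d))
        t_cursor += d
        k += 1
    in_roi_next = True
    while t_cursor < 8.0 - 0.15:
        d = d_roi if in_roi_next else d_out
        d = max(0.2, rng.normal(d, 0.05 * d))
        fixations.append((in_roi_next, d))
        t_cursor += d
        in_roi_next = not in_roi_next
    # realize the schedule sample-exactly
    produced = 0
    roi_onset = None
    roi_durs, out_time = [], 0.0
    idx_other = 0
    for in_roi, d in fixations:
        target = roi_c if in_roi else others[idx_other % len(others)]
        if not in_roi:
            idx_other += 1
        amp = _angle_between(script.pos, target)
        n_s = max(2, int(round(_sacc_duration(amp, dur_scale) * FS)))
        n_f = int(round(d * FS))
        if produced + n_s + n_f > n_search:
            n_f = n_search - produced - n_s
            if n_f < 6:
                break
        script.saccade_to(target, n_s)
        script.fixate(n_f)
        produced += n_s + n_f
        if in_roi:
            if roi_onset is None:
                roi_onset = (produced - n_f) * DT
            roi_durs.append(n_f * DT)
        else:
            out_time += n_f * DT
    if produced < n_search:
        script.fixate(n_search - produced)
        if fixations and not fixations[-1][0]:
            out_time += (n_search - produced) * DT
        elif roi_durs:
            roi_durs[-1] += (n_search - produced) * DT
    roi_time = sum(roi_durs)
    real["vsst_tf_roi"] = roi_onset if roi_onset is not None else 8.0
    real["vsst_fix_frac"] = roi_time / max(roi_time + out_time, 1e-9)
    real["vsst_tm_roi"] = float(np.median(roi_durs)) if roi_durs else 0.0
    real["vsst_t_roi"] = roi_time
    return script.take()


def _dwell_phase(rng, script, n_phase, roi_c, away, frac, dur_scale,
                 block=0.8) -> float:
    """Alternate in/out dwell blocks achieving ~``frac`` time on the target.

    Returns the realized in-ROI sample fraction.
    """
    produced = 0
    in_samples = 0
    go_in = True
    while produced < n_phase:
        d_in = max(0.25, rng.normal(block * frac, 0.05))
        d_out = max(0.20, rng.normal(block * (1 - frac), 0.05))
        target = roi_c if go_in else away
        amp = _angle_between(script.pos, target)
        n_s = max(2, int(round(_sacc_duration(amp, dur_scale) * FS)))
        n_f = int(round((d_in if go_in else d_out) * FS))
        if produced + n_s + n_f > n_phase:
            n_f = n_phase - produced - n_s
            if n_f <= 0:
                break
        script.saccade_to(target, n_s)
        script.fixate(n_f)
        if go_in:
            in_samples += n_f
        produced += n_s + n_f
        go_in = not go_in
    if produced < n_phase:
        remaining = n_phase - produced
        # finish on whichever target we are currently holding
        on_roi = np.linalg.norm(script.pos - roi_c) < 1e-9
        script.fixate(remaining)
        if on_roi:
            in_samples += remaining
        produced = n_phase
    return in_samples / n_phase


def _build_mct_trial(rng, lat, real, trial, rois, dur_scale) -> np.ndarray:
    """3 s presentation + 10 s dynamic search + 5 s calculation."""
    script = _GazeScript(CENTER)
    script.fixate(int(3.0 * FS))
    roi_t = rois.mct_targets[trial].center
    away = _plane(MCT_AWAY)
    aa = _dwell_phase(rng, script, int(10.0 * FS), roi_t, away,
                      lat["mct_aa_frac"], dur_scale)
    real[f"mct_aa_frac_{trial}"] = aa
    # calculation: stare away, then jump to the correct option at latency Lc
    n_calc = int(5.0 * FS)
    lc = min(lat["mct_lc"], 4.0)
    correct = rois.mct_correct_options[trial].center
    n_s0 = max(2, int(round(_sacc_duration(
        _angle_between(script.pos, away), dur_scale) * FS)))
    script.saccade_to(away, n_s0)
    n_pre = max(int(round(lc * FS)), n_s0)
    script.fixate(n_pre - n_s0)
    n_s = max(2, int(round(_sacc_duration(
        _angle_between(away, correct), dur_scale) * FS)))
    script.saccade_to(correct, n_s)
    script.fixate(n_calc - n_pre - n_s)
    real[f"mct_lc_{trial}"] = (n_pre + n_s) * DT
    return script.take()


def _build_st_trial(rng, lat, real, trial, dur_scale) -> np.ndarray:
    """2 s central fixation + 2 s peripheral response."""
    is_anti = trial >= 6
    side = 1 if rng.random() < 0.5 else -1
    script = _GazeScript(CENTER)
    script.fixate(int(2.0 * FS))
    ls = lat["st_ls"] + (0.03 if is_anti else 0.0) \
        + float(rng.normal(0.0, 0.01))
    ls = max(0.12, ls)
    n_lat = int(round(ls * FS))
    script.fixate(n_lat)
    if is_anti:
        amp = lat["st_amp_as"]
    else:
        amp = _angle_between(CENTER, _plane((side * ST_OFFSET, 0.0)))
        amp *= float(np.clip(rng.normal(1.0, 0.03), 0.9, 1.1))
    # anti-saccade goes opposite the (virtual) target side
    gaze_side = -side if is_anti else side
    x_land = PLANE_Z * np.tan(np.radians(amp)) * gaze_side
    dur = _sacc_duration(amp, dur_scale * float(np.clip(
        rng.normal(1.0, 0.05), 0.8, 1.2)))
    n_s = max(3, int(round(dur * FS)))
    script.saccade_to(np.array([x_land, 0.0, PLANE_Z]), n_s)
    n_rest = int(2.0 * FS) - n_lat - n_s
    script.fixate(max(0, n_rest))
    cond = "as" if is_anti else "ps"
    real.setdefault(f"st_ls_{cond}", []).append(n_lat * DT)
    real.setdefault(f"st_amp_{cond}", []).append(amp)
    real.setdefault(f"st_dur_{cond}", []).append(n_s * DT)
    return script.take()


def _build_fet_trial(rng, lat, trial) -> tuple[np.ndarray, np.ndarray]:
    """5 s expression phase: gaze on the portrait, FBS ramp at 60 Hz."""
    n120 = int(5.0 * FS)
    script = _GazeScript(_plane(FET_PORTRAIT))
    script.fixate(n120)
    n60 = (n120 + 1) // 2
    t60 = np.arange(n60) / FACIAL_RATE
    onset = lat["fet_latency"]
    plateau = lat["fet_intensity"]
    ramp = plateau * _smoothstep(t60, onset, 0.30)
    fbs60 = np.zeros((n60, 6))
    emo_channels = (2, 4) if trial == 0 else (3, 5)  # happy / sad cheeks
    for c in emo_channels:
        fbs60[:, c] = np.clip(
            ramp * np.clip(rng.normal(1.0, 0.05), 0.8, 1.2), 0.0, 1.0)
    fbs60[:, 0] = np.clip(0.05 + 0.02 * rng.standard_normal(n60), 0, 1)
    fbs60[:, 1] = np.clip(0.05 + 0.02 * rng.standard_normal(n60), 0, 1)
    return script.take(), fbs60


# ---------------------------------------------------------------------------
# subject assembly

def _draw_latents(rng, group: Group,
                  effects: dict[str, tuple[float, float, float]],
                  ) -> dict[str, float]:
    lat: dict[str, float] = {}
    for name, (hc, cd, sd) in effects.items():
        mu = hc if group is Group.HC else cd
        lat[name] = float(rng.normal(mu, sd))
    # physical / algorithmic clamps
    lat["vsst_tf_roi"] = float(np.clip(lat["vsst_tf_roi"], 0.25, 5.0))
    lat["vsst_fix_frac"] = float(np.clip(lat["vsst_fix_frac"], 0.10, 0.92))
    lat["vsst_fix_dur"] = float(np.clip(lat["vsst_fix_dur"], 0.20, 2.5))
    lat["mct_aa_frac"] = float(np.clip(lat["mct_aa_frac"], 0.10, 0.92))
    lat["mct_lc"] = float(np.clip(lat["mct_lc"], 0.30, 4.0))
    lat["prt_t1"] = float(np.clip(lat["prt_t1"], 0.12, 0.45))
    lat["prt_rd"] = float(np.clip(lat["prt_rd"], 0.25, 1.6))
    lat["prt_rise"] = float(np.clip(lat["prt_rise"], 0.15,
                                    0.95 - lat["prt_t1"]))
    lat["st_ls"] = float(np.clip(lat["st_ls"], 0.13, 0.60))
    lat["st_amp_as"] = float(np.clip(lat["st_amp_as"], 8.0, 30.0))
    lat["st_dur_scale"] = float(np.clip(lat["st_dur_scale"], 0.7, 1.8))
    lat["fet_intensity"] = float(np.clip(lat["fet_intensity"], 0.12, 0.92))
    lat["fet_latency"] = float(np.clip(lat["fet_latency"], 0.10, 4.0))
    lat["gaze_drift"] = float(np.clip(lat["gaze_drift"], 0.05, 0.80))
    lat["hippus_amp"] = float(np.clip(lat["hippus_amp"], 0.005, 0.20))
    lat["head_sway"] = float(np.clip(lat["head_sway"], 0.0005, 0.02))
    return lat


def _subject_rois(rng) -> SessionROIs:
    target_idx = int(rng.integers(len(VSST_OBJECTS)))
    correct = [int(rng.integers(len(MCT_OPTIONS))) for _ in range(2)]
    return SessionROIs(
        vsst_target=ROISpec(_plane(VSST_OBJECTS[target_idx]), ROI_RADIUS),
        mct_targets=[ROISpec(_plane(MCT_TARGET), ROI_RADIUS)] * 2,
        mct_correct_options=[ROISpec(_plane(MCT_OPTIONS[c]), ROI_RADIUS)
                             for c in correct],
    )


def generate_subject(subject_id: str, group: Group, cfg: CohortConfig,
                     rng: np.random.Generator,
                     ) -> tuple[SessionRecording, SubjectTruth]:
    """Synthesize one complete five-paradigm session."""
    lat = _draw_latents(rng, group, cfg.effects)
    rois = _subject_rois(rng)
    real: dict[str, float] = {}
    dur_scale = lat["st_dur_scale"]
    n_gap = int(cfg.gap_seconds * FS)

    blocks: list[tuple[Task, int, np.ndarray]] = []  # (task, trial, gaze)

    def gap() -> None:
        script = _GazeScript(CENTER)
        script.fixate(n_gap)
        blocks.append((Task.NONE, -1, script.take()))

    gap()
    blocks.append((Task.VSST, 0, _build_vsst(rng, lat, real, rois, dur_scale)))
    for tr in range(2):
        gap()
        blocks.append((Task.MCT, tr,
                       _build_mct_trial(rng, lat, real, tr, rois, dur_scale)))
    for tr in range(2):
        gap()
        script = _GazeScript(CENTER)
        script.fixate(int(5.0 * FS))
        blocks.append((Task.PRT, tr, script.take()))
    for tr in range(12):
        gap()
        blocks.append((Task.ST, tr,
                       _build_st_trial(rng, lat, real, tr, dur_scale)))
    fet_fbs: list[tuple[int, np.ndarray]] = []  # (start idx filled later)
    for tr in range(2):
        gap()
        gaze_fet, fbs60 = _build_fet_trial(rng, lat, tr)
        blocks.append((Task.FET, tr, gaze_fet))
        fet_fbs.append((len(blocks) - 1, fbs60))

    # concatenate the gaze path and build per-sample labels
    gaze = np.concatenate([b[2] for b in blocks])
    n = len(gaze)
    task_label = np.concatenate([
        np.full(len(b[2]), b[0].value, dtype=object) for b in blocks])
    trial_index = np.concatenate([
        np.full(len(b[2]), b[1], dtype=int) for b in blocks])
    t = np.arange(n) * DT

    # pupil trace: baseline + pupillary unrest (hippus) + PLR constrictions
    base = float(np.clip(rng.normal(*cfg.pupil_base), 3.0, 6.0))
    hippus_f = rng.uniform(0.20, 0.45)
    hippus_phi = rng.uniform(0.0, 2 * np.pi)
    pupil = base + lat["hippus_amp"] * np.sin(
        2 * np.pi * hippus_f * t + hippus_phi)
    offsets = np.cumsum([0] + [len(b[2]) for b in blocks[:-1]])
    prt_real = []
    for bi, (task, trial, g) in enumerate(blocks):
        if task is not Task.PRT:
            continue
        start = offsets[bi]
        stim_start = start + int(4.0 * FS)
        stim_t = (np.arange(n - stim_start)) * DT
        rd, rise = lat["prt_rd"], lat["prt_rise"]
        c = rd * _smoothstep(stim_t, lat["prt_t1"], rise)
        trough_at = lat["prt_t1"] + rise
        # mild within-stimulus redilation ("pupil escape") after peak
        # constriction keeps the trough well defined
        esc = (stim_t > trough_at) & (stim_t <= 1.0)
        c[esc] -= 0.2 * rd * (stim_t[esc] - trough_at)
        # post-stimulus: exponential recovery from the end-of-window level
        rec_mask = stim_t > 1.0
        level = rd * (1.0 - 0.2 * max(0.0, 1.0 - trough_at))
        c[rec_mask] = level * np.exp(-(stim_t[rec_mask] - 1.0) / 0.35)
        pupil[stim_start:] -= c
        prt_real.append({"t1": lat["prt_t1"], "rd": lat["prt_rd"],
                         "t3": trough_at - lat["prt_t1"],
                         "vc_max": 1.875 * lat["prt_rd"] / lat["prt_rise"]})
    real["prt_t1"] = lat["prt_t1"]
    real["prt_rd"] = lat["prt_rd"]
    real["prt_rise"] = lat["prt_rise"]

    pl = pupil + 0.05 + cfg.pupil_noise * rng.standard_normal(n)
    pr = pupil - 0.05 + cfg.pupil_noise * rng.standard_normal(n)

    # facial channels: zero outside FET, 60 Hz ramps upsampled inside
    fbs = np.zeros((n, 6))
    for bi, fbs60 in fet_fbs:
        start = offsets[bi]
        span = len(blocks[bi][2])
        up = upsample_facial(fbs60, span)
        fbs[start:start + span] = np.clip(
            up + cfg.fbs_jitter * rng.standard_normal((span, 6)) * (up > 0),
            0.0, 1.0)
    real["fet_intensity"] = lat["fet_intensity"]
    real["fet_latency"] = lat["fet_latency"]

    # openness + blinks (either-eye dips below the detection threshold)
    ol = np.clip(0.97 + 0.01 * rng.standard_normal(n), 0.0, 1.0)
    orr = np.clip(0.97 + 0.01 * rng.standard_normal(n), 0.0, 1.0)
    n_blinks = rng.poisson(cfg.blink_rate * (n * DT) / 60.0)
    blink_times = np.sort(rng.uniform(0.5, n * DT - 0.5, size=n_blinks))
    for bt in blink_times:
        b0 = int(bt * FS)
        b1 = b0 + int(rng.uniform(0.10, 0.25) * FS)
        b1 = min(b1, n)
        ol[b0:b1] = 0.15
        orr[b0:b1] = 0.15
        pl[b0:b1] = np.nan
        pr[b0:b1] = np.nan

    jit = cfg.gaze_jitter * rng.standard_normal((n, 3))
    jit[:, 2] *= 0.2  # depth jitter is small for a plane-mounted display
    # fixational drift: mean-reverting (AR(1)) wander of the gaze point on
    # the target plane with ~1 s relaxation and a group-shifted stationary SD
    drift_sd_m = PLANE_Z * np.tan(np.radians(lat["gaze_drift"]))
    rho = 1.0 - DT / 1.0
    step_sd = drift_sd_m * np.sqrt(1.0 - rho ** 2)
    steps = step_sd * rng.standard_normal((n, 2))
    from scipy.signal import lfilter
    drift = lfilter([1.0], [1.0, -rho], steps, axis=0)
    jit[:, :2] += drift
    # postural head sway: slow common wander of both eye origins; the gaze
    # endpoint stays world-anchored (vestibulo-ocular compensation)
    sway_steps = lat["head_sway"] * np.sqrt(1.0 - rho ** 2) \
        * rng.standard_normal((n, 3))
    sway = lfilter([1.0], [1.0, -rho], sway_steps, axis=0)
    sway[:, 2] *= 0.5
    origin_l = np.tile([-EYE_HALF_SEP, 0.0, 0.0], (n, 1)) + sway \
        + 0.0005 * rng.standard_normal((n, 3))
    origin_r = np.tile([EYE_HALF_SEP, 0.0, 0.0], (n, 1)) + sway \
        + 0.0005 * rng.standard_normal((n, 3))

    rec = SessionRecording(
        subject_id=subject_id, group=group, timestamps=t,
        eye_origin_left=origin_l, eye_origin_right=origin_r,
        gaze_point=gaze + jit, pupil_left=pl, pupil_right=pr,
        openness_left=ol, openness_right=orr, fbs=fbs,
        task_label=task_label.astype(str), trial_index=trial_index)
    truth = SubjectTruth(subject_id=subject_id, group=group, targets=lat,
                         realized=real, rois=rois,
                         blink_times=[float(b) for b in blink_times])
    return rec, truth


def _draw_covariates(rng, subject_id: str, group: Group) -> SubjectCovariates:
    d = DEMOGRAPHICS[group]
    age = float(np.clip(rng.normal(*d["age"]), 55, 95))
    edu = float(np.clip(np.round(rng.normal(*d["edu"])), 2, 18))
    lo, hi = (20.0, 30.0) if group is Group.HC else (4.0, 24.0)
    total = float(np.clip(np.round(rng.normal(*d["moca"])), lo, hi))
    # allocate the total over the ten items, respecting item maxima
    frac = total / MOCA_ITEM_MAX.sum()
    sub = np.floor(MOCA_ITEM_MAX * frac).astype(float)
    order = rng.permutation(10)
    i = 0
    while sub.sum() < total and i < 100:
        j = order[i % 10]
        if sub[j] < MOCA_ITEM_MAX[j]:
            sub[j] += 1
        i += 1
    sex = "F" if rng.random() < d["female"] else "M"
    return SubjectCovariates(subject_id=subject_id, group=group, age=age,
                             sex=sex, education=edu, moca_sub=sub,
                             moca_total=float(sub.sum()))


def generate_cohort(cfg: CohortConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort (default 20 HC + 20 CD)."""
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    sessions, covs, truths = [], [], []
    groups = [Group.HC] * cfg.n_hc + [Group.CD] * cfg.n_cd
    for i, group in enumerate(groups):
        sid = f"S{i + 1:03d}"
        child = np.random.default_rng(rng.integers(2 ** 31))
        rec, truth = generate_subject(sid, group, cfg, child)
        sessions.append(rec)
        truths.append(truth)
        covs.append(_draw_covariates(child, sid, group))
    return Cohort(sessions=sessions, covariates=covs, truth=truths, config=cfg)


def draw_cohort_targets(cfg: CohortConfig | None = None):
    """Draw only the per-subject latent behavioral targets (no signals).

    This is the cheap path for calibration studies (e.g. type-I-error rates
    of the group screening over many seeds) that need the injected feature
    values but not the raw 120 Hz streams. The draws use the same per-subject
    RNG stream layout as :func:`generate_cohort`.
    """
    import pandas as pd
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    groups = [Group.HC] * cfg.n_hc + [Group.CD] * cfg.n_cd
    for i, group in enumerate(groups):
        child = np.random.default_rng(rng.integers(2 ** 31))
        lat = _draw_latents(child, group, cfg.effects)
        rows.append(dict(subject_id=f"S{i + 1:03d}", group=group.value, **lat))
    return pd.DataFrame(rows).set_index("subject_id")


def null_cohort(cfg: CohortConfig | None = None) -> Cohort:
    """Cohort with every group effect removed (for calibration checks)."""
    cfg = cfg or CohortConfig()
    return generate_cohort(cfg.nulled())


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write session CSVs, the covariates CSV and a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort.sessions:
        write_session(rec, out / f"{rec.subject_id}.csv")
    write_covariates(cohort.covariates, out / "covariates.csv")
    gt = [{
        "subject_id": t.subject_id, "group": t.group.value,
        "targets": t.targets, "realized": t.realized,
        "blink_times": t.blink_times,
        "rois": {
            "vsst_target": list(t.rois.vsst_target.center),
            "mct_targets": [list(r.center) for r in t.rois.mct_targets],
            "mct_correct_options": [list(r.center)
                                    for r in t.rois.mct_correct_options],
            "radius": ROI_RADIUS,
        },
    } for t in cohort.truth]
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))


def load_rois(entry: dict) -> SessionROIs:
    """Rebuild a subject's scoring geometry from a ground-truth record."""
    r = entry["rois"]
    rad = r.get("radius", ROI_RADIUS)
    return SessionROIs(
        vsst_target=ROISpec(np.array(r["vsst_target"]), rad),
        mct_targets=[ROISpec(np.array(c), rad) for c in r["mct_targets"]],
        mct_correct_options=[ROISpec(np.array(c), rad)
                             for c in r["mct_correct_options"]],
    )
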