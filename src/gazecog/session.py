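"""Session data model and multimodal recording I/O.

A recording holds one subject's synchronized behavioral streams sampled at a
nominal 120 Hz: eleven oculomotor channels (two 3-D eye origins, the combined
3-D gaze point, two pupil diameters in mm), two eye-openness channels in
[0, 1], six facial blend-shape (FBS) intensity channels in [0, 1], a per-sample
task label and trial index, and timestamps in seconds.

The on-disk format is a plain CSV with one header row and the fixed column
order ``t, task, trial, lox, loy, loz, rox, roy, roz, gx, gy, gz, pl, pr,
ol, or_, fbs1..fbs6``. Missing samples (e.g. tracker dropout during a blink)
are stored as NaN.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SAMPLING_RATE = 120.0
FACIAL_RATE = 60.0

#: channel counts used throughout: 11 oculomotor + 6 facial blend shapes
N_EYE_CHANNELS = 11
N_FBS_CHANNELS = 6

NUMERIC_COLUMNS = [
    "t",
    "lox", "loy", "loz",
    "rox", "roy", "roz",
    "gx", "gy", "gz",
    "pl", "pr",
    "ol", "or_",
    "fbs1", "fbs2", "fbs3", "fbs4", "fbs5", "fbs6",
]
COLUMNS = ["t", "task", "trial"] + NUMERIC_COLUMNS[1:]


class Group(str, enum.Enum):
    HC = "HC"
    CD = "CD"


class Task(str, enum.Enum):
    """The five assessment paradigms plus the between-task filler label."""

    VSST = "VSST"  # visual short-term memory and search
    MCT = "MCT"    # memory calculation
    PRT = "PRT"    # pupillary response (light reflex)
    ST = "ST"      # saccade task (pro- and anti-saccades)
    FET = "FET"    # facial emotion expression
    NONE = "NONE"


class Phase(str, enum.Enum):
    MEMORIZE = "memorize"
    SEARCH = "search"
    CALCULATE = "calculate"
    FIXATE = "fixate"
    STIMULUS = "stimulus"
    CENTRAL = "central"
    PERIPHERAL = "peripheral"
    EXPRESSION = "expression"


#: Nominal phase durations (seconds) per trial of each paradigm. PRT's 1-s
#: light stimulus occupies the final second of the 5-s fixation, so the
#: fixate phase is listed as 4 s followed by a 1 s stimulus phase.
TASK_TIMING: dict[Task, list[tuple[Phase, float]]] = {
    Task.VSST: [(Phase.MEMORIZE, 3.0), (Phase.SEARCH, 8.0)],
    Task.MCT: [(Phase.MEMORIZE, 3.0), (Phase.SEARCH, 10.0), (Phase.CALCULATE, 5.0)],
    Task.PRT: [(Phase.FIXATE, 4.0), (Phase.STIMULUS, 1.0)],
    Task.ST: [(Phase.CENTRAL, 2.0), (Phase.PERIPHERAL, 2.0)],
    Task.FET: [(Phase.EXPRESSION, 5.0)],
}

#: Trials per paradigm: VSST single trial, MCT and PRT and FET two trials,
#: ST 6 pro-saccade + 6 anti-saccade trials.
TASK_TRIALS: dict[Task, int] = {
    Task.VSST: 1,
    Task.MCT: 2,
    Task.PRT: 2,
    Task.ST: 12,
    Task.FET: 2,
}


class SchemaError(ValueError):
    """A session file does not conform to the documented column schema."""


class ValidationError(ValueError):
    """A recording violates a structural invariant."""


@dataclass
class SessionRecording:
    """One subject's synchronized multimodal streams with task labels.

    All array fields share a single length; ``eye_origin_*``, ``gaze_point``
    are ``(n, 3)``; ``fbs`` is ``(n, 6)``; the rest are ``(n,)``.
    """

    subject_id: str
    group: Group
    timestamps: np.ndarray
    eye_origin_left: np.ndarray
    eye_origin_right: np.ndarray
    gaze_point: np.ndarray
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    openness_left: np.ndarray
    openness_right: np.ndarray
    fbs: np.ndarray
    task_label: np.ndarray  # array of str
    trial_index: np.ndarray  # array of int

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.timestamps)

    def validate(self) -> None:
        n = len(self.timestamps)
        shapes = {
            "eye_origin_left": (n, 3), "eye_origin_right": (n, 3),
            "gaze_point": (n, 3), "fbs": (n, N_FBS_CHANNELS),
            "pupil_left": (n,), "pupil_right": (n,),
            "openness_left": (n,), "openness_right": (n,),
            "task_label": (n,), "trial_index": (n,),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if tuple(arr.shape) != shape:
                raise ValidationError(f"{name}: expected shape {shape}, got {arr.shape}")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        for name in ("openness_left", "openness_right"):
            vals = getattr(self, name)
            ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
            if not ok.all():
                raise ValidationError(f"{name} outside [0, 1]")
        ok = np.isnan(self.fbs) | ((self.fbs >= 0.0) & (self.fbs <= 1.0))
        if not ok.all():
            raise ValidationError("fbs outside [0, 1]")
        for name in ("pupil_left", "pupil_right"):
            vals = getattr(self, name)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValidationError(f"{name} must be positive where valid")
        labels = set(np.unique(self.task_label))
        unknown = labels - {t.value for t in Task}
        if unknown:
            raise ValidationError(f"unknown task labels: {sorted(unknown)}")

    def copy(self) -> "SessionRecording":
        kwargs = {
            f: (getattr(self, f).copy() if isinstance(getattr(self, f), np.ndarray)
                else getattr(self, f))
            for f in self.__dataclass_fields__
        }
        return SessionRecording(**kwargs)

    def eye_matrix(self) -> np.ndarray:
        """Stack the 11 oculomotor channels into a ``(11, n)`` matrix."""
        return np.vstack([
            self.eye_origin_left.T, self.eye_origin_right.T,
            self.gaze_point.T, self.pupil_left, self.pupil_right,
        ])

    def full_matrix(self) -> np.ndarray:
        """``(17, n)`` matrix of the 11 eye + 6 facial channels."""
        return np.vstack([self.eye_matrix(), self.fbs.T])


@dataclass
class TaskSegment:
    """A (task, trial, phase) span of a recording; ranges are half-open."""

    task: Task
    trial: int
    phase: Phase
    sample_range: tuple[int, int]
    recording: SessionRecording

    @property
    def start(self) -> int:
        return self.sample_range[0]

    @property
    def stop(self) -> int:
        return self.sample_range[1]

    @property
    def n_samples(self) -> int:
        return self.stop - self.start

    @property
    def duration(self) -> float:
        return self.n_samples / SAMPLING_RATE

    @property
    def timestamps(self) -> np.ndarray:
        return self.recording.timestamps[self.start:self.stop]

    def channel(self, name: str) -> np.ndarray:
        return getattr(self.recording, name)[self.start:self.stop]


@dataclass
class SubjectCovariates:
    """Demographics plus the ten granular MoCA-B item scores (total 0-30)."""

    subject_id: str
    group: Group
    age: float
    sex: str  # "F" / "M"
    education: float
    moca_sub: np.ndarray  # 10 item scores
    moca_total: float

    def __post_init__(self) -> None:
        self.moca_sub = np.asarray(self.moca_sub, dtype=float)
        if self.moca_sub.shape != (10,):
            raise ValidationError("moca_sub must have exactly 10 entries")
        if not 0.0 <= self.moca_total <= 30.0:
            raise ValidationError("moca_total outside [0, 30]")


# ---------------------------------------------------------------------------
# I/O

def read_session(path: str | Path, subject_id: str | None = None,
                 group: Group | str = Group.HC) -> SessionRecording:
    """Read a session CSV into a validated :class:`SessionRecording`.

    Raises :class:`SchemaError` if a mandatory column is missing and
    :class:`ValidationError` (with offending row numbers where possible)
    for structural violations such as non-monotone timestamps.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    t = df["t"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: one for the diff offset, one for the CSV header line
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise ValidationError(
            f"{path.name}: non-monotone timestamps at data line(s) {lines}")
    g = lambda c: df[c].to_numpy(dtype=float)
    xyz = lambda cs: np.column_stack([g(c) for c in cs])
    return SessionRecording(
        subject_id=subject_id or path.stem,
        group=Group(group),
        timestamps=t,
        eye_origin_left=xyz(["lox", "loy", "loz"]),
        eye_origin_right=xyz(["rox", "roy", "roz"]),
        gaze_point=xyz(["gx", "gy", "gz"]),
        pupil_left=g("pl"),
        pupil_right=g("pr"),
        openness_left=g("ol"),
        openness_right=g("or_"),
        fbs=np.column_stack([g(f"fbs{i}") for i in range(1, 7)]),
        task_label=df["task"].astype(str).to_numpy(),
        trial_index=df["trial"].to_numpy(dtype=int),
    )


def write_session(rec: SessionRecording, path: str | Path) -> None:
    """Write a recording to CSV with the canonical header order.

    ``read_session(write_session(rec))`` reproduces every numeric channel to
    better than 1e-9 (values are serialized with repr-level precision); NaN
    gap samples survive the round trip as empty cells.
    """
    df = pd.DataFrame({
        "t": rec.timestamps,
        "task": rec.task_label,
        "trial": rec.trial_index,
        "lox": rec.eye_origin_left[:, 0], "loy": rec.eye_origin_left[:, 1],
        "loz": rec.eye_origin_left[:, 2],
        "rox": rec.eye_origin_right[:, 0], "roy": rec.eye_origin_right[:, 1],
        "roz": rec.eye_origin_right[:, 2],
        "gx": rec.gaze_point[:, 0], "gy": rec.gaze_point[:, 1],
        "gz": rec.gaze_point[:, 2],
        "pl": rec.pupil_left, "pr": rec.pupil_right,
        "ol": rec.openness_left, "or_": rec.openness_right,
    })
    for i in range(N_FBS_CHANNELS):
        df[f"fbs{i + 1}"] = rec.fbs[:, i]
    df.to_csv(path, index=False, float_format="%.12g")


def read_covariates(path: str | Path) -> list[SubjectCovariates]:
    """Read the per-subject demographics/MoCA-B CSV."""
    df = pd.read_csv(path)
    required = (["subject_id", "group", "age", "sex", "education"]
                + [f"moca{i}" for i in range(1, 11)] + ["moca_total"])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"covariates file missing column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(SubjectCovariates(
            subject_id=str(row["subject_id"]),
            group=Group(row["group"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            education=float(row["education"]),
            moca_sub=np.array([row[f"moca{i}"] for i in range(1, 11)], dtype=float),
            moca_total=float(row["moca_total"]),
        ))
    return out


def write_covariates(covs: Sequence[SubjectCovariates], path: str | Path) -> None:
    rows = []
    for c in covs:
        row = {"subject_id": c.subject_id, "group": c.group.value, "age": c.age,
               "sex": c.sex, "education": c.education}
        row.update({f"moca{i + 1}": c.moca_sub[i] for i in range(10)})
        row["moca_total"] = c.moca_total
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Alignment and segmentation

def upsample_facial(face_stream: np.ndarray, target_len: int,
                    source_times: np.ndarray | None = None,
                    target_times: np.ndarray | None = None) -> np.ndarray:
    """Upsample a 60 Hz facial stream to 120 Hz by nearest-neighbor in time.

    ``face_stream`` is ``(n, 6)``. Each output sample takes the value of the
    source sample nearest in time (ties broken toward the earlier sample), so
    no new values are ever invented. With the default uniform clocks this
    duplicates each source sample twice: ``[a, b, c] -> [a, a, b, b, c, c]``.
    """
    face_stream = np.atleast_2d(np.asarray(face_stream, dtype=float))
    n_src = face_stream.shape[0]
    if n_src == 0:
        raise ValueError("empty facial stream")
    if not (abs(target_len - 2 * n_src) <= 1 or target_len == n_src):
        raise ValueError(
            f"target_len {target_len} is not ~2x the source length {n_src}")
    if source_times is None:
        source_times = np.arange(n_src) / FACIAL_RATE
    if target_times is None:
        target_times = np.arange(target_len) / SAMPLING_RATE
    # nearest source index per target time; "side=right" + the 0.5 midpoint
    # shift makes an exact tie resolve to the earlier sample
    idx = np.searchsorted(
        (source_times[1:] + source_times[:-1]) / 2.0, target_times, side="left")
    return face_stream[idx]


def segment_tasks(rec: SessionRecording,
                  timing: dict[Task, list[tuple[Phase, float]]] | None = None,
                  ) -> list[TaskSegment]:
    """Split a recording into (task, trial, phase) segments.

    Contiguous runs of one (task, trial) label become a trial span; phase
    boundaries inside the span are assigned from the nominal paradigm timing
    table because phase onsets are not logged. A trial shorter than its
    nominal phase budget gets truncated phases.
    """
    timing = timing or TASK_TIMING
    fs = SAMPLING_RATE
    segments: list[TaskSegment] = []
    labels = rec.task_label
    trials = rec.trial_index
    n = len(rec)
    i = 0
    while i < n:
        if labels[i] == Task.NONE.value:
            i += 1
            continue
        task = Task(labels[i])
        trial = int(trials[i])
        j = i
        while j < n and labels[j] == labels[i] and trials[j] == trial:
            j += 1
        phases = timing.get(task)
        if phases is None:
            raise ValidationError(f"no timing entry for task {task}")
        start = i
        for k, (phase, dur) in enumerate(phases):
            if start >= j:
                break
            stop = j if k == len(phases) - 1 else min(j, start + int(round(dur * fs)))
            if stop > start:
                segments.append(TaskSegment(task, trial, phase, (start, stop), rec))
            start = stop
        i = j
    return segments


def zero_fill_facial(rec: SessionRecording, segments: Sequence[TaskSegment],
                     ) -> SessionRecording:
    """Zero the facial channels everywhere outside the expression task.

    The first four paradigms collect only eye-tracking data; their facial
    channels are defined to be zero. Eye channels are untouched.
    """
    out = rec.copy()
    for seg in segments:
        if seg.task is not Task.FET:
            out.fbs[seg.start:seg.stop] = 0.0
    return out


def zero_fill_segment(seg: TaskSegment) -> TaskSegment:
    """Zero the facial channels of a single non-FET segment (in place)."""
    if seg.task is Task.FET:
        raise ValueError("facial channels of the expression task are real data")
    seg.recording.fbs[seg.start:seg.stop] = 0.0
    return seg
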