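"""Fixation/saccade segmentation of merged gaze with I-VDT.

I-VDT combines a velocity threshold (samples moving faster than ``v`` are
saccade candidates) with a dispersion test over a temporal window for the
remaining samples. Smooth pursuit is collapsed into fixation here: the
paradigms use stationary targets, so low-velocity samples that fail the
dispersion test are still treated as (unstable) fixation rather than given
a third class. Saccade candidate runs shorter than the minimum saccade
duration are demoted and merged into the flanking fixations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import MergedGaze, _angle_deg


@dataclass
class IVDTConfig:
    velocity_threshold: float = 30.0   # deg/s
    window: float = 0.130              # s, temporal window of the dispersion test
    dispersion_threshold: float = 2.0  # deg
    min_saccade_duration: float = 0.04  # s

    def __post_init__(self) -> None:
        if min(self.velocity_threshold, self.window,
               self.dispersion_threshold, self.min_saccade_duration) <= 0:
            raise ValueError("all I-VDT parameters must be positive")


class EventKind(str, enum.Enum):
    FIXATION = "fixation"
    SACCADE = "saccade"


@dataclass
class GazeEvent:
    kind: EventKind
    onset: float                 # s
    offset: float                # s
    sample_range: tuple[int, int]  # half-open, relative to the segmented span
    centroid: np.ndarray | None = None   # (3,), fixations
    amplitude: float = 0.0       # deg, saccades
    mean_velocity: float = 0.0   # deg/s, saccades
    peak_velocity: float = 0.0   # deg/s, saccades
    latency: float | None = None  # s relative to a stimulus onset, saccades

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _dispersion_deg(dirs: np.ndarray) -> float:
    """Max pairwise angle (deg) between unit direction vectors."""
    if len(dirs) < 2:
        return 0.0
    # the diameter pair touches the convex hull; at window sizes used here
    # (tens of samples) the direct O(n^2) evaluation is affordable
    dots = np.clip(dirs @ dirs.T, -1.0, 1.0)
    return float(np.degrees(np.arccos(dots.min())))


def ivdt_segment(gaze: MergedGaze, cfg: IVDTConfig | None = None,
                 ) -> list[GazeEvent]:
    """Tile a merged-gaze span with fixation and saccade events.

    Samples with velocity strictly above the threshold seed saccade runs;
    runs meeting the minimum duration become saccades, shorter runs are
    demoted. Inter-saccade spans are split into fixations by a greedy
    dispersion-window test: a window of at least ``cfg.window`` seconds with
    dispersion <= threshold is extended sample-by-sample while the test
    holds. Spans shorter than the window produce no event list entry only
    when the whole input is shorter than the window.
    """
    cfg = cfg or IVDTConfig()
    n = len(gaze)
    t = gaze.timestamps
    if n == 0 or (t[-1] - t[0]) < cfg.window:
        return []
    dt = float(np.median(np.diff(t)))
    win = max(2, int(round(cfg.window / dt)))
    min_sacc = max(1, int(round(cfg.min_saccade_duration / dt)))
    dirs = gaze.directions()

    fast = gaze.angular_velocity > cfg.velocity_threshold
    # saccade runs with sufficient duration; shorter runs demoted to fixation
    sacc_runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if fast[i]:
            j = i
            while j < n and fast[j]:
                j += 1
            if j - i >= min_sacc:
                sacc_runs.append((i, j))
            i = j
        else:
            i += 1

    events: list[GazeEvent] = []

    def add_fixations(a: int, b: int) -> None:
        """Split span [a, b) into fixations by the dispersion test."""
        if b - a <= 0:
            return
        s = a
        while s < b:
            if b - s < win and events and events[-1].kind is EventKind.FIXATION \
                    and events[-1].sample_range[1] == s:
                # residual shorter than the window: absorb into the previous
                # fixation outright (pursuit-like tails collapse to fixation)
                prev = events.pop()
                events.append(_make_fixation(gaze, prev.sample_range[0], b))
                return
            e = min(b, s + win)
            # grow while dispersion stays under threshold; the running max
            # pairwise angle is updated incrementally (O(n) per added sample)
            cur = _dispersion_deg(dirs[s:e])
            while e < b:
                new = np.degrees(np.arccos(np.clip(
                    dirs[s:e] @ dirs[e], -1.0, 1.0))).max()
                if max(cur, new) > cfg.dispersion_threshold:
                    break
                cur = max(cur, float(new))
                e += 1
            events.append(_make_fixation(gaze, s, e))
            s = e

    prev_end = 0
    for (a, b) in sacc_runs:
        add_fixations(prev_end, a)
        events.append(_make_saccade(gaze, dirs, a, b))
        prev_end = b
    add_fixations(prev_end, n)
    return events


def _make_fixation(gaze: MergedGaze, a: int, b: int) -> GazeEvent:
    t = gaze.timestamps
    offset = t[b] if b < len(t) else t[b - 1] + (t[-1] - t[-2] if len(t) > 1 else 0.0)
    return GazeEvent(
        kind=EventKind.FIXATION, onset=float(t[a]), offset=float(offset),
        sample_range=(a, b), centroid=gaze.endpoint[a:b].mean(axis=0))


def _make_saccade(gaze: MergedGaze, dirs: np.ndarray, a: int, b: int) -> GazeEvent:
    t = gaze.timestamps
    offset = t[b] if b < len(t) else t[b - 1] + (t[-1] - t[-2] if len(t) > 1 else 0.0)
    amp = float(_angle_deg(dirs[a:a + 1], dirs[min(b, len(dirs) - 1):
                                               min(b, len(dirs) - 1) + 1])[0])
    vel = gaze.angular_velocity[a:b]
    return GazeEvent(
        kind=EventKind.SACCADE, onset=float(t[a]), offset=float(offset),
        sample_range=(a, b), amplitude=amp,
        mean_velocity=float(vel.mean()), peak_velocity=float(vel.max()))


def saccade_metrics(event: GazeEvent, gaze: MergedGaze,
                    stimulus_onset: float) -> GazeEvent:
    """Attach latency (and refresh kinematics) of a saccade event.

    Latency is onset minus stimulus onset and may be negative; negative or
    sub-100 ms latencies are flagged anticipatory downstream, not here.
    """
    if event.kind is not EventKind.SACCADE:
        raise ValueError("saccade_metrics expects a saccade event")
    a, b = event.sample_range
    dirs = gaze.directions()
    event.amplitude = float(_angle_deg(dirs[a:a + 1],
                                       dirs[min(b, len(dirs) - 1):
                                            min(b, len(dirs) - 1) + 1])[0])
    vel = gaze.angular_velocity[a:b]
    event.mean_velocity = float(vel.mean())
    event.peak_velocity = float(vel.max())
    event.latency = event.onset - stimulus_onset
    return event


def filter_anticipatory(events: list[GazeEvent],
                        min_latency: float = 0.1) -> list[GazeEvent]:
    """Drop anticipatory saccades (latency < 100 ms); fixations pass through."""
    out = []
    for ev in events:
        if ev.kind is EventKind.SACCADE and ev.latency is not None \
                and ev.latency < min_latency:
            continue
        out.append(ev)
    return out


def events_table(events: list[GazeEvent]) -> pd.DataFrame:
    """Export events as a tab-separable table."""
    return pd.DataFrame([{
        "onset": ev.onset, "offset": ev.offset, "kind": ev.kind.value,
        "amplitude": ev.amplitude, "mean_velocity": ev.mean_velocity,
        "peak_velocity": ev.peak_velocity, "latency": ev.latency,
    } for ev in events])
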