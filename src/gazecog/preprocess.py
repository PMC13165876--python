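"""Signal conditioning for the multimodal streams.

The fixed pipeline is: blink detection on the binocular eye-openness
channels -> linear interpolation of the masked gaps on pupil, gaze and
origin channels -> causal 2nd-order Butterworth low-pass on the pupil
diameters (cutoff 1/8 of the sampling rate) -> cyclopean gaze merging with
angular velocity -> Gaussian smoothing (sigma = 2 samples) of the facial
blend-shape channels. Z-scoring of model inputs uses statistics estimated
on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .session import SAMPLING_RATE, SessionRecording


@dataclass
class PreprocessConfig:
    blink_threshold: float = 0.9       # tau: openness below this marks a blink
    butterworth_order: int = 2
    cutoff_frac: float = 1.0 / 8.0     # fraction of the sampling rate
    gaussian_sigma: float = 2.0        # samples
    sampling_rate: float = SAMPLING_RATE

    def __post_init__(self) -> None:
        if not 0.0 < self.blink_threshold <= 1.0:
            raise ValueError("blink_threshold must be in (0, 1]")
        if not 0.0 < self.cutoff_frac < 0.5:
            raise ValueError("cutoff_frac must be in (0, 0.5)")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")


@dataclass
class FilterSpec:
    """Coefficients of the recursive low-pass ``y[n] = (1/omega) * sum_i h[i]
    x[n-i] - sum_j g[j] y[n-j]`` with orders p = len(h)-1, q = len(g)."""

    h: np.ndarray
    g: np.ndarray
    omega: float = 1.0

    @classmethod
    def butterworth(cls, order: int = 2, cutoff_frac: float = 1.0 / 8.0,
                    fs: float = SAMPLING_RATE) -> "FilterSpec":
        """Standard bilinear-transform Butterworth design.

        ``cutoff_frac`` is the cutoff as a fraction of the sampling rate, so
        the default places it at fs/8 (15 Hz at 120 Hz sampling).
        """
        b, a = signal.butter(order, cutoff_frac * fs, btype="low", fs=fs)
        # a[0] is 1 after scipy normalization; keep omega explicit anyway
        return cls(h=np.asarray(b) * a[0], g=np.asarray(a[1:]), omega=float(a[0]))


def detect_blinks(openness_left: np.ndarray, openness_right: np.ndarray,
                  tau: float = 0.9) -> np.ndarray:
    """Mark samples where either eye's openness drops below ``tau``.

    Blinks corrupt both the gaze estimate and the pupil diameter, so a
    single-eye closure is enough to flag the sample.
    """
    ol = np.asarray(openness_left, dtype=float)
    orr = np.asarray(openness_right, dtype=float)
    if ol.shape != orr.shape:
        raise ValueError("openness series must have equal length")
    if ol.size == 0:
        raise ValueError("empty openness series")
    return np.fmin(ol, orr) < tau


def interpolate_gaps(series: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked samples by linear interpolation between valid flanks.

    Leading/trailing gaps are filled by holding the nearest valid value.
    Unmasked samples are returned unchanged. NaNs inside the masked region
    are permitted (tracker dropout); NaNs outside it are treated as masked.
    """
    x = np.asarray(series, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool) | ~np.isfinite(x)
    if mask.all():
        raise ValueError("cannot interpolate a fully masked series")
    if not mask.any():
        return x
    idx = np.arange(x.size)
    valid = ~mask
    x[mask] = np.interp(idx[mask], idx[valid], x[valid])
    return x


def butterworth_smooth(x: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Causal recursive low-pass filtering of a repaired series.

    Uses the direct-form difference equation realized by ``scipy.signal
    .lfilter``; the recursion is causal, so all latency-type features inherit
    the same group delay in both groups.
    """
    spec = spec or FilterSpec.butterworth()
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("series too short to filter")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input; repair gaps before filtering")
    b = np.asarray(spec.h, dtype=float) / spec.omega
    a = np.concatenate([[1.0], np.asarray(spec.g, dtype=float)])
    # plain causal recursion with zero initial state, exactly the
    # difference-equation form; the start-up transient decays within ~10
    # samples at the default cutoff
    return signal.lfilter(b, a, x)


@dataclass
class MergedGaze:
    """Cyclopean gaze: per-sample endpoint, origin and angular velocity."""

    endpoint: np.ndarray          # (n, 3) m
    cyclopean_origin: np.ndarray  # (n, 3) m
    angular_velocity: np.ndarray  # (n,) deg/s, nonnegative
    timestamps: np.ndarray        # (n,) s

    def directions(self) -> np.ndarray:
        """Unit gaze direction vectors from the cyclopean origin."""
        d = self.endpoint - self.cyclopean_origin
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        return d / np.where(norm == 0, 1.0, norm)

    def __len__(self) -> int:
        return len(self.timestamps)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle in degrees between rows of two unit-vector arrays."""
    dot = np.clip(np.einsum("ij,ij->i", u, v), -1.0, 1.0)
    return np.degrees(np.arccos(dot))


def merge_gaze(rec: SessionRecording, start: int = 0, stop: int | None = None,
               ) -> MergedGaze:
    """Merge the binocular line of sight and compute angular velocity.

    The cyclopean origin is the midpoint of the two eye origins; the merged
    endpoint is the recorded combined gaze point. Velocity at sample *i* is
    the central-difference angle subtended at the origin between endpoints
    *i-1* and *i+1*, divided by the spanned time; edges use one-sided
    differences. Degenerate (zero-length) directions yield interpolated
    velocities.
    """
    stop = len(rec) if stop is None else stop
    t = rec.timestamps[start:stop]
    origin = 0.5 * (rec.eye_origin_left[start:stop] + rec.eye_origin_right[start:stop])
    endpoint = rec.gaze_point[start:stop].astype(float)
    d = endpoint - origin
    norm = np.linalg.norm(d, axis=1)
    bad = norm < 1e-12
    dirs = d / np.where(norm[:, None] == 0, 1.0, norm[:, None])
    n = len(t)
    vel = np.zeros(n)
    if n >= 2:
        if n >= 3:
            ang = _angle_deg(dirs[2:], dirs[:-2])
            vel[1:-1] = ang / (t[2:] - t[:-2])
        vel[0] = _angle_deg(dirs[1:2], dirs[0:1])[0] / (t[1] - t[0])
        vel[-1] = _angle_deg(dirs[-1:], dirs[-2:-1])[0] / (t[-1] - t[-2])
    if bad.any() and not bad.all():
        vel = interpolate_gaps(vel, bad)
    return MergedGaze(endpoint=endpoint, cyclopean_origin=origin,
                      angular_velocity=np.abs(vel), timestamps=t)


def gaussian_smooth(fbs: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Smooth facial blend-shape channels with a normalized Gaussian kernel.

    The kernel is truncated at 4 sigma with reflect padding, so constant
    signals pass through unchanged. Accepts ``(n,)`` or ``(n, c)`` input.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(fbs, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return ndimage.gaussian_filter1d(x, sigma=sigma, axis=0, mode="reflect",
                                     truncate=4.0)


def zscore_channels(X: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None,
                    ) -> np.ndarray:
    """Standardize a ``(C, L)`` matrix per channel.

    ``stats`` is a ``(mean, sd)`` pair estimated on the training split; when
    omitted, statistics are computed from ``X`` itself. Channels with zero
    spread are centered only.
    """
    X = np.asarray(X, dtype=float)
    if stats is None:
        mean = X.mean(axis=1)
        sd = X.std(axis=1)
    else:
        mean, sd = (np.asarray(s, dtype=float) for s in stats)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean[:, None]) / sd_safe[:, None]


def channel_stats(Xs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-channel mean/sd over a list of ``(C, L_i)`` matrices."""
    cat = np.concatenate(Xs, axis=1)
    return cat.mean(axis=1), cat.std(axis=1)


def preprocess_recording(rec: SessionRecording, cfg: PreprocessConfig | None = None,
                         ) -> tuple[SessionRecording, np.ndarray]:
    """Run the full conditioning pipeline on a recording.

    Returns the repaired/filtered copy and the blink mask. The blink mask is
    applied jointly to pupil, gaze-point and eye-origin channels; the pupil
    diameters are then low-pass filtered and the facial channels Gaussian
    smoothed.
    """
    cfg = cfg or PreprocessConfig()
    out = rec.copy()
    mask = detect_blinks(rec.openness_left, rec.openness_right,
                         cfg.blink_threshold)
    spec = FilterSpec.butterworth(cfg.butterworth_order, cfg.cutoff_frac,
                                  cfg.sampling_rate)
    for name in ("pupil_left", "pupil_right"):
        repaired = interpolate_gaps(getattr(out, name), mask)
        setattr(out, name, butterworth_smooth(repaired, spec))
    for name in ("gaze_point", "eye_origin_left", "eye_origin_right"):
        arr = getattr(out, name)
        for k in range(3):
            arr[:, k] = interpolate_gaps(arr[:, k], mask)
    out.fbs = gaussian_smooth(np.nan_to_num(out.fbs), cfg.gaussian_sigma)
    np.clip(out.fbs, 0.0, 1.0, out=out.fbs)
    return out, mask
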