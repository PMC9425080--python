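"""Trunk-accelerometer signal conditioning and gait-event detection.

The processing chain for one walking trial is:

    transform_axes -> tilt_correct -> lowpass_filter -> split_segments
        -> detect_gait_events (per direction segment)

Axes follow the ISB convention (anteroposterior, mediolateral, vertical;
vertical positive up, in g).  Event detection follows the wavelet scheme
of McCamley-type detectors: the gravity-free vertical acceleration is
smoothed by cumulative integration, differentiated with a Gaussian
continuous wavelet transform (initial contacts at the minima), and
differentiated once more (final contacts at the peaks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import integrate
from scipy.signal import butter, filtfilt, find_peaks, welch

__all__ = [
    "AccelerationRecording",
    "GaitEvents",
    "InsufficientStridesError",
    "transform_axes",
    "tilt_correct",
    "lowpass_filter",
    "split_segments",
    "detect_gait_events",
]

AXES = ("ap", "ml", "v")


class InsufficientStridesError(ValueError):
    """Raised when too few gait events can be recovered from a signal."""


@dataclass
class AccelerationRecording:
    """Tri-axial trunk acceleration time series, in g.

    ``samples`` has shape (n, 3) with columns (anteroposterior,
    mediolateral, vertical); ``t`` holds uniformly spaced timestamps in
    seconds.
    """

    t: np.ndarray
    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    task: str = ""
    gravity_free: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if len(self.t) != len(self.samples):
            raise ValueError("t and samples length mismatch")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.abs(dt - 1.0 / self.sampling_rate).max() \
                    > 0.5 / self.sampling_rate:
                raise ValueError("non-uniform sampling")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    @property
    def vertical(self) -> np.ndarray:
        return self.samples[:, 2]

    def copy_with(self, **kw) -> "AccelerationRecording":
        base = dict(t=self.t, samples=self.samples,
                    sampling_rate=self.sampling_rate,
                    subject_id=self.subject_id, task=self.task,
                    gravity_free=self.gravity_free)
        base.update(kw)
        return AccelerationRecording(**base)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "ax": self.samples[:, 0],
                             "ay": self.samples[:, 1],
                             "az": self.samples[:, 2]})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, sampling_rate: float | None = None,
                 **kw) -> "AccelerationRecording":
        df = pd.read_csv(path)
        required = {"t", "ax", "ay", "az"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        t = df["t"].to_numpy(dtype=float)
        if sampling_rate is None:
            sampling_rate = 1.0 / float(np.median(np.diff(t)))
        return cls(t=t, samples=df[["ax", "ay", "az"]].to_numpy(float),
                   sampling_rate=sampling_rate, **kw)


@dataclass
class GaitEvents:
    """Ordered initial/final contacts with alternating foot labels.

    Between consecutive initial contacts (IC) there is exactly one final
    contact (FC): the toe-off of the foot entering swing.  Foot labels
    are arbitrary names (F1 = foot of the first detected IC).
    """

    ic_times: np.ndarray
    fc_times: np.ndarray
    foot_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        if not self.foot_labels:
            self.foot_labels = tuple(
                "F1" if i % 2 == 0 else "F2"
                for i in range(len(self.ic_times)))
        self.validate()

    def validate(self) -> None:
        ic, fc = self.ic_times, self.fc_times
        if np.any(np.diff(ic) <= 0) or np.any(np.diff(fc) <= 0):
            raise ValueError("event times must be strictly increasing")
        if len(self.foot_labels) != len(ic):
            raise ValueError("foot labels must align with initial contacts")
        for a, b in zip(self.foot_labels, self.foot_labels[1:]):
            if a == b:
                raise ValueError("foot labels must alternate strictly")
        if len(fc) != max(len(ic) - 1, 0):
            raise ValueError("expected one final contact per step interval")
        if len(fc) and (np.any(fc <= ic[:-1]) or np.any(fc >= ic[1:])):
            raise ValueError("each final contact must lie between "
                             "consecutive initial contacts")

    @property
    def n_steps(self) -> int:
        return max(len(self.ic_times) - 1, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [("IC", t, f) for t, f in zip(self.ic_times, self.foot_labels)]
        # FC between IC_i and IC_{i+1} is the toe-off of the foot striking
        # at IC_{i+1} (the one leaving the ground to swing forward)
        rows += [("FC", t, self.foot_labels[i + 1])
                 for i, t in enumerate(self.fc_times)]
        rows.sort(key=lambda r: r[1])
        return pd.DataFrame(rows, columns=["event", "time", "foot"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GaitEvents":
        ic = df[df["event"] == "IC"].sort_values("time")
        fc = df[df["event"] == "FC"].sort_values("time")
        return cls(ic_times=ic["time"].to_numpy(float),
                   fc_times=fc["time"].to_numpy(float),
                   foot_labels=tuple(ic["foot"]))


def transform_axes(recording: AccelerationRecording,
                   mapping: np.ndarray) -> AccelerationRecording:
    """Apply a signed axis permutation so device axes follow ISB order.

    ``mapping`` is a 3x3 signed permutation matrix; output sample i is
    ``mapping @ sample_i``.
    """
    M = np.asarray(mapping, dtype=float)
    if M.shape != (3, 3) or not np.array_equal(np.abs(M) @ np.abs(M.T),
                                               np.eye(3)):
        raise ValueError("mapping must be a signed permutation of 3 axes")
    return recording.copy_with(samples=recording.samples @ M.T)


def tilt_correct(recording: AccelerationRecording,
                 min_gravity: float = 0.05) -> AccelerationRecording:
    """Dynamic tilt correction (Moe-Nilssen style) and gravity removal.

    The mean acceleration vector estimates the gravity direction; samples
    are rotated so that the mean horizontal accelerations vanish and the
    mean gravity lies on the vertical axis, then 1 g is subtracted from
    the vertical channel.  A recording whose mean vector is already small
    (< 0.5 g) is taken to be gravity-free and returned unchanged, which
    makes the correction idempotent; a mean below ``min_gravity`` g with
    gravity still expected indicates free fall and is rejected.
    """
    if recording.duration < 2.0:
        raise ValueError("need at least 2 s of data for tilt estimation")
    m = recording.samples.mean(axis=0)
    norm = float(np.linalg.norm(m))
    if norm < min_gravity and not recording.gravity_free:
        raise ValueError("mean acceleration near zero: free fall or "
                         "gravity already removed")
    if norm < 0.5:
        return recording.copy_with(gravity_free=True)
    # rotation taking the unit mean vector onto +vertical (Rodrigues)
    u = m / norm
    ez = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, ez)
    s, c = np.linalg.norm(v), float(u @ ez)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s ** 2)
    rotated = recording.samples @ R.T
    rotated[:, 2] -= 1.0
    return recording.copy_with(samples=rotated, gravity_free=True)


def lowpass_filter(recording_or_signal, sampling_rate: float | None = None,
                   cutoff: float = 3.0, order: int = 4):
    """Zero-lag low-pass Butterworth (forward-backward application).

    Accepts either an :class:`AccelerationRecording` (all axes filtered)
    or a plain 1-D array with ``sampling_rate`` given.
    """
    if isinstance(recording_or_signal, AccelerationRecording):
        rec = recording_or_signal
        fs = rec.sampling_rate
        if cutoff >= fs / 2:
            raise ValueError("cutoff must be below the Nyquist frequency")
        b, a = butter(order, cutoff, fs=fs)
        return rec.copy_with(samples=filtfilt(b, a, rec.samples, axis=0))
    x = np.asarray(recording_or_signal, dtype=float)
    if sampling_rate is None:
        raise ValueError("sampling_rate required for array input")
    if cutoff >= sampling_rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = butter(order, cutoff, fs=sampling_rate)
    return filtfilt(b, a, x)


def split_segments(recording: AccelerationRecording, trim: float = 3.0,
                   min_gap: float = 1.0, rms_fraction: float = 0.2
                   ) -> tuple[AccelerationRecording, AccelerationRecording]:
    """Split a two-direction walk at the turn and trim the segment edges.

    The turn is located as a sustained (>= ``min_gap`` s) window where the
    moving RMS of the gravity-free vertical dynamics drops below
    ``rms_fraction`` of the whole-recording RMS; the split point is the
    midpoint of that window.  The first and last ``trim`` seconds of each
    resulting segment are then removed.
    """
    fs = recording.sampling_rate
    v = recording.vertical - recording.vertical.mean()
    n_win = max(int(round(min_gap * fs)), 1)
    power = np.convolve(v ** 2, np.ones(n_win) / n_win, mode="same")
    moving_rms = np.sqrt(power)
    threshold = rms_fraction * np.sqrt(np.mean(v ** 2))
    quiet = moving_rms < threshold
    # longest run of quiet samples
    edges = np.diff(np.concatenate(([0], quiet.astype(int), [0])))
    starts, ends = np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)
    runs = [(s, e) for s, e in zip(starts, ends) if (e - s) >= n_win]
    if not runs:
        raise ValueError("no low-activity turn window found: cannot split "
                         "the recording into direction segments")
    s, e = max(runs, key=lambda r: r[1] - r[0])
    split = (s + e) // 2
    out = []
    for sl in (slice(0, split), slice(split, len(v))):
        seg_t = recording.t[sl]
        if seg_t[-1] - seg_t[0] < 2 * trim:
            raise ValueError(
                f"segment of {seg_t[-1] - seg_t[0]:.1f} s is shorter than "
                f"twice the {trim:.1f} s trim margin")
        keep = (seg_t >= seg_t[0] + trim) & (seg_t <= seg_t[-1] - trim)
        out.append(recording.copy_with(t=seg_t[keep],
                                       samples=recording.samples[sl][keep]))
    return out[0], out[1]


def _dominant_step_frequency(x: np.ndarray, fs: float,
                             band: tuple[float, float] = (0.5, 4.0)) -> float:
    """Spectral peak of the vertical dynamics within a walking band (Hz)."""
    nper = min(len(x), int(fs * 8))
    f, p = welch(x - x.mean(), fs=fs, nperseg=nper)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any() or p[sel].max() <= 0:
        return 2.0
    return float(f[sel][np.argmax(p[sel])])


def _cwt_derivative(x: np.ndarray, scale: float, fs: float) -> np.ndarray:
    """Smoothed derivative via a first-order Gaussian wavelet transform.

    The sign is normalized so the output approximates + d/dt of the
    Gaussian-smoothed input (wavelet sign conventions differ between
    implementations).
    """
    coeffs, _ = pywt.cwt(x, [scale], "gaus1", sampling_period=1.0 / fs)
    d = coeffs[0]
    ref = np.gradient(x) * fs
    if np.dot(d, ref) < 0:
        d = -d
    return d


def detect_gait_events(vertical_signal, sampling_rate: float | None = None,
                       wavelet_scale: float | None = None,
                       t0: float = 0.0,
                       min_step: float = 0.25, max_step: float = 2.0
                       ) -> GaitEvents:
    """Detect initial and final contacts from gravity-free vertical accel.

    The signal is smoothed by cumulative-trapezoid integration (zero-mean
    integration constant), then differentiated twice with a Gaussian
    continuous wavelet transform; initial contacts are the minima of the
    first derivative and final contacts the peaks of the second.  The
    wavelet scale defaults to one matched to the dominant step frequency.
    Intervals shorter than ``min_step`` s are merged (the weaker event is
    dropped); gaps longer than ``max_step`` s are flagged with a warning.

    Accepts either an :class:`AccelerationRecording` (its vertical axis is
    used, ``t0`` taken from its timestamps) or a 1-D array with
    ``sampling_rate``.
    """
    if isinstance(vertical_signal, AccelerationRecording):
        rec = vertical_signal
        x = rec.vertical
        sampling_rate = rec.sampling_rate
        t0 = float(rec.t[0]) if len(rec.t) else 0.0
    else:
        x = np.asarray(vertical_signal, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for array input")
    fs = sampling_rate
    if len(x) < int(fs):
        raise InsufficientStridesError("signal too short")
    x = x - x.mean()
    if np.sqrt(np.mean(x ** 2)) < 1e-9:
        raise InsufficientStridesError("insufficient strides: flat signal")
    v = integrate.cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
    v -= v.mean()
    if wavelet_scale is None:
        f_step = _dominant_step_frequency(x, fs)
        wavelet_scale = pywt.central_frequency("gaus1") * fs / f_step
    d1 = _cwt_derivative(v, wavelet_scale, fs)   # ~ smoothed acceleration
    d2 = _cwt_derivative(d1, wavelet_scale, fs)  # ~ smoothed jerk
    dist = max(int(min_step * fs), 1)
    prom1 = 0.25 * np.std(d1)
    ic_idx, _ = find_peaks(-d1, distance=dist, prominence=prom1)
    if len(ic_idx) < 4:
        raise InsufficientStridesError(
            f"insufficient strides: {len(ic_idx)} initial contacts found")
    steps = np.diff(ic_idx) / fs
    if np.any(steps > max_step):
        warnings.warn("step interval above the physiological gate "
                      f"({max_step:.2f} s): possible missed contacts",
                      stacklevel=2)
    fc_idx, fc_props = find_peaks(d2, prominence=0.05 * np.std(d2))
    fc_prom = fc_props["prominences"]
    fc_times = []
    offsets = []
    for a, b in zip(ic_idx[:-1], ic_idx[1:]):
        inside = np.flatnonzero((fc_idx > a) & (fc_idx < b))
        if len(inside):
            best = inside[np.argmax(fc_prom[inside])]
            fc_times.append(fc_idx[best] / fs)
            offsets.append((fc_idx[best] - a) / fs)
        else:
            fc_times.append(np.nan)
    # a missing final contact is imputed at the median IC->FC offset so
    # the interleaving invariant holds; flagged by the imputation count
    med = np.median(offsets) if offsets else 0.25 * float(np.median(steps))
    for i, (a, b) in enumerate(zip(ic_idx[:-1], ic_idx[1:])):
        if np.isnan(fc_times[i]):
            fc_times[i] = min(a / fs + med, (a + 0.9 * (b - a)) / fs)
    return GaitEvents(ic_times=t0 + ic_idx / fs,
                      fc_times=t0 + np.asarray(fc_times))
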