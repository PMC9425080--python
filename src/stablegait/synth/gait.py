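"""Synthetic trunk-acceleration walks with ground-truth gait events.

Each walking direction is a train of per-step waveforms: two harmonics of
the step cycle (fundamental at the step frequency), with the waveform
minimum at the step onset, i.e. at the initial contact.  Step intervals
are i.i.d. around the profile mean with the profile's coefficient of
variation, alternating feet carry an asymmetry ratio, and the signal is
scaled so its RMS after the 3 Hz low-pass equals the profile RMS.  The
two directions are joined by a low-amplitude turn gap, gravity and a
small static tilt are applied to all three axes, and white sensor noise
is added.  This is a phenomenological signal model built to exercise the
event detector and feature extractor, not a biomechanical simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..signal import AccelerationRecording, GaitEvents, lowpass_filter

TASKS = ("NormalW", "EasyD", "HardD", "FastW")
DUAL_TASKS = ("EasyD", "HardD")

# second-harmonic relative amplitude of the per-step waveform
_H2 = 0.25


@dataclass(frozen=True)
class GaitProfile:
    """Planted spatio-temporal gait characteristics for one task."""

    mean_step_time: float        # s
    step_time_cov: float         # percent
    accel_rms: float             # g, after 3 Hz low-pass
    step_length: float           # m
    asymmetry_ratio: float = 1.0   # F1/F2 step-time ratio, >= 1
    double_support_frac: float = 0.125  # fraction of stride time

    def __post_init__(self) -> None:
        if self.mean_step_time <= 0 or self.accel_rms <= 0 \
                or self.step_length <= 0:
            raise ValueError("durations, RMS and step length must be > 0")
        if self.step_time_cov < 0:
            raise ValueError("step-time CoV must be >= 0")
        if not 0 < self.double_support_frac < 0.5:
            raise ValueError("double-support fraction must be in (0, 0.5)")
        if self.asymmetry_ratio < 1.0:
            raise ValueError("asymmetry ratio is defined >= 1")


# NormalW profiles per group; magnitudes chosen for clear but overlapping
# group separation (variability MCI-E > HE > YA; RMS/speed YA > HE > MCI-E)
BASE_PROFILES = {
    "YA": GaitProfile(0.52, 2.0, 0.20, 0.66, 1.02, 0.115),
    "HE": GaitProfile(0.55, 2.6, 0.18, 0.62, 1.04, 0.125),
    "MCI-E": GaitProfile(0.58, 4.0, 0.15, 0.57, 1.06, 0.14),
}

# multiplicative task modifiers: (step_time, cov, rms, step_length)
# cov modifiers for dual tasks depend on group (dual-task interference
# grows with impairment)
_TASK_MODS = {
    "NormalW": (1.00, 1.00, 1.00, 1.00),
    "FastW": (0.85, 0.90, 1.35, 1.08),
    "EasyD": (1.04, None, 0.95, 0.97),
    "HardD": (1.10, None, 0.90, 0.93),
}
_DUAL_COV_MODS = {
    "EasyD": {"YA": 1.10, "HE": 1.25, "MCI-E": 1.45},
    "HardD": {"YA": 1.20, "HE": 1.50, "MCI-E": 1.90},
}


def subject_profiles(group: str, rng: np.random.Generator
                     ) -> dict[str, GaitProfile]:
    """Draw one subject's per-task gait profiles around the group means.

    Subject-level lognormal variation is shared across tasks so that the
    same person is consistently slow/variable, with a small extra
    task-level jitter.
    """
    base = BASE_PROFILES[group]
    subj = {
        "time": float(np.exp(rng.normal(0, 0.085))),
        "cov": float(np.exp(rng.normal(0, 0.30))),
        "rms": float(np.exp(rng.normal(0, 0.14))),
        "len": float(np.exp(rng.normal(0, 0.11))),
    }
    out = {}
    for task in TASKS:
        mt, mc, mr, ml = _TASK_MODS[task]
        if mc is None:
            mc = _DUAL_COV_MODS[task][group]
        # task-level latent variability: the same person fluctuates
        # between trials, so extra tasks are not free extra precision
        jt = float(np.exp(rng.normal(0, 0.05)))
        jc = float(np.exp(rng.normal(0, 0.12)))
        jr = float(np.exp(rng.normal(0, 0.07)))
        jl = float(np.exp(rng.normal(0, 0.06)))
        out[task] = replace(
            base,
            mean_step_time=base.mean_step_time * mt * subj["time"] * jt,
            step_time_cov=base.step_time_cov * mc * subj["cov"] * jc,
            accel_rms=base.accel_rms * mr * subj["rms"] * jr,
            step_length=base.step_length * ml * subj["len"] * jl,
        )
    return out


def _step_waveform(phase: np.ndarray) -> np.ndarray:
    """Per-step vertical shape with its minimum at phase 0 (the IC)."""
    return -(np.cos(2 * np.pi * phase) + _H2 * np.cos(4 * np.pi * phase))


def _direction_segment(profile: GaitProfile, n_steps: int, fs: float,
                       rng: np.random.Generator):
    """One direction of walking: (vertical dynamics, onset times, fc times).

    Returns the unscaled vertical waveform sampled at fs, the step-onset
    (IC) times and final-contact times relative to the segment start.
    """
    sd = profile.step_time_cov / 100.0 * profile.mean_step_time
    steps = rng.normal(profile.mean_step_time, sd, size=n_steps)
    steps = np.clip(steps, 0.25 * profile.mean_step_time, None)
    # alternate-foot asymmetry: F1 steps longer by the asymmetry ratio
    r = profile.asymmetry_ratio
    f1 = 2 * r / (1 + r)
    f2 = 2 / (1 + r)
    steps *= np.where(np.arange(n_steps) % 2 == 0, f1, f2)
    onsets = np.concatenate(([0.0], np.cumsum(steps)))
    duration = onsets[-1]
    t = np.arange(int(np.floor(duration * fs))) / fs
    k = np.searchsorted(onsets, t, side="right") - 1
    k = np.clip(k, 0, n_steps - 1)
    phase = (t - onsets[k]) / steps[k]
    amp = np.exp(rng.normal(0, 0.03, size=n_steps))  # per-step vigor jitter
    x = amp[k] * _step_waveform(phase)
    fc = onsets[:-1] + 2 * profile.double_support_frac * steps
    return t, x, onsets, fc


def generate_acceleration(profile: GaitProfile, task: str = "NormalW",
                          distance: float = 20.0,
                          sampling_rate: float = 100.0,
                          seed: int | None = 0,
                          turn_duration: float = 3.0,
                          lead: float = 4.0,
                          tilt_deg: float | None = None,
                          noise_sd: float = 0.01,
                          subject_id: str = "",
                          filter_cutoff: float = 3.0):
    """Simulate one two-direction walking trial of ``distance`` m per leg.

    Returns ``(recording, (events_out, events_back))``: the raw tri-axial
    recording (gravity and static tilt included) and the ground-truth
    gait events of each direction, in absolute recording time.  ``lead``
    seconds of walking are prepended/appended to each direction so the
    3 s edge trim of the processing chain removes signal that has no
    bearing on the planted statistics.

    The vertical waveform is scaled so that its RMS after a zero-lag
    Butterworth low-pass at ``filter_cutoff`` Hz equals the profile RMS.
    """
    if sampling_rate < 50:
        raise ValueError("sampling_rate must be at least 50 Hz")
    if distance <= 0:
        raise ValueError("distance must be positive")
    rng = np.random.default_rng(seed)
    n_steps = int(round(distance / profile.step_length)) \
        + 2 * int(np.ceil(lead / profile.mean_step_time))
    duration = n_steps * profile.mean_step_time
    if duration < 4 * profile.mean_step_time + 2 * 3.0:
        raise ValueError(
            f"direction of {duration:.1f} s is too short: need at least two "
            "strides plus the 6 s trim margin; increase distance or lower "
            "step length")
    fs = sampling_rate
    segs, events = [], []
    offset = 0.0
    for direction in range(2):
        t, x, onsets, fc = _direction_segment(profile, n_steps, fs, rng)
        scale = profile.accel_rms / _filtered_rms(x, fs, filter_cutoff)
        segs.append(scale * x)
        events.append((onsets + offset, fc + offset))
        offset += len(t) / fs
        if direction == 0:
            n_turn = int(turn_duration * fs)
            segs.append(rng.normal(0, 0.05 * profile.accel_rms, size=n_turn))
            offset += n_turn / fs
    v_dyn = np.concatenate(segs)
    n = len(v_dyn)
    t = np.arange(n) / fs
    samples = np.empty((n, 3))
    # weak step-coupled horizontal components plus sensor noise
    samples[:, 0] = 0.25 * v_dyn + rng.normal(0, noise_sd, n)
    samples[:, 1] = 0.15 * np.roll(v_dyn, int(0.1 * fs)) \
        + rng.normal(0, noise_sd, n)
    samples[:, 2] = v_dyn + 1.0 + rng.normal(0, noise_sd, n)
    if tilt_deg is None:
        tilt_deg = float(rng.uniform(1.0, 5.0))
    a = np.deg2rad(tilt_deg)
    phi = float(rng.uniform(0, 2 * np.pi))
    Rx = np.array([[1, 0, 0],
                   [0, np.cos(a * np.cos(phi)), -np.sin(a * np.cos(phi))],
                   [0, np.sin(a * np.cos(phi)), np.cos(a * np.cos(phi))]])
    Ry = np.array([[np.cos(a * np.sin(phi)), 0, np.sin(a * np.sin(phi))],
                   [0, 1, 0],
                   [-np.sin(a * np.sin(phi)), 0, np.cos(a * np.sin(phi))]])
    samples = samples @ (Ry @ Rx).T
    rec = AccelerationRecording(t=t, samples=samples, sampling_rate=fs,
                                subject_id=subject_id, task=task)
    gt = tuple(GaitEvents(ic_times=ic, fc_times=fc) for ic, fc in events)
    return rec, gt


def _filtered_rms(x: np.ndarray, fs: float, cutoff: float) -> float:
    xf = lowpass_filter(x - x.mean(), fs, cutoff=cutoff)
    return float(np.sqrt(np.mean(xf ** 2)))
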