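"""Spatio-temporal gait features (STGF), dual-task costs and the 96-column
feature table.

Sixteen STGF are computed per walking task and direction: step time
(StpT) and its coefficient of variation (StpTCoV), stride time (StrT) and
StrTCoV, cadence (Cd), vertical-acceleration RMS, double- and single-
support durations (DSD, SSD), per-foot swing / stance / step durations
(SwDurF1, SwDurF2, StDurF1, StDurF2, StepDurF1, StepDurF2), step length
(StepLg, inverted-pendulum model) and gait speed (GS).  With four tasks
that is 64 STGF; dual-task costs of the two dual tasks against normal
walking add 32 more, giving 96 measures per direction, and the two
directions are averaged element-wise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.signal import detrend

from .signal import AccelerationRecording, GaitEvents

logger = logging.getLogger(__name__)

__all__ = [
    "STGF_NAMES",
    "StgfVector",
    "StrideIntervals",
    "compute_stride_params",
    "compute_stgf",
    "compute_dtc",
    "assemble_feature_table",
    "select_model_columns",
    "enumerate_models",
    "MODEL_TASKS",
]

TASKS = ("NormalW", "EasyD", "HardD", "FastW")
DUAL_TASKS = ("EasyD", "HardD")
SINGLE_TASK_REFERENCE = "NormalW"

STGF_NAMES = ("StpT", "StpTCoV", "StrT", "StrTCoV", "Cd", "RMS", "DSD",
              "SSD", "SwDurF1", "SwDurF2", "StDurF1", "StDurF2",
              "StepDurF1", "StepDurF2", "StepLg", "GS")

STGF_UNITS = {"StpT": "s", "StpTCoV": "%", "StrT": "s", "StrTCoV": "%",
              "Cd": "steps/min", "RMS": "g", "DSD": "s", "SSD": "s",
              "SwDurF1": "s", "SwDurF2": "s", "StDurF1": "s",
              "StDurF2": "s", "StepDurF1": "s", "StepDurF2": "s",
              "StepLg": "m", "GS": "m/s"}

#: the eleven feature-subset models: each single task, every unordered
#: task pair, and all tasks together
MODEL_TASKS: dict[str, tuple[str, ...]] = {
    **{t: (t,) for t in TASKS},
    **{f"{a}+{b}": (a, b) for a, b in itertools.combinations(TASKS, 2)},
    "All-tasks": TASKS,
}


@dataclass(frozen=True)
class StgfVector:
    """The sixteen spatio-temporal gait features of one task/direction."""

    StpT: float       # mean step time, s
    StpTCoV: float    # step-time coefficient of variation, %
    StrT: float       # mean stride time, s
    StrTCoV: float    # stride-time coefficient of variation, %
    Cd: float         # cadence, steps/min
    RMS: float        # vertical-acceleration RMS, g
    DSD: float        # double-support duration, s
    SSD: float        # single-support duration, s
    SwDurF1: float    # swing duration, foot 1, s
    SwDurF2: float    # swing duration, foot 2, s
    StDurF1: float    # stance duration, foot 1, s
    StDurF2: float    # stance duration, foot 2, s
    StepDurF1: float  # step duration, foot 1, s
    StepDurF2: float  # step duration, foot 2, s
    StepLg: float     # step length, m
    GS: float         # gait speed, m/s

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name)
                          for f in fields(self)})


@dataclass
class StrideIntervals:
    """Per-foot interval series derived from a gait-event sequence."""

    step_times: np.ndarray            # consecutive IC differences
    step_feet: tuple[str, ...]        # foot striking at the END of the step
    stride_times: dict[str, np.ndarray]   # same-foot IC differences
    stance: dict[str, np.ndarray]     # IC to same-foot (next) FC
    swing: dict[str, np.ndarray]      # FC to same-foot next IC
    double_support: np.ndarray        # IC to the following FC
    single_support: np.ndarray        # step time minus double support


def compute_stride_params(events: GaitEvents) -> StrideIntervals:
    """Decompose IC/FC sequences into per-foot gait-cycle intervals.

    Conventions: the FC between IC_i and IC_{i+1} is the toe-off of the
    foot striking at IC_{i+1} (it leaves the ground to swing forward), so
    stance of that foot runs from its previous IC to that FC and its
    swing from the FC to IC_{i+1}.  Double support after IC_i is the
    interval from IC_i to the next FC; single support is the remainder of
    the step.
    """
    events.validate()
    ic, fc, feet = events.ic_times, events.fc_times, events.foot_labels
    if len(ic) < 4:
        raise ValueError("need at least 4 initial contacts")
    step_times = np.diff(ic)
    stride, stance, swing = {}, {}, {}
    for foot in ("F1", "F2"):
        idx = np.flatnonzero(np.array(feet) == foot)
        stride[foot] = np.diff(ic[idx])
        # FC index i belongs to the foot of IC_{i+1}
        st, sw = [], []
        for i in range(len(fc)):
            if feet[i + 1] != foot:
                continue
            prev = i - 1  # previous IC of this foot is at index i-1
            if prev >= 0:
                st.append(fc[i] - ic[prev])
            sw.append(ic[i + 1] - fc[i])
        stance[foot] = np.asarray(st)
        swing[foot] = np.asarray(sw)
    double = fc - ic[:-1]
    single = step_times - double
    return StrideIntervals(step_times=step_times, step_feet=tuple(feet[1:]),
                           stride_times=stride, stance=stance, swing=swing,
                           double_support=double, single_support=single)


def _cov_percent(x: np.ndarray) -> float:
    """100 * sample standard deviation / mean."""
    if len(x) < 3:
        raise ValueError("need at least 3 intervals for a CoV")
    return float(100.0 * np.std(x, ddof=1) / np.mean(x))


def _pendulum_step_length(vertical: np.ndarray, ic_idx: np.ndarray,
                          fs: float, height_cm: float,
                          g: float = 9.80665) -> float:
    """Inverted-pendulum step length from double-integrated acceleration.

    Per step, the vertical acceleration (in g) is integrated twice with
    linear detrending at each stage; the displacement range h within the
    step gives step length 2*sqrt(2*l*h - h^2) with pendulum length
    l = 0.53 * body height.
    """
    leg = 0.53 * height_cm / 100.0
    a = (vertical - vertical.mean()) * g
    lengths = []
    for s, e in zip(ic_idx[:-1], ic_idx[1:]):
        if e - s < 4:
            continue
        seg = a[s:e]
        vel = detrend(integrate.cumulative_trapezoid(seg, dx=1 / fs,
                                                     initial=0.0))
        disp = detrend(integrate.cumulative_trapezoid(vel, dx=1 / fs,
                                                      initial=0.0))
        h = float(disp.max() - disp.min())
        h = min(h, leg)  # the pendulum geometry caps the excursion
        lengths.append(2.0 * np.sqrt(max(2.0 * leg * h - h * h, 0.0)))
    if not lengths:
        raise ValueError("no usable steps for the step-length model")
    return float(np.mean(lengths))


def compute_stgf(intervals: StrideIntervals,
                 vertical_signal: np.ndarray | AccelerationRecording,
                 height: float, sampling_rate: float | None = None,
                 events: GaitEvents | None = None,
                 t0: float = 0.0) -> StgfVector:
    """Assemble the sixteen STGF from interval series and the vertical
    acceleration of the trimmed segment.

    ``height`` is the subject's body height in cm (used by the
    inverted-pendulum step-length model).  ``events`` is needed to locate
    step windows in the signal; when ``vertical_signal`` is a recording,
    sampling rate and time origin are taken from it.
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
    st = intervals.step_times
    if len(st) < 3:
        raise ValueError("fewer than 3 steps: CoV undefined")
    strides = np.concatenate([intervals.stride_times["F1"],
                              intervals.stride_times["F2"]])
    step_by_foot = {
        foot: st[np.array(intervals.step_feet) == foot]
        for foot in ("F1", "F2")}
    mean_step = float(np.mean(st))
    rms = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    if events is None:
        raise ValueError("events are required to window the signal")
    ic_idx = np.clip(np.round((events.ic_times - t0) * sampling_rate
                              ).astype(int), 0, len(x) - 1)
    step_lg = _pendulum_step_length(x, ic_idx, sampling_rate, height)
    return StgfVector(
        StpT=mean_step,
        StpTCoV=_cov_percent(st),
        StrT=float(np.mean(strides)),
        StrTCoV=_cov_percent(strides),
        Cd=60.0 / mean_step,
        RMS=rms,
        DSD=float(np.mean(intervals.double_support)),
        SSD=float(np.mean(intervals.single_support)),
        SwDurF1=float(np.mean(intervals.swing["F1"])),
        SwDurF2=float(np.mean(intervals.swing["F2"])),
        StDurF1=float(np.mean(intervals.stance["F1"])),
        StDurF2=float(np.mean(intervals.stance["F2"])),
        StepDurF1=float(np.mean(step_by_foot["F1"])),
        StepDurF2=float(np.mean(step_by_foot["F2"])),
        StepLg=step_lg,
        GS=step_lg / mean_step,
    )


def compute_dtc(single_task_value: float, dual_task_value: float) -> float:
    """Dual-task cost in percent: ((single - dual) / single) * 100."""
    if single_task_value == 0:
        raise ValueError("zero single-task value: dual-task cost undefined")
    return (single_task_value - dual_task_value) / single_task_value * 100.0


def _direction_columns(task_vectors: dict[str, StgfVector]) -> pd.Series:
    """96 (or fewer) named measures for one subject and direction."""
    cols = {}
    for task, vec in task_vectors.items():
        s = vec.as_series()
        for name, val in s.items():
            cols[f"{task}::{name}"] = val
    if SINGLE_TASK_REFERENCE in task_vectors:
        ref = task_vectors[SINGLE_TASK_REFERENCE].as_series()
        for dual in DUAL_TASKS:
            if dual not in task_vectors:
                continue
            dv = task_vectors[dual].as_series()
            for name in STGF_NAMES:
                cols[f"dtc::{dual}::{name}"] = compute_dtc(ref[name],
                                                           dv[name])
    return pd.Series(cols)


def assemble_feature_table(
        per_subject: dict[str, dict[str, dict[str, StgfVector]]],
        labels: pd.Series | dict | None = None) -> pd.DataFrame:
    """Average per-direction measure vectors into the final feature table.

    Parameters
    ----------
    per_subject : mapping subject -> task -> direction -> StgfVector
        Directions are arbitrary keys (e.g. "out"/"back"); every retained
        subject must have the same tasks with both directions.  Dual-task
        costs are computed within each direction before averaging.
    labels : optional mapping subject -> group label, attached as a
        ``label`` column.

    Subjects missing a task or direction are dropped with a logged
    reason.
    """
    rows = {}
    for subject, tasks in per_subject.items():
        bad = [t for t, dirs in tasks.items() if len(dirs) < 2]
        if bad or not tasks:
            logger.warning("dropping subject %s: incomplete tasks %s",
                           subject, bad or "(none)")
            continue
        per_dir = []
        dir_keys = sorted({d for dirs in tasks.values() for d in dirs})
        for d in dir_keys:
            task_vectors = {t: dirs[d] for t, dirs in tasks.items()
                            if d in dirs}
            per_dir.append(_direction_columns(task_vectors))
        rows[subject] = pd.concat(per_dir, axis=1).mean(axis=1)
    table = pd.DataFrame(rows).T
    table.index.name = "id"
    if labels is not None:
        lab = pd.Series(labels)
        table.insert(0, "label", lab.reindex(table.index))
    if table.drop(columns=["label"], errors="ignore").isna().any().any():
        raise ValueError("feature table contains missing values")
    return table


def enumerate_models() -> list[str]:
    """The eleven feature-subset model identifiers."""
    return list(MODEL_TASKS)


def model_columns(model: str) -> list[str]:
    """Column names belonging to a feature-subset model."""
    if model not in MODEL_TASKS:
        raise KeyError(f"unknown model {model!r}; "
                       f"choose from {list(MODEL_TASKS)}")
    tasks = MODEL_TASKS[model]
    cols = [f"{t}::{n}" for t in tasks for n in STGF_NAMES]
    cols += [f"dtc::{d}::{n}" for d in DUAL_TASKS if d in tasks
             for n in STGF_NAMES]
    return cols


def select_model_columns(table: pd.DataFrame, model: str) -> pd.DataFrame:
    """Restrict a feature table to one model's columns (label kept)."""
    cols = model_columns(model)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks columns for model {model!r}: "
                       f"{missing[:4]}...")
    keep = (["label"] if "label" in table.columns else []) + cols
    return table[keep]
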