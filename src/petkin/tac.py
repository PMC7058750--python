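"""Core dynamic-PET data types and curve utilities.

Conventions used throughout the package:

* Time zero is the injection time. All times are stored in **seconds**
  internally; user-facing tables report minutes.
* A frame value is the average activity concentration over the frame,
  plotted at the frame midpoint.
* Activity concentrations are Bq/mL unless stated otherwise.
* Decay correction is referenced to injection time (the standard SUV
  convention); the reference is configurable per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Physical half-life of Ga-68 in seconds (67.71 min).
GA68_HALF_LIFE_S = 67.71 * 60.0


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping dynamic framing grid.

    Parameters
    ----------
    start : array of frame start times, seconds from injection.
    duration : array of frame durations, seconds.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or start.shape != duration.shape:
            raise ValueError("start and duration must be 1-D arrays of equal length")
        if start.size == 0:
            raise ValueError("empty frame schedule")
        if np.any(duration <= 0):
            raise ValueError("all frame durations must be > 0")
        if start[0] < 0:
            raise ValueError("first frame must start at or after injection")
        if not np.allclose(start[1:], start[:-1] + duration[:-1], atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def mid(self) -> np.ndarray:
        """Frame midpoints in seconds."""
        return self.start + self.duration / 2.0

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def total_duration(self) -> float:
        """Scan length in seconds (end of last frame)."""
        return float(self.start[-1] + self.duration[-1])

    @classmethod
    def from_durations(cls, durations: Sequence[float], t0: float = 0.0) -> "FrameSchedule":
        durations = np.asarray(durations, dtype=float)
        start = t0 + np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(start=start, duration=durations)

    @classmethod
    def default_60min(cls) -> "FrameSchedule":
        """The 28-frame, 60-min protocol: 10x30 s, 5x60 s, 5x120 s, 8x300 s."""
        durations = [30.0] * 10 + [60.0] * 5 + [120.0] * 5 + [300.0] * 8
        return cls.from_durations(durations)


@dataclass(frozen=True)
class SubjectMeta:
    """Subject-level quantities needed for SUV scaling.

    injected_activity is in MBq (decay-corrected to injection time),
    body_weight in kg, hematocrit a fraction in (0, 1) when known.
    """

    injected_activity: float
    body_weight: float
    hematocrit: float | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.injected_activity <= 0:
            raise ValueError("injected_activity must be > 0")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        if self.hematocrit is not None and not (0.0 < self.hematocrit < 1.0):
            raise ValueError("hematocrit must be in (0, 1)")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame activity concentration (Bq/mL) for one region."""

    schedule: FrameSchedule
    values: np.ndarray
    region_label: str = ""
    decay_corrected: bool = True
    half_life: float = GA68_HALF_LIFE_S
    noise_corrupted: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.n_frames,):
            raise ValueError("values length must equal the number of frames")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if np.any(values < 0) and not self.noise_corrupted:
            raise ValueError(
                "negative activity only permitted when flagged noise_corrupted"
            )


@dataclass(frozen=True)
class SUVCurve:
    """Per-frame standardized uptake value (g/mL)."""

    schedule: FrameSchedule
    suv: np.ndarray
    region_label: str = ""

    def __post_init__(self) -> None:
        suv = np.asarray(self.suv, dtype=float)
        object.__setattr__(self, "suv", suv)
        if suv.shape != (self.schedule.n_frames,):
            raise ValueError("suv length must equal the number of frames")


def decay_correct(
    tac: TimeActivityCurve, reference: float = 0.0
) -> TimeActivityCurve:
    """Decay-correct a physical-activity TAC to ``reference`` (s from injection).

    Each frame value is multiplied by exp(lambda * (t_mid - reference)) with
    lambda = ln 2 / half_life. Raises if the curve is already corrected.
    """
    if tac.decay_corrected:
        raise ValueError("TAC is already decay-corrected")
    if not (tac.half_life > 0):
        raise ValueError("half-life must be known and > 0")
    lam = math.log(2.0) / tac.half_life
    factor = np.exp(lam * (tac.schedule.mid - reference))
    return replace(tac, values=tac.values * factor, decay_corrected=True)


def decay_uncorrect(
    tac: TimeActivityCurve, reference: float = 0.0
) -> TimeActivityCurve:
    """Inverse of :func:`decay_correct`: map back to physical (measured) activity."""
    if not tac.decay_corrected:
        raise ValueError("TAC is not decay-corrected")
    if not (tac.half_life > 0):
        raise ValueError("half-life must be known and > 0")
    lam = math.log(2.0) / tac.half_life
    factor = np.exp(-lam * (tac.schedule.mid - reference))
    return replace(tac, values=tac.values * factor, decay_corrected=False)


def suv_from_tac(tac: TimeActivityCurve, meta: SubjectMeta) -> SUVCurve:
    """SUV(t) = C(kBq/mL) / (injected dose (MBq) / body weight (kg)).

    The kBq/MBq and kg->g factors cancel, yielding g/mL. Requires a
    decay-corrected TAC in Bq/mL.
    """
    if not tac.decay_corrected:
        raise ValueError("SUV requires a decay-corrected TAC")
    c_kbq = tac.values / 1000.0
    suv = c_kbq / (meta.injected_activity / meta.body_weight)
    return SUVCurve(schedule=tac.schedule, suv=suv, region_label=tac.region_label)


def window_mean_suv(suv: SUVCurve, t_lo_min: float, t_hi_min: float) -> float:
    """Duration-weighted mean SUV over frames fully inside [t_lo, t_hi] minutes."""
    t_lo, t_hi = t_lo_min * 60.0, t_hi_min * 60.0
    if t_hi <= t_lo:
        raise ValueError("empty window")
    sched = suv.schedule
    inside = (sched.start >= t_lo - 1e-9) & (sched.end <= t_hi + 1e-9)
    if not np.any(inside):
        raise ValueError(f"no frames fully inside window [{t_lo_min}, {t_hi_min}] min")
    w = sched.duration[inside]
    return float(np.sum(w * suv.suv[inside]) / np.sum(w))


def trapezoid_auc(
    time: np.ndarray, value: np.ndarray, t_lo: float, t_hi: float
) -> float:
    """Trapezoidal integral of a sampled curve over [t_lo, t_hi].

    Linear interpolation is used at the window edges; the window must lie
    within the sampled range.
    """
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    if time.ndim != 1 or time.shape != value.shape or time.size < 2:
        raise ValueError("need >= 2 samples")
    if np.any(np.diff(time) <= 0):
        raise ValueError("times must be strictly increasing")
    if t_hi <= t_lo:
        raise ValueError("empty integration window")
    if t_lo < time[0] - 1e-9 or t_hi > time[-1] + 1e-9:
        raise ValueError("integration window outside the sampled range")
    inner = (time > t_lo) & (time < t_hi)
    t = np.concatenate([[t_lo], time[inner], [t_hi]])
    v = np.concatenate(
        [[np.interp(t_lo, time, value)], value[inner], [np.interp(t_hi, time, value)]]
    )
    return float(np.trapezoid(v, t))


def resample_to_grid(
    time: np.ndarray,
    value: np.ndarray,
    grid: np.ndarray,
    extrapolation: str = "error",
) -> np.ndarray:
    """Linearly interpolate a sampled curve onto ``grid``.

    Values before the first sample are 0 (pre-injection). Beyond the last
    sample the behaviour follows ``extrapolation``: ``"error"`` (default)
    or ``"hold"`` (hold the last value).
    """
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError("times must be strictly increasing")
    if extrapolation not in ("error", "hold"):
        raise ValueError(f"unknown extrapolation policy {extrapolation!r}")
    if extrapolation == "error" and np.any(grid > time[-1] + 1e-9):
        raise ValueError("grid extends beyond the last sample (no tail policy set)")
    return np.interp(grid, time, value, left=0.0, right=value[-1])


def frame_average(
    grid: np.ndarray, value: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Average a finely sampled curve over each frame of ``schedule``.

    Uses the trapezoid rule within each frame divided by the frame duration,
    which is exact for piecewise-linear curves when frame boundaries lie on
    the grid.
    """
    out = np.empty(schedule.n_frames)
    for i, (a, b) in enumerate(zip(schedule.start, schedule.end)):
        out[i] = trapezoid_auc(grid, value, a, b) / (b - a)
    return out
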