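"""Arterial input-function construction.

Builds the 60-min arterial plasma input function from a 1-s automatic
blood-sampler curve (first 10 min) merged with decay-corrected manual
samples, and exposes the hematocrit / plasma-to-blood relations.

The sampler measures counts per second through a detector with external
tubing; the recorded signal is therefore background-shifted, not
decay-corrected, and dispersed by tracer transport through the line. The
dispersion kernel is modelled as monoexponential, (1/tau) exp(-t/tau),
the standard external-detector model; its inverse is
c(t) = g(t) + tau * dg/dt.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .tac import GA68_HALF_LIFE_S, trapezoid_auc

#: Cohort-default plasma-to-blood activity ratio (hematocrit ~0.38).
DEFAULT_PLASMA_TO_BLOOD = 1.62


@dataclass(frozen=True)
class SamplerCurve:
    """Raw automatic-sampler record: counts per second at ~1 s resolution."""

    time: np.ndarray           # s from injection
    counts: np.ndarray         # cps, background-shifted, not decay-corrected
    background: float          # cps
    calibration_factor: float  # (Bq/mL) per cps
    dispersion_tau: float = 5.0  # s
    half_life: float = GA68_HALF_LIFE_S

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "counts", counts)
        if time.shape != counts.shape or time.ndim != 1 or time.size < 3:
            raise ValueError("time and counts must be equal-length 1-D arrays")
        if np.any(np.diff(time) <= 0):
            raise ValueError("sampler times must be strictly increasing")
        if self.calibration_factor <= 0:
            raise ValueError("calibration factor must be > 0")
        if self.dispersion_tau < 0:
            raise ValueError("dispersion tau must be >= 0")


@dataclass(frozen=True)
class ManualSample:
    """One manual arterial draw, activities decay-corrected to injection."""

    draw_time: float              # s
    whole_blood_activity: float   # Bq/mL
    plasma_activity: float        # Bq/mL

    def __post_init__(self) -> None:
        if self.plasma_activity < 0:
            raise ValueError("plasma activity must be >= 0")


@dataclass(frozen=True)
class InputFunction:
    """Finely sampled blood or plasma activity curve (Bq/mL, decay-corrected)."""

    time: np.ndarray
    value: np.ndarray
    matrix: str = "whole_blood"        # "whole_blood" | "plasma"
    provenance: str = "sampler_merged"  # "sampler_merged" | "image_derived"

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        value = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "value", value)
        if time.shape != value.shape or time.ndim != 1:
            raise ValueError("time and value must be equal-length 1-D arrays")
        if np.any(np.diff(time) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(value)):
            raise ValueError("values must be finite")
        if self.matrix not in ("whole_blood", "plasma"):
            raise ValueError(f"unknown matrix {self.matrix!r}")

    def auc(self, t_lo: float | None = None, t_hi: float | None = None) -> float:
        t_lo = self.time[0] if t_lo is None else t_lo
        t_hi = self.time[-1] if t_hi is None else t_hi
        return trapezoid_auc(self.time, self.value, t_lo, t_hi)


def fill_gaps(time: np.ndarray, counts: np.ndarray, max_gap: float = 30.0,
              dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Bridge sampler pauses shorter than ``max_gap`` s by linear interpolation.

    Pauses occur while manual samples are drawn. Gaps >= max_gap are left
    as-is (the merge stage must then handle them explicitly).
    """
    time = np.asarray(time, dtype=float)
    counts = np.asarray(counts, dtype=float)
    out_t = [time[0]]
    out_c = [counts[0]]
    for i in range(1, time.size):
        gap = time[i] - time[i - 1]
        if dt * 1.5 < gap < max_gap:
            t_fill = np.arange(time[i - 1] + dt, time[i] - dt / 2, dt)
            out_t.extend(t_fill)
            out_c.extend(np.interp(t_fill, time[i - 1 : i + 1], counts[i - 1 : i + 1]))
        out_t.append(time[i])
        out_c.append(counts[i])
    return np.asarray(out_t), np.asarray(out_c)


def correct_sampler(raw: SamplerCurve) -> InputFunction:
    """Background-subtract, dispersion-correct and decay-correct a sampler curve.

    Order of operations: net counts ``max(counts - background, 0)``;
    dispersion removed by the monoexponential-kernel inverse
    ``c(t) = g(t) + tau*dg/dt`` with central differences; negative values
    clipped at 0; decay-corrected to injection and calibrated to Bq/mL.
    """
    t, g = fill_gaps(raw.time, raw.counts)
    g = np.maximum(g - raw.background, 0.0)
    if raw.dispersion_tau > 0:
        dg = np.gradient(g, t)
        c = g + raw.dispersion_tau * dg
        n_clip = int(np.sum(c < 0))
        if n_clip > 0.2 * c.size:
            warnings.warn(
                f"dispersion correction clipped {n_clip}/{c.size} samples negative; "
                "tau may be too large",
                stacklevel=2,
            )
        c = np.maximum(c, 0.0)
    else:
        c = g
    lam = math.log(2.0) / raw.half_life
    value = raw.calibration_factor * c * np.exp(lam * t)
    return InputFunction(time=t, value=value, matrix="whole_blood",
                         provenance="sampler_merged")


def disperse(time: np.ndarray, value: np.ndarray, tau: float) -> np.ndarray:
    """Forward-convolve a curve with the monoexponential kernel (1/tau)e^{-t/tau}.

    Discretized exactly for piecewise-linear input (used by the synthetic
    generator and by round-trip tests of :func:`correct_sampler`).
    """
    if tau == 0:
        return np.asarray(value, dtype=float).copy()
    from scipy.signal import lfilter

    dt = float(np.mean(np.diff(time)))
    a = dt / tau
    e = math.exp(-a)
    # exact convolution of a piecewise-linear signal with (1/tau)e^{-t/tau}
    i0 = (1.0 - e)            # integral of kernel over one step
    i1 = (a - (1.0 - e)) / a  # first-moment weight
    b_cur = i1
    b_prev = i0 - i1
    return lfilter([b_cur, b_prev], [1.0, -e], value)


def merge_with_manual(
    sampler_if: InputFunction,
    samples: list[ManualSample],
    end_time: float = 3600.0,
    dt: float = 1.0,
    tolerance: float = 0.15,
) -> InputFunction:
    """Extend the 10-min sampler curve to 60 min using manual whole-blood samples.

    The merged curve equals the sampler curve up to its last sample; beyond
    it the curve follows log-linear (mono-exponential) segments through the
    manual whole-blood points, anchored at the sampler endpoint. Manual
    samples inside the sampler window are used only for a scale-consistency
    check (warning when the ratio deviates more than ``tolerance``).
    """
    if sampler_if.matrix != "whole_blood":
        raise ValueError("sampler input function must be whole blood")
    t_end_sampler = sampler_if.time[-1]
    tail = sorted(
        (s for s in samples if s.draw_time > t_end_sampler), key=lambda s: s.draw_time
    )
    if len(tail) < 2:
        raise ValueError("need >= 2 manual samples beyond the sampler window")

    for s in samples:
        if s.draw_time <= t_end_sampler:
            ref = np.interp(s.draw_time, sampler_if.time, sampler_if.value)
            if ref > 0 and s.whole_blood_activity > 0:
                ratio = s.whole_blood_activity / ref
                if abs(ratio - 1.0) > tolerance:
                    warnings.warn(
                        f"manual sample at {s.draw_time:.0f} s disagrees with sampler "
                        f"(manual/sampler = {ratio:.3f})",
                        stacklevel=2,
                    )

    nodes_t = [t_end_sampler] + [s.draw_time for s in tail]
    nodes_v = [float(sampler_if.value[-1])] + [s.whole_blood_activity for s in tail]
    t_tail = np.arange(t_end_sampler + dt, end_time + dt / 2, dt)
    # log-linear interpolation; fall back to linear across non-positive nodes
    logv = np.log(np.maximum(nodes_v, 1e-12))
    v_tail = np.exp(np.interp(t_tail, nodes_t, logv))
    if min(nodes_v) <= 0:
        v_tail = np.interp(t_tail, nodes_t, nodes_v)

    time = np.concatenate([sampler_if.time, t_tail])
    value = np.concatenate([sampler_if.value, v_tail])
    return InputFunction(time=time, value=value, matrix="whole_blood",
                         provenance=sampler_if.provenance)


def extend_tail(f: InputFunction, end_time: float, dt: float = 30.0) -> InputFunction:
    """Extend an input function to ``end_time`` by log-linear extrapolation.

    Continues the mono-exponential segment through the last two samples
    (blood clearance is near-exponential late in the scan); falls back to
    holding the last value when the tail is non-positive or rising.
    Used for frame-midpoint-sampled curves (e.g. image-derived input
    functions) that stop half a frame short of the scan end.
    """
    if f.time[-1] >= end_time:
        return f
    t1, t0 = f.time[-1], f.time[-2]
    v1, v0 = f.value[-1], f.value[-2]
    t_ext = np.arange(t1 + dt, end_time + dt, dt)
    t_ext[-1] = min(t_ext[-1], end_time) if t_ext[-1] > end_time else t_ext[-1]
    t_ext = np.unique(np.clip(t_ext, t1 + 1e-6, end_time))
    if v0 > 0 and 0 < v1 <= v0:
        rate = math.log(v1 / v0) / (t1 - t0)
        v_ext = v1 * np.exp(rate * (t_ext - t1))
    else:
        v_ext = np.full(t_ext.size, max(v1, 0.0))
    return replace(f, time=np.concatenate([f.time, t_ext]),
                   value=np.concatenate([f.value, v_ext]))


def plasma_blood_ratio(samples: list[ManualSample]) -> float:
    """Arithmetic mean of per-sample plasma/whole-blood activity ratios."""
    ratios = []
    for s in samples:
        if s.whole_blood_activity <= 0:
            warnings.warn(
                f"sample at {s.draw_time:.0f} s has non-positive whole-blood "
                "activity; excluded from ratio",
                stacklevel=2,
            )
            continue
        ratios.append(s.plasma_activity / s.whole_blood_activity)
    if not ratios:
        raise ValueError("no usable samples for plasma-to-blood ratio")
    return float(np.mean(ratios))


def subject_plasma_ratio(samples: list[ManualSample], min_samples: int = 3) -> float:
    """Per-subject ratio when enough manual samples exist, else the cohort default.

    The ratio depends only on hematocrit and is stable across subjects, so
    the cohort default 1.62 is a sound fallback for sparse draws.
    """
    usable = [s for s in samples if s.whole_blood_activity > 0]
    if len(usable) >= min_samples:
        return plasma_blood_ratio(usable)
    return DEFAULT_PLASMA_TO_BLOOD


def blood_to_plasma(if_wb: InputFunction, ratio: float) -> InputFunction:
    """Scale a whole-blood curve into plasma by the plasma-to-blood ratio."""
    if if_wb.matrix == "plasma":
        raise ValueError("input function is already plasma")
    if ratio <= 0:
        raise ValueError("plasma-to-blood ratio must be > 0")
    return replace(if_wb, value=if_wb.value * ratio, matrix="plasma")


def hct_from_ratio(ratio: float) -> float:
    """Hematocrit from the plasma-to-blood ratio: HCT = 1 - 1/R.

    Valid for a tracer excluded from red blood cells, for which
    R_P/B = 1/(1-HCT).
    """
    if ratio < 1.0:
        raise ValueError("ratio < 1 would require tracer uptake into red cells")
    return 1.0 - 1.0 / ratio


def ratio_from_hct(hct: float) -> float:
    """Plasma-to-blood ratio from hematocrit: R = 1/(1-HCT)."""
    if not (0.0 <= hct < 1.0):
        raise ValueError("hematocrit must be in [0, 1)")
    return 1.0 / (1.0 - hct)


def aucr(idif: InputFunction, aif: InputFunction) -> float:
    """AUC ratio AUC_IDIF / AUC_AIF over the common time span.

    Both curves must be in the same matrix (whole blood vs whole blood, or
    plasma vs plasma); mixing matrices would fold the hematocrit factor
    into the equivalence check.
    """
    if idif.matrix != aif.matrix:
        raise ValueError("input functions must share the same matrix")
    t_lo = max(idif.time[0], aif.time[0])
    t_hi = min(idif.time[-1], aif.time[-1])
    if t_hi <= t_lo:
        raise ValueError("curves share no common time span")
    return idif.auc(t_lo, t_hi) / aif.auc(t_lo, t_hi)
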