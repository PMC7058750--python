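"""Compartment-model simulation, fitting, AIC selection, and Patlak analysis.

Four serial-compartment configurations are supported, named by tissue
compartments and free rate constants:

* ``1T1k`` — irreversible one-tissue model, K1 only (pure accumulation);
* ``1T2k`` — reversible one-tissue model, K1, k2;
* ``2T3k`` — irreversible two-tissue model, K1, k2, k3 (k3 = trapping);
* ``2T4k`` — reversible two-tissue model, K1, k2, k3, k4.

State equations (rates in /min, concentrations in Bq/mL):

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

with terms dropped for the smaller models. The model TAC is
``(1 - vB)*(C1 + C2) + vB*C_wb`` when the fractional blood volume is
fitted, else ``C1 + C2``; the whole-blood curve (not plasma) carries the
intravascular term. The solution is computed by exact exponential-basis
convolution of a piecewise-linear input on a fine grid, then averaged over
each frame.

The net influx rate Ki = K1*k3/(k2 + k3) is the macro-parameter of
irreversible trapping; it also equals the Patlak slope after the
reversible compartments equilibrate (t >= t*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .blood import InputFunction
from .tac import FrameSchedule, TimeActivityCurve, frame_average, resample_to_grid

MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "1T1k": ("K1",),
    "1T2k": ("K1", "k2"),
    "2T3k": ("K1", "k2", "k3"),
    "2T4k": ("K1", "k2", "k3", "k4"),
}

#: Fit bounds: K1 in mL/min/mL, k's in /min, vB dimensionless.
DEFAULT_BOUNDS = {"K1": (0.0, 5.0), "k2": (0.0, 5.0), "k3": (0.0, 5.0),
                  "k4": (0.0, 5.0), "vB": (0.0, 0.5)}


@dataclass(frozen=True)
class ModelSpec:
    """A compartment-model configuration: base model plus optional vB term."""

    name: str
    fit_vb: bool = False

    def __post_init__(self) -> None:
        if self.name not in MODEL_PARAM_NAMES:
            raise ValueError(f"unknown model {self.name!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        base = MODEL_PARAM_NAMES[self.name]
        return base + ("vB",) if self.fit_vb else base

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def label(self) -> str:
        return self.name + ("+VB" if self.fit_vb else "")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants: K1 in mL/min/mL, k2..k4 in /min, vB a fraction."""

    K1: float
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    vB: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.vB < 1.0):
            raise ValueError("vB must be in [0, 1)")

    def as_vector(self, spec: ModelSpec) -> np.ndarray:
        return np.array([getattr(self, n) for n in spec.param_names])

    @classmethod
    def from_vector(cls, spec: ModelSpec, x: Sequence[float]) -> "KineticParams":
        return cls(**dict(zip(spec.param_names, x)))


@dataclass
class KineticFit:
    """Result of one weighted nonlinear least-squares compartment fit."""

    spec: ModelSpec
    params: KineticParams
    rss: float
    n_points: int
    aic: float
    ki: float
    ki_defined: bool
    identifiable: bool
    param_rse: dict[str, float] = field(default_factory=dict)
    region_label: str = ""


@dataclass
class PatlakFit:
    """Patlak graphical-analysis result: slope Ki, intercept V."""

    ki: float           # mL/min/mL
    intercept: float    # mL/mL
    t_star: float       # minutes
    r_squared: float
    points_used: int


def _expconv(cp: np.ndarray, dt: float, alpha: float) -> np.ndarray:
    """y(t) = int_0^t cp(s) exp(-alpha (t - s)) ds for piecewise-linear cp.

    Exact per linear segment; implemented as a first-order IIR filter.
    ``alpha`` is in /s on a grid with step ``dt`` seconds.
    """
    if alpha * dt < 1e-12:
        # pure integration limit
        out = np.concatenate([[0.0], np.cumsum((cp[1:] + cp[:-1]) / 2.0 * dt)])
        return out
    a = alpha * dt
    e = math.exp(-a)
    i0 = (1.0 - e) / alpha
    i1 = (dt - i0) / alpha
    b_cur = i1 / dt
    b_prev = i0 - b_cur
    return lfilter([b_cur, b_prev], [1.0, -e], cp)


def impulse_terms(spec: ModelSpec, p: KineticParams) -> list[tuple[float, float]]:
    """Decompose the tissue impulse response into sum_j A_j exp(-alpha_j t).

    Returns [(A_j, alpha_j)] with A in (mL/min/mL) and alpha in /min, such
    that C1+C2 = conv(Cp, h) with h(t) = sum A_j exp(-alpha_j t).
    """
    K1, k2, k3, k4 = p.K1, p.k2, p.k3, p.k4
    if spec.name == "1T1k":
        return [(K1, 0.0)]
    if spec.name == "1T2k":
        return [(K1, k2)]
    if spec.name == "2T3k":
        a = k2 + k3
        if a <= 0:
            return [(K1, 0.0)]
        return [(K1 * k2 / a, a), (K1 * k3 / a, 0.0)]
    # 2T4k: eigenvalues of the two-compartment exchange matrix
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    sq = math.sqrt(max(disc, 0.0))
    if sq < 1e-10:  # degenerate (repeated eigenvalue): nudge apart
        sq = 1e-10
    a1 = (s - sq) / 2.0
    a2 = (s + sq) / 2.0
    c1 = K1 * (k3 + k4 - a1) / sq
    c2 = K1 * (a2 - k3 - k4) / sq
    return [(c1, a1), (c2, a2)]


def _frame_matrix(schedule: FrameSchedule, grid: np.ndarray) -> np.ndarray | None:
    """Frame-averaging weight matrix W so that W @ curve = frame means.

    Trapezoid-within-frame weights; valid only when every frame boundary
    lies on the grid (returns None otherwise, callers then fall back to
    the generic path).
    """
    n = schedule.n_frames
    W = np.zeros((n, grid.size))
    dt = grid[1] - grid[0]
    for i, (a, b) in enumerate(zip(schedule.start, schedule.end)):
        ia = int(np.searchsorted(grid, a - dt / 2))
        ib = int(np.searchsorted(grid, b - dt / 2))
        if (
            ia >= grid.size or ib >= grid.size
            or abs(grid[ia] - a) > 1e-9 or abs(grid[ib] - b) > 1e-9
        ):
            return None
        w = np.full(ib - ia + 1, dt)
        w[0] = w[-1] = dt / 2
        W[i, ia : ib + 1] = w / (b - a)
    return W


_FORWARD_CACHE: dict[tuple, tuple] = {}


def _forward_context(
    plasma: InputFunction,
    whole_blood: InputFunction | None,
    schedule: FrameSchedule,
    grid_dt: float,
):
    """Precompute (grid, cp, cwb, frame matrix) for repeated forward runs."""
    end = schedule.total_duration
    if plasma.time[-1] < end - 1e-6:
        raise ValueError("plasma input function does not cover the schedule")
    key = (
        plasma.time.tobytes(), plasma.value.tobytes(),
        None if whole_blood is None else whole_blood.value.tobytes(),
        schedule.start.tobytes(), schedule.duration.tobytes(), grid_dt,
    )
    hit = _FORWARD_CACHE.get(key)
    if hit is not None:
        return hit
    grid = np.arange(0.0, end + grid_dt / 2, grid_dt)
    cp = resample_to_grid(plasma.time, plasma.value, grid)
    cwb = None
    if whole_blood is not None:
        if whole_blood.time[-1] < end - 1e-6:
            raise ValueError("whole-blood curve does not cover the schedule")
        cwb = resample_to_grid(whole_blood.time, whole_blood.value, grid)
    W = _frame_matrix(schedule, grid)
    ctx = (grid, cp, cwb, W)
    if len(_FORWARD_CACHE) > 32:
        _FORWARD_CACHE.clear()
    _FORWARD_CACHE[key] = ctx
    return ctx


def _forward_frames(
    spec: ModelSpec, params: KineticParams, ctx, schedule: FrameSchedule,
    grid_dt: float,
) -> np.ndarray:
    grid, cp, cwb, W = ctx
    ct = np.zeros_like(grid)
    for amp, alpha_min in impulse_terms(spec, params):
        if amp == 0.0:
            continue
        # rates are /min; grid is seconds
        ct += (amp / 60.0) * _expconv(cp, grid_dt, alpha_min / 60.0)
    if spec.fit_vb:
        if cwb is None:
            raise ValueError("whole-blood curve required when fitting vB")
        ct = (1.0 - params.vB) * ct + params.vB * cwb
    if W is not None:
        return W @ ct
    return frame_average(grid, ct, schedule)


def simulate_tissue(
    spec: ModelSpec,
    params: KineticParams,
    plasma: InputFunction,
    whole_blood: InputFunction | None,
    schedule: FrameSchedule,
    grid_dt: float = 1.0,
    region_label: str = "",
) -> TimeActivityCurve:
    """Forward-simulate the model TAC on ``schedule``.

    The plasma curve is interpolated onto a ``grid_dt``-second grid, the
    exponential-basis convolution is evaluated exactly for the
    piecewise-linear input, and the result is averaged over each frame.
    """
    ctx = _forward_context(plasma, whole_blood if spec.fit_vb else None,
                           schedule, grid_dt)
    values = _forward_frames(spec, params, ctx, schedule, grid_dt)
    return TimeActivityCurve(schedule=schedule, values=values,
                             region_label=region_label)


def aic(rss: float, n_points: int, n_params: int) -> float:
    """Gaussian least-squares AIC: n ln(RSS/n) + 2(p + 1).

    The +1 counts the estimated noise variance. RSS = 0 (a perfect fit)
    returns -inf as a sentinel.
    """
    if n_points <= n_params + 2:
        raise ValueError("need n_points > n_params + 2")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0:
        return float("-inf")
    return n_points * math.log(rss / n_points) + 2.0 * (n_params + 1)


def net_influx(params: KineticParams) -> tuple[float, bool]:
    """Ki = K1*k3/(k2 + k3); returns (value, defined_flag).

    ``defined_flag`` is False for the 0/0 guard (k2 + k3 = 0).
    """
    if params.K1 < 0 or params.k2 < 0 or params.k3 < 0:
        raise ValueError("rate constants must be >= 0")
    denom = params.k2 + params.k3
    if denom == 0:
        return 0.0, False
    return params.K1 * params.k3 / denom, True


def _macro_ki(spec: ModelSpec, params: KineticParams) -> tuple[float, bool]:
    if spec.name == "1T1k":
        return params.K1, True
    if spec.name == "1T2k":
        # fully reversible: no net trapping at equilibrium
        return 0.0, False
    return net_influx(params)


def fit_model(
    tac: TimeActivityCurve,
    spec: ModelSpec,
    plasma: InputFunction,
    whole_blood: InputFunction | None = None,
    weights: np.ndarray | None = None,
    frame_mask: np.ndarray | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 10,
    seed: int = 0,
    grid_dt: float = 1.0,
) -> KineticFit:
    """Weighted nonlinear least-squares fit of one compartment model.

    Multi-start bounded trust-region optimization (``n_starts`` log-uniform
    draws within bounds plus one mid-bounds start, fixed ``seed``); the
    lowest-RSS solution wins. ``frame_mask`` excludes frames (e.g. motion
    at scan end). The identifiability flag is cleared when the relative
    standard error of k2 or k3 exceeds 100%.
    """
    sched = tac.schedule
    n = sched.n_frames
    if frame_mask is None:
        frame_mask = np.ones(n, dtype=bool)
    frame_mask = np.asarray(frame_mask, dtype=bool)
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    use = frame_mask & (weights > 0)
    n_used = int(np.sum(use))
    if n_used < spec.n_params + 2:
        raise ValueError("fewer usable frames than parameters + 2")
    sw = np.sqrt(weights[use])
    y = tac.values[use]

    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[p][0] for p in spec.param_names])
    hi = np.array([bnds[p][1] for p in spec.param_names])

    ctx = _forward_context(plasma, whole_blood if spec.fit_vb else None,
                           sched, grid_dt)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = KineticParams.from_vector(spec, x)
        model = _forward_frames(spec, p, ctx, sched, grid_dt)
        return sw * (model[use] - y)

    rng = np.random.default_rng(seed)
    floor = np.maximum(lo, 1e-3)
    starts = [np.sqrt(floor * np.maximum(hi, 1e-3))]  # geometric mid-bounds
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.exp(rng.uniform(np.log(floor), np.log(np.maximum(hi, 1e-3)))))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                                method="trf", xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"all {len(starts)} starts failed for {spec.label}")

    params = KineticParams.from_vector(spec, best.x)
    rss = float(2.0 * best.cost)  # least_squares cost = RSS/2
    fit_aic = aic(max(rss, 1e-300), n_used, spec.n_params) if rss > 1e-290 else float("-inf")

    # covariance from the Gauss-Newton approximation at the optimum
    param_rse: dict[str, float] = {}
    identifiable = True
    try:
        J = best.jac
        dof = max(n_used - spec.n_params, 1)
        s2 = rss / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for name, est, err in zip(spec.param_names, best.x, se):
            rse = err / abs(est) if abs(est) > 1e-12 else float("inf")
            param_rse[name] = float(rse)
            if name in ("k2", "k3") and rse > 1.0:
                identifiable = False
    except np.linalg.LinAlgError:
        identifiable = False

    ki, ki_defined = _macro_ki(spec, params)
    return KineticFit(spec=spec, params=params, rss=rss, n_points=n_used,
                      aic=fit_aic, ki=ki, ki_defined=ki_defined,
                      identifiable=identifiable, param_rse=param_rse,
                      region_label=tac.region_label)


def all_model_specs(with_vb: bool = True) -> list[ModelSpec]:
    """The candidate set: the four models, each with and without vB."""
    specs = [ModelSpec(name) for name in MODEL_PARAM_NAMES]
    if with_vb:
        specs += [ModelSpec(name, fit_vb=True) for name in MODEL_PARAM_NAMES]
    return specs


def select_model(
    tac: TimeActivityCurve,
    candidates: Sequence[ModelSpec],
    plasma: InputFunction,
    whole_blood: InputFunction | None = None,
    **fit_kwargs,
) -> tuple[KineticFit, pd.DataFrame]:
    """Fit every candidate and select the lowest-AIC model.

    Ties are broken toward fewer parameters. Returns the winning fit and a
    ranked table (one row per candidate) with parameters, RSS, AIC and Ki.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate model")
    fits: list[KineticFit] = []
    errors: list[str] = []
    for spec in candidates:
        try:
            fits.append(fit_model(tac, spec, plasma, whole_blood, **fit_kwargs))
        except Exception as exc:  # keep going; a subset may still fit
            errors.append(f"{spec.label}: {exc}")
    if not fits:
        raise RuntimeError("all candidate fits failed: " + "; ".join(errors))
    fits.sort(key=lambda f: (f.aic, f.spec.n_params))
    rows = []
    for rank, f in enumerate(fits, start=1):
        row = {
            "region": f.region_label, "model": f.spec.label,
            "n_params": f.spec.n_params, "rank": rank,
            "K1_mL_min_mL": f.params.K1, "k2_per_min": f.params.k2,
            "k3_per_min": f.params.k3, "k4_per_min": f.params.k4,
            "vB": f.params.vB, "rss": f.rss, "aic": f.aic,
            "Ki_mL_min_mL": f.ki, "ki_defined": f.ki_defined,
            "identifiable": f.identifiable,
        }
        rows.append(row)
    return fits[0], pd.DataFrame(rows)


def patlak(
    tac: TimeActivityCurve,
    plasma: InputFunction,
    t_star: float = 15.0,
    frame_mask: np.ndarray | None = None,
    grid_dt: float = 1.0,
) -> PatlakFit:
    """Patlak graphical analysis: OLS of C_T/Cp against int_0^t Cp / Cp.

    Uses frames with midpoint >= ``t_star`` minutes; the plasma integral is
    computed by trapezoid on the fine grid and the axes are in minutes, so
    the slope is Ki in mL/min/mL and the intercept the distribution volume
    of the reversible compartments plus blood.
    """
    sched = tac.schedule
    end = sched.total_duration
    if plasma.time[-1] < end - 1e-6:
        raise ValueError("plasma input function does not cover the schedule")
    grid = np.arange(0.0, end + grid_dt / 2, grid_dt)
    cp_grid = resample_to_grid(plasma.time, plasma.value, grid)
    int_cp = np.concatenate(
        [[0.0], np.cumsum((cp_grid[1:] + cp_grid[:-1]) / 2.0 * grid_dt)]
    )

    mids = sched.mid
    sel = mids >= t_star * 60.0
    if frame_mask is not None:
        sel &= np.asarray(frame_mask, dtype=bool)
    if int(np.sum(sel)) < 3:
        raise ValueError("need >= 3 frames at or beyond t_star")
    cp_mid = np.interp(mids[sel], grid, cp_grid)
    if np.any(cp_mid <= 0):
        raise ValueError("plasma activity must be > 0 at all Patlak frames")
    icp_mid = np.interp(mids[sel], grid, int_cp)

    x = icp_mid / cp_mid / 60.0  # minutes
    y = tac.values[sel] / cp_mid
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(res[0]) if res.size else float(np.sum((y - A @ [slope, intercept]) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PatlakFit(ki=float(slope), intercept=float(intercept), t_star=t_star,
                     r_squared=r2, points_used=int(np.sum(sel)))
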