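"""Ground-truth-labelled synthetic studies.

Generates everything the rest of the package consumes — arterial bolus
curves, sampler records, manual samples, tissue TACs, a multi-subject
cohort, and a 4-D vessel phantom — emulating a 60-min dynamic pelvic
acquisition with radial-artery sampling. Every generator is a pure
function of (truth, seed): regeneration is bit-identical.

The plasma bolus is a Feng-type tri-exponential,

    Cp(t) = (A1*(t-t0) - A2 - A3) e^{-l1 (t-t0)}
            + A2 e^{-l2 (t-t0)} + A3 e^{-l3 (t-t0)},   t > t0,

which rises linearly from zero at the bolus arrival t0, peaks within
seconds and decays tri-exponentially — the standard analytic bolus model
for PET simulation. Whole blood is plasma divided by the plasma-to-blood
ratio 1/(1-HCT) (tracer excluded from red cells, no metabolites).

Default amplitudes are scaled to a ~190 MBq injection in a 75 kg subject:
arterial peak ~120 kBq/mL, 60-min plasma tail ~1.5 kBq/mL, giving late
lesion SUVs of a few g/mL for tissue kinetics in the clinical ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import kinetics
from .blood import InputFunction, ManualSample, SamplerCurve, disperse, ratio_from_hct
from .image import DynamicImage, VoxelMask
from .tac import (
    GA68_HALF_LIFE_S,
    FrameSchedule,
    SubjectMeta,
    TimeActivityCurve,
    frame_average,
)

#: Clinically anchored kinetic interquartile ranges per tissue class
#: (K1 mL/min/mL; k2, k3 /min), sampled log-uniformly.
REGION_PARAM_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "lesion": {"K1": (0.099, 0.229), "k2": (0.213, 0.484), "k3": (0.057, 0.125)},
    "prostate": {"K1": (0.078, 0.107), "k2": (0.147, 0.329), "k3": (0.036, 0.056)},
    "muscle": {"K1": (0.021, 0.033), "k2": (0.184, 0.466), "k3": (0.031, 0.045)},
}

MANUAL_SAMPLE_TIMES_S = (180.0, 420.0, 900.0, 1500.0, 2400.0, 3570.0)


@dataclass(frozen=True)
class AifShape:
    """Feng tri-exponential bolus parameters (amplitudes Bq/mL, rates /s)."""

    t0: float = 10.0      # bolus arrival, s
    a1: float = 40000.0   # Bq/mL/s
    a2: float = 10000.0   # Bq/mL
    a3: float = 5000.0    # Bq/mL
    l1: float = 0.12      # /s
    l2: float = 0.01      # /s
    l3: float = 0.00012   # /s

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.a3) < 0 or min(self.l1, self.l2, self.l3) <= 0:
            raise ValueError("non-physical bolus parameters")


@dataclass(frozen=True)
class NoiseModel:
    """Frame-noise approximation: Gaussian with variance ~ value / (dt * decay).

    sd_i = alpha * sqrt(value_i / (duration_i * exp(-lambda t_i))); frames
    with shorter duration and later (more decayed) acquisition are noisier,
    as in count-limited dynamic PET. ``alpha = 0`` reproduces noiseless
    curves exactly.
    """

    alpha: float = 50.0
    half_life: float = GA68_HALF_LIFE_S

    def sd(self, schedule: FrameSchedule, values: np.ndarray) -> np.ndarray:
        lam = math.log(2.0) / self.half_life
        dcf = np.exp(-lam * schedule.mid)
        return self.alpha * np.sqrt(np.maximum(values, 0.0) / (schedule.duration * dcf))

    def apply(
        self, tac: TimeActivityCurve, rng: np.random.Generator
    ) -> TimeActivityCurve:
        if self.alpha == 0:
            return tac
        noisy = tac.values + rng.normal(0.0, 1.0, tac.values.size) * self.sd(
            tac.schedule, tac.values
        )
        return replace(tac, values=noisy, noise_corrupted=True)


@dataclass(frozen=True)
class PhantomGeometry:
    """Vessel-phantom layout: straight z-axis cylinders in a tissue slab."""

    vessel_diameters_mm: tuple[float, ...] = (8.0, 9.0)
    psf_fwhm_mm: float = 4.0
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    shape: tuple[int, int, int] = (48, 48, 24)


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to regenerate a study exactly."""

    seed: int = 0
    aif: AifShape = field(default_factory=AifShape)
    hematocrit: float = 0.38
    dispersion_tau: float = 5.0      # s
    calibration_factor: float = 10.0  # (Bq/mL)/cps
    background_cps: float = 20.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    injected_activity: float = 191.6  # MBq
    body_weight: float = 75.0         # kg
    half_life: float = GA68_HALF_LIFE_S

    @property
    def plasma_to_blood(self) -> float:
        return ratio_from_hct(self.hematocrit)


def feng_plasma(t: np.ndarray, shape: AifShape) -> np.ndarray:
    """Evaluate the tri-exponential plasma bolus (decay-corrected, Bq/mL)."""
    t = np.asarray(t, dtype=float)
    u = t - shape.t0
    out = np.where(
        u > 0,
        (shape.a1 * u - shape.a2 - shape.a3) * np.exp(-shape.l1 * u)
        + shape.a2 * np.exp(-shape.l2 * u)
        + shape.a3 * np.exp(-shape.l3 * u),
        0.0,
    )
    return np.maximum(out, 0.0)


def make_aif(
    truth: SyntheticTruth,
    end_time: float = 3600.0,
    dt: float = 1.0,
    sampler_end: float = 600.0,
    scale: float = 1.0,
) -> tuple[InputFunction, InputFunction, SamplerCurve, list[ManualSample]]:
    """Generate the blood data of one subject.

    Returns (plasma, whole_blood, sampler_curve, manual_samples). The
    sampler record is the whole-blood curve convolved with the dispersion
    kernel, decay-uncorrected and converted to counts with the calibration
    factor, plus a constant background; manual samples are decay-corrected
    draws at the six nominal times.
    """
    grid = np.arange(0.0, end_time + dt / 2, dt)
    cp = scale * feng_plasma(grid, truth.aif)
    ratio = truth.plasma_to_blood
    wb = cp / ratio
    plasma = InputFunction(time=grid, value=cp, matrix="plasma")
    whole_blood = InputFunction(time=grid, value=wb, matrix="whole_blood")

    s_grid = grid[grid <= sampler_end + dt / 2]
    wb_disp = disperse(s_grid, wb[: s_grid.size], truth.dispersion_tau)
    lam = math.log(2.0) / truth.half_life
    counts = wb_disp * np.exp(-lam * s_grid) / truth.calibration_factor + truth.background_cps
    sampler = SamplerCurve(
        time=s_grid, counts=counts, background=truth.background_cps,
        calibration_factor=truth.calibration_factor,
        dispersion_tau=truth.dispersion_tau, half_life=truth.half_life,
    )
    samples = [
        ManualSample(
            draw_time=t_s,
            whole_blood_activity=float(np.interp(t_s, grid, wb)),
            plasma_activity=float(np.interp(t_s, grid, cp)),
        )
        for t_s in MANUAL_SAMPLE_TIMES_S
    ]
    return plasma, whole_blood, sampler, samples


def draw_params(
    region: str, rng: np.random.Generator, vb: float = 0.0
) -> kinetics.KineticParams:
    """Draw 2T3k rate constants log-uniformly within the tissue-class IQR."""
    ranges = REGION_PARAM_RANGES[region]
    vals = {
        name: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for name, (lo, hi) in ranges.items()
    }
    return kinetics.KineticParams(K1=vals["K1"], k2=vals["k2"], k3=vals["k3"], vB=vb)


@dataclass
class SubjectStudy:
    """One synthetic subject: blood data, region TACs, truth, covariates."""

    meta: SubjectMeta
    plasma: InputFunction
    whole_blood: InputFunction
    sampler: SamplerCurve
    manual_samples: list[ManualSample]
    tacs: dict[str, TimeActivityCurve]
    true_params: dict[str, kinetics.KineticParams]
    covariates: dict[str, float]


@dataclass
class Cohort:
    truth: SyntheticTruth
    schedule: FrameSchedule
    subjects: list[SubjectStudy]

    @property
    def n_lesions(self) -> int:
        return sum(
            sum(1 for r in s.tacs if r.startswith("lesion")) for s in self.subjects
        )


def make_cohort(
    truth: SyntheticTruth | None = None,
    n_subjects: int = 14,
    n_two_lesion_subjects: int = 4,
    schedule: FrameSchedule | None = None,
    seed: int | None = None,
    psa_slope: float = 1.0,
    psa_sigma: float = 0.35,
) -> Cohort:
    """Generate a study cohort emulating the clinical sample.

    Defaults: 14 tracer-positive subjects, the first ``n_two_lesion_subjects``
    carrying two lesions (18 lesions total); each subject has lesion,
    normal-prostate and muscle TACs simulated from the irreversible
    two-tissue model with clinically anchored parameters, plus serum PSA linked
    monotonically to the hottest lesion's Ki:
    log PSA = a + psa_slope*log Ki + N(0, psa_sigma).
    """
    truth = truth if truth is not None else SyntheticTruth()
    if seed is None:
        seed = truth.seed
    if n_subjects < 1:
        raise ValueError("need n_subjects >= 1")
    if not (0 <= n_two_lesion_subjects <= n_subjects):
        raise ValueError("invalid lesion multiplicity")
    schedule = schedule if schedule is not None else FrameSchedule.default_60min()
    rng = np.random.default_rng(seed)

    subjects = []
    for i in range(n_subjects):
        scale = float(np.exp(rng.normal(0.0, 0.10)))
        plasma, wb, sampler, samples = make_aif(truth, scale=scale)
        regions = ["lesion", "prostate", "muscle"]
        if i < n_two_lesion_subjects:
            regions.insert(1, "lesion2")
        tacs: dict[str, TimeActivityCurve] = {}
        params: dict[str, kinetics.KineticParams] = {}
        for region in regions:
            cls = "lesion" if region.startswith("lesion") else region
            p = draw_params(cls, rng)
            clean = kinetics.simulate_tissue(
                kinetics.ModelSpec("2T3k"), p, plasma, wb, schedule,
                region_label=region,
            )
            tacs[region] = truth.noise.apply(clean, rng)
            params[region] = p

        max_ki = max(
            kinetics.net_influx(params[r])[0] for r in params if r.startswith("lesion")
        )
        a = math.log(8.6) - psa_slope * math.log(0.036)
        psa = math.exp(a + psa_slope * math.log(max_ki) + rng.normal(0.0, psa_sigma))
        prostate_weight = float(np.clip(rng.normal(40.0, 10.0), 15.0, 90.0))
        covars = {
            "psa_ng_ml": psa,
            "psa_density": psa / prostate_weight,
            "gleason": float(rng.choice([6, 7, 7, 7, 8, 9, 10])),
            "pirads": float(rng.choice([2, 3, 4, 5, 5])),
            "adc_e3_mm2_s": float(np.exp(rng.normal(math.log(0.71), 0.25))),
            "lesion_size_cm": float(np.exp(rng.normal(math.log(1.8), 0.4))),
        }
        weight = float(np.clip(rng.normal(truth.body_weight, 8.0), 50.0, 120.0))
        meta = SubjectMeta(
            injected_activity=truth.injected_activity * scale,
            body_weight=weight, hematocrit=truth.hematocrit,
            subject_id=f"S{i + 1:02d}",
        )
        subjects.append(
            SubjectStudy(meta=meta, plasma=plasma, whole_blood=wb, sampler=sampler,
                         manual_samples=samples, tacs=tacs, true_params=params,
                         covariates=covars)
        )
    return Cohort(truth=truth, schedule=schedule, subjects=subjects)


def _cylinder_fraction(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    center_xy_mm: tuple[float, float],
    radius_mm: float,
    supersample: int = 4,
) -> np.ndarray:
    """Per-voxel volume fraction of a z-axis cylinder (anti-aliased fill)."""
    nx, ny, nz = shape
    vx, vy, _ = voxel_size
    ss = supersample
    xs = (np.arange(nx * ss) + 0.5) * (vx / ss)
    ys = (np.arange(ny * ss) + 0.5) * (vy / ss)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    inside = ((X - center_xy_mm[0]) ** 2 + (Y - center_xy_mm[1]) ** 2) <= radius_mm**2
    frac = inside.reshape(nx, ss, ny, ss).mean(axis=(1, 3))
    return np.repeat(frac[:, :, None], nz, axis=2)


@dataclass
class PhantomStudy:
    """A 4-D vessel phantom with full ground truth."""

    image: DynamicImage
    vessel_masks: dict[float, VoxelMask]      # diameter -> boolean mask
    background_mask: VoxelMask
    true_vessel_values: np.ndarray            # per-frame whole-blood truth
    true_background_values: np.ndarray        # per-frame tissue truth


def make_phantom(
    truth: SyntheticTruth,
    whole_blood: InputFunction,
    background_tac: TimeActivityCurve,
    schedule: FrameSchedule | None = None,
    noise_rng: np.random.Generator | None = None,
    diameters: tuple[float, ...] | None = None,
) -> PhantomStudy:
    """Build the dynamic vessel phantom.

    Straight cylinders (one per diameter) filled with the frame-averaged
    whole-blood activity, embedded in a uniform tissue slab following
    ``background_tac``, blurred in-plane and axially with the isotropic
    Gaussian PSF, with optional frame noise. Voxel masks mark voxels whose
    centres fall inside each cylinder.
    """
    geom = truth.geometry
    schedule = schedule if schedule is not None else FrameSchedule.default_60min()
    diameters = diameters if diameters is not None else geom.vessel_diameters_mm
    shape = geom.shape
    vs = geom.voxel_size_mm
    for d in diameters:
        if d < 2 * min(vs[:2]):
            raise ValueError(f"vessel diameter {d} mm under 2 voxels")

    end = schedule.total_duration
    grid = np.arange(0.0, end + 0.5, 1.0)
    wb_vals = np.interp(grid, whole_blood.time, whole_blood.value)
    wb_frames = frame_average(grid, wb_vals, schedule)
    bg_frames = np.asarray(background_tac.values, dtype=float)
    if bg_frames.size != schedule.n_frames:
        raise ValueError("background TAC must match the schedule")

    fov_x = shape[0] * vs[0]
    fov_y = shape[1] * vs[1]
    n_v = len(diameters)
    centers = [
        (fov_x * (j + 1) / (n_v + 1), fov_y / 2.0) for j in range(n_v)
    ]
    fractions = []
    masks: dict[float, VoxelMask] = {}
    for d, c in zip(diameters, centers):
        r = d / 2.0
        if c[0] - r < 0 or c[0] + r > fov_x or c[1] - r < 0 or c[1] + r > fov_y:
            raise ValueError("cylinder exceeds the grid")
        fractions.append(_cylinder_fraction(shape, vs, c, r))
        xs = (np.arange(shape[0]) + 0.5) * vs[0]
        ys = (np.arange(shape[1]) + 0.5) * vs[1]
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        in2d = ((X - c[0]) ** 2 + (Y - c[1]) ** 2) <= r**2
        masks[float(d)] = VoxelMask(
            data=np.repeat(in2d[:, :, None], shape[2], axis=2),
            label=f"vessel_{d:g}mm", effective_diameter=float(d),
        )
    vessel_frac = np.clip(np.sum(fractions, axis=0), 0.0, 1.0)
    bg_frac = 1.0 - vessel_frac

    sigma_vox = [
        (geom.psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))) / v for v in vs
    ]
    data = np.empty(shape + (schedule.n_frames,))
    for f in range(schedule.n_frames):
        vol = vessel_frac * wb_frames[f] + bg_frac * bg_frames[f]
        if geom.psf_fwhm_mm > 0:
            vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
        data[..., f] = vol
    if noise_rng is not None and truth.noise.alpha > 0:
        lam = math.log(2.0) / truth.half_life
        dcf = np.exp(-lam * schedule.mid)
        sd = truth.noise.alpha * np.sqrt(
            np.maximum(data, 0.0) / (schedule.duration * dcf)
        )
        data = data + noise_rng.normal(0.0, 1.0, data.shape) * sd

    any_vessel = np.zeros(shape, dtype=bool)
    for m in masks.values():
        any_vessel |= m.data
    bg_mask = VoxelMask(data=~any_vessel, label="background")
    img = DynamicImage(data=data, voxel_size=vs, schedule=schedule)
    return PhantomStudy(
        image=img, vessel_masks=masks, background_mask=bg_mask,
        true_vessel_values=wb_frames, true_background_values=bg_frames,
    )


def make_calibration_phantoms(
    truth: SyntheticTruth,
    whole_blood: InputFunction,
    background_tac: TimeActivityCurve,
    diameters: tuple[float, ...] | None = None,
    schedule: FrameSchedule | None = None,
) -> list[tuple[float, DynamicImage, VoxelMask, np.ndarray]]:
    """Single-vessel phantoms (one per diameter) for PVC calibration."""
    diameters = diameters if diameters is not None else truth.geometry.vessel_diameters_mm
    out = []
    for d in diameters:
        ph = make_phantom(truth, whole_blood, background_tac, schedule=schedule,
                          diameters=(d,))
        out.append((float(d), ph.image, ph.vessel_masks[float(d)],
                    ph.true_vessel_values))
    return out
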