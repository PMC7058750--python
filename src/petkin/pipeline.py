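"""End-to-end study orchestration on synthetic data.

``run_study`` chains the full quantification: blood data -> corrected and
merged arterial input function -> image-derived input function from the
vessel phantom (partial-volume corrected) -> compartment fits with AIC
selection -> Ki / Patlak / SUV tables -> validation statistics. Outputs
are plain CSV and JSON so every run is diff-able.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import blood, image, kinetics, stats, synthetic
from .tac import FrameSchedule, TimeActivityCurve, suv_from_tac, window_mean_suv

log = logging.getLogger("petkin.pipeline")

SUV_WINDOWS_MIN = ((15.0, 30.0), (30.0, 45.0), (45.0, 60.0))


@dataclass(frozen=True)
class StudyConfig:
    """Resolved configuration of one synthetic-study run."""

    seed: int = 0
    n_subjects: int = 14
    n_two_lesion_subjects: int = 4
    noise_alpha: float = 50.0
    with_idif: bool = True
    t_star_min: float = 15.0
    n_starts: int = 10
    weights_scheme: str = "uniform"  # "uniform" | "frame"
    suv_windows: tuple[tuple[float, float], ...] = SUV_WINDOWS_MIN
    select_full_candidate_set: bool = True

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.n_two_lesion_subjects <= self.n_subjects):
            raise ValueError("invalid n_two_lesion_subjects")
        if self.weights_scheme not in ("uniform", "frame"):
            raise ValueError("weights_scheme must be 'uniform' or 'frame'")
        if self.noise_alpha < 0 or self.n_starts < 1 or self.t_star_min <= 0:
            raise ValueError("invalid configuration")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _weights(scheme: str, schedule: FrameSchedule, half_life: float) -> np.ndarray:
    if scheme == "uniform":
        return np.ones(schedule.n_frames)
    lam = math.log(2.0) / half_life
    w = schedule.duration * np.exp(-lam * schedule.mid)
    return w / w.mean()


def build_aif(subject: synthetic.SubjectStudy) -> tuple[blood.InputFunction, blood.InputFunction, float]:
    """Sampler record + manual samples -> (plasma AIF, whole-blood AIF, ratio)."""
    wb_sampler = blood.correct_sampler(subject.sampler)
    wb_merged = blood.merge_with_manual(wb_sampler, subject.manual_samples)
    ratio = blood.subject_plasma_ratio(subject.manual_samples)
    plasma = blood.blood_to_plasma(wb_merged, ratio)
    return plasma, wb_merged, ratio


def build_idif(
    subject: synthetic.SubjectStudy,
    truth: synthetic.SyntheticTruth,
    cal: image.PvcCalibration,
    schedule: FrameSchedule,
    ratio: float,
    rng: np.random.Generator | None = None,
) -> tuple[blood.InputFunction, blood.InputFunction, float]:
    """Phantom -> pooled-vessel median -> PVC -> (plasma IDIF, wb IDIF, AUCr)."""
    phantom = synthetic.make_phantom(
        truth, subject.whole_blood, subject.tacs["muscle"],
        schedule=schedule, noise_rng=rng,
    )
    # pool both vessel cylinders into one mask; correct at the mean diameter
    pooled = np.zeros(phantom.image.data.shape[:3], dtype=bool)
    for m in phantom.vessel_masks.values():
        pooled |= m.data
    pooled_mask = image.VoxelMask(data=pooled, label="vessels")
    raw = image.mask_tac(phantom.image, pooled_mask, statistic="median")
    bg = image.mask_tac(
        phantom.image, image.shell_mask(pooled_mask, phantom.image.voxel_size),
        statistic="median",
    )
    d_eff = float(np.mean(list(phantom.vessel_masks)))
    idif_wb = image.pvc_correct_idif(raw, bg, cal, d_eff)
    auc_ratio = blood.aucr(idif_wb, subject.whole_blood)
    # frame midpoints stop half a frame short of the scan end
    idif_wb = blood.extend_tail(idif_wb, schedule.total_duration)
    idif_plasma = blood.blood_to_plasma(idif_wb, ratio)
    return idif_plasma, idif_wb, auc_ratio


def calibrate_phantom_pvc(
    truth: synthetic.SyntheticTruth, schedule: FrameSchedule
) -> image.PvcCalibration:
    """PVC calibration from single-vessel phantoms with generic curves."""
    plasma, wb, _, _ = synthetic.make_aif(truth)
    p_muscle = kinetics.KineticParams(K1=0.027, k2=0.29, k3=0.038)
    bg_tac = kinetics.simulate_tissue(
        kinetics.ModelSpec("2T3k"), p_muscle, plasma, wb, schedule,
        region_label="muscle",
    )
    return image.calibrate_pvc(
        synthetic.make_calibration_phantoms(truth, wb, bg_tac, schedule=schedule)
    )


def run_study(config: StudyConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Run the complete analysis chain and write its tables to ``outdir``.

    Emits input-function summaries with AUCr, the per-region model-fit /
    AIC-ranking table, the SUV window table, and the correlation/agreement
    table, plus a JSON run log with the seed and config hash. Returns the
    tables keyed by name.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = synthetic.SyntheticTruth(
        seed=config.seed, noise=synthetic.NoiseModel(alpha=config.noise_alpha)
    )
    schedule = FrameSchedule.default_60min()
    log.info("generating cohort: %d subjects", config.n_subjects)
    cohort = synthetic.make_cohort(
        truth, n_subjects=config.n_subjects,
        n_two_lesion_subjects=config.n_two_lesion_subjects,
    )
    weights = _weights(config.weights_scheme, schedule, truth.half_life)
    candidates = (
        kinetics.all_model_specs()
        if config.select_full_candidate_set
        else [kinetics.ModelSpec("2T3k")]
    )

    cal = calibrate_phantom_pvc(truth, schedule) if config.with_idif else None

    fit_rows, suv_rows, if_rows, select_rows = [], [], [], []
    for subj in cohort.subjects:
        sid = subj.meta.subject_id
        plasma_aif, wb_aif, ratio = build_aif(subj)
        if_rows.append({
            "subject": sid, "plasma_to_blood_ratio": ratio,
            "hct_from_ratio": blood.hct_from_ratio(ratio),
        })
        arms = {"aif_plasma": (plasma_aif, wb_aif)}
        if config.with_idif:
            idif_plasma, idif_wb, auc_ratio = build_idif(
                subj, truth, cal, schedule, ratio
            )
            if_rows[-1]["aucr_wb"] = auc_ratio
            arms["idif_plasma"] = (idif_plasma, idif_wb)
            arms["idif_wb"] = (idif_wb, idif_wb)

        for region, tac in subj.tacs.items():
            # SUV windows (AIF-independent)
            suv = suv_from_tac(tac, subj.meta)
            row = {"subject": sid, "region": region}
            for lo, hi in config.suv_windows:
                row[f"suv_{lo:g}_{hi:g}"] = window_mean_suv(suv, lo, hi)
            suv_rows.append(row)

            true_ki, _ = kinetics.net_influx(subj.true_params[region])
            for arm, (pl, wb) in arms.items():
                if arm != "aif_plasma" and not region.startswith("lesion"):
                    continue  # IDIF validation is lesion-based
                if arm == "aif_plasma" and config.select_full_candidate_set:
                    best, table = kinetics.select_model(
                        tac, candidates, pl, wb, weights=weights,
                        n_starts=config.n_starts, seed=config.seed,
                    )
                    table.insert(0, "subject", sid)
                    table.insert(2, "arm", arm)
                    select_rows.append(table)
                fit = kinetics.fit_model(
                    tac, kinetics.ModelSpec("2T3k"), pl, wb, weights=weights,
                    n_starts=config.n_starts, seed=config.seed,
                )
                pk = kinetics.patlak(tac, pl, t_star=config.t_star_min)
                fit_rows.append({
                    "subject": sid, "region": region, "arm": arm,
                    "K1_mL_min_mL": fit.params.K1, "k2_per_min": fit.params.k2,
                    "k3_per_min": fit.params.k3,
                    "Ki_mL_min_mL": fit.ki, "patlak_Ki_mL_min_mL": pk.ki,
                    "patlak_r2": pk.r_squared, "rss": fit.rss, "aic": fit.aic,
                    "identifiable": fit.identifiable, "true_Ki": true_ki,
                })

    fits = pd.DataFrame(fit_rows)
    suvs = pd.DataFrame(suv_rows)
    ifs = pd.DataFrame(if_rows)
    selection = (
        pd.concat(select_rows, ignore_index=True) if select_rows else pd.DataFrame()
    )

    validation = validate_tables(fits, suvs, cohort, config)

    tables = {
        "input_functions": ifs, "model_fits": fits,
        "model_selection": selection, "suv_windows": suvs,
        **validation,
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    run_log = {
        "seed": config.seed, "config": dataclasses.asdict(config),
        "config_hash": config.hash(), "n_lesions": cohort.n_lesions,
        "versions": _versions(),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    log.info("study complete: %s", outdir)
    return tables


def validate_tables(
    fits: pd.DataFrame, suvs: pd.DataFrame,
    cohort: synthetic.Cohort, config: StudyConfig,
) -> dict[str, pd.DataFrame]:
    """Validation statistics over the fitted cohort.

    Builds the lesion-level paired table (most-avid selection), then the
    SUV-vs-Ki / covariate Spearman matrix, region/window comparisons, and
    the AIF-vs-IDIF agreement (ICC) rows.
    """
    aif = fits[fits["arm"] == "aif_plasma"]
    lesions = aif[aif["region"].str.startswith("lesion")].copy()
    suv_cols = [c for c in suvs.columns if c.startswith("suv_")]
    late_col = suv_cols[-1]
    merged = lesions.merge(suvs, on=["subject", "region"])
    covars = pd.DataFrame([
        {"subject": s.meta.subject_id, **s.covariates} for s in cohort.subjects
    ])
    merged = merged.merge(covars, on="subject")
    avid = stats.most_avid_per_subject(merged, suv_col=late_col)

    corr_rows = []
    for sc in suv_cols:
        for target in ["Ki_mL_min_mL", "psa_ng_ml", "psa_density"]:
            rho, p = stats.spearman(avid[sc].to_numpy(), avid[target].to_numpy())
            corr_rows.append({"suv_window": sc, "target": target,
                              "rho": rho, "p": p})
    rho_pk, p_pk = stats.spearman(
        lesions["Ki_mL_min_mL"].to_numpy(), lesions["patlak_Ki_mL_min_mL"].to_numpy()
    )
    corr_rows.append({"suv_window": "", "target": "patlak_vs_compartment_Ki",
                      "rho": rho_pk, "p": p_pk})
    correlations = pd.DataFrame(corr_rows)

    agreement_rows = []
    for arm in ("idif_plasma", "idif_wb"):
        sub = fits[fits["arm"] == arm]
        if sub.empty:
            continue
        paired = lesions.merge(sub, on=["subject", "region"],
                               suffixes=("_aif", "_" + arm))
        paired = paired.merge(
            suvs[["subject", "region", late_col]], on=["subject", "region"]
        )
        paired = stats.most_avid_per_subject(paired, suv_col=late_col)
        for quantity in ("Ki_mL_min_mL", "patlak_Ki_mL_min_mL", "K1_mL_min_mL"):
            icc, p = stats.icc3(
                paired[[quantity + "_aif", quantity + "_" + arm]].to_numpy()
            )
            agreement_rows.append({"arm": arm, "quantity": quantity,
                                   "icc3": icc, "p": p})
    agreement = pd.DataFrame(agreement_rows)

    region_rows = []
    avid_suv = stats.most_avid_per_subject(
        suvs[suvs["region"].str.startswith("lesion")], suv_col=late_col
    )
    by_region = {"lesion": avid_suv}
    for reg in ("prostate", "muscle"):
        by_region[reg] = suvs[suvs["region"] == reg]
    for reg, df in by_region.items():
        for sc in suv_cols:
            q = df[sc].quantile([0.25, 0.5, 0.75])
            region_rows.append({"region": reg, "window": sc,
                                "median": q[0.5], "q1": q[0.25], "q3": q[0.75]})
    suv_summary = pd.DataFrame(region_rows)
    # Friedman across windows (lesions) and across regions (late window)
    lesion_mat = avid_suv[suv_cols].to_numpy()
    if lesion_mat.shape[0] >= 2 and len(suv_cols) >= 3:
        fr_stat, fr_p = stats.friedman(lesion_mat, method="asymptotic")
        suv_summary.attrs["friedman_windows_lesion"] = (fr_stat, fr_p)
        suv_summary = pd.concat([
            suv_summary,
            pd.DataFrame([{"region": "lesion", "window": "friedman_windows",
                           "median": fr_stat, "q1": fr_p, "q3": np.nan}]),
        ], ignore_index=True)
    return {"correlations": correlations, "agreement": agreement,
            "suv_summary": suv_summary}


def _versions() -> dict[str, str]:
    import nibabel
    import scipy

    return {
        "numpy": np.__version__, "scipy": scipy.__version__,
        "pandas": pd.__version__, "nibabel": nibabel.__version__,
    }
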