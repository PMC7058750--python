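"""Plain-text and NIfTI interfaces.

CSV schemas:

* TAC file: ``frame_start_s, frame_duration_s, value_Bq_per_mL, region``
  (one block of rows per region, shared schedule);
* sampler file: ``time_s, cps``;
* manual samples: ``draw_time_s, wb_Bq_per_mL, plasma_Bq_per_mL``;
* input function: ``time_s, value_Bq_per_mL, matrix``.

Subject metadata and PVC calibration tables round-trip through YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .blood import InputFunction, ManualSample
from .image import DynamicImage, PvcCalibration, VoxelMask
from .tac import FrameSchedule, SubjectMeta, TimeActivityCurve


def write_tacs(path: str | Path, tacs: list[TimeActivityCurve]) -> None:
    frames = []
    for tac in tacs:
        frames.append(pd.DataFrame({
            "frame_start_s": tac.schedule.start,
            "frame_duration_s": tac.schedule.duration,
            "value_Bq_per_mL": tac.values,
            "region": tac.region_label,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tacs(path: str | Path) -> list[TimeActivityCurve]:
    df = pd.read_csv(path)
    out = []
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("frame_start_s")
        sched = FrameSchedule(
            start=grp["frame_start_s"].to_numpy(),
            duration=grp["frame_duration_s"].to_numpy(),
        )
        values = grp["value_Bq_per_mL"].to_numpy()
        out.append(TimeActivityCurve(
            schedule=sched, values=values, region_label=str(region),
            noise_corrupted=bool(np.any(values < 0)),
        ))
    return out


def write_input_function(path: str | Path, f: InputFunction) -> None:
    pd.DataFrame({
        "time_s": f.time, "value_Bq_per_mL": f.value, "matrix": f.matrix,
    }).to_csv(path, index=False)


def read_input_function(path: str | Path, provenance: str = "sampler_merged") -> InputFunction:
    df = pd.read_csv(path)
    matrix = str(df["matrix"].iloc[0])
    return InputFunction(
        time=df["time_s"].to_numpy(), value=df["value_Bq_per_mL"].to_numpy(),
        matrix=matrix, provenance=provenance,
    )


def write_manual_samples(path: str | Path, samples: list[ManualSample]) -> None:
    pd.DataFrame({
        "draw_time_s": [s.draw_time for s in samples],
        "wb_Bq_per_mL": [s.whole_blood_activity for s in samples],
        "plasma_Bq_per_mL": [s.plasma_activity for s in samples],
    }).to_csv(path, index=False)


def read_manual_samples(path: str | Path) -> list[ManualSample]:
    df = pd.read_csv(path)
    return [
        ManualSample(draw_time=row.draw_time_s,
                     whole_blood_activity=row.wb_Bq_per_mL,
                     plasma_activity=row.plasma_Bq_per_mL)
        for row in df.itertuples()
    ]


def write_sampler_csv(path: str | Path, time: np.ndarray, cps: np.ndarray) -> None:
    pd.DataFrame({"time_s": time, "cps": cps}).to_csv(path, index=False)


def read_sampler_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), df["cps"].to_numpy()


def subject_meta_to_dict(meta: SubjectMeta) -> dict:
    return {
        "injected_activity_MBq": meta.injected_activity,
        "body_weight_kg": meta.body_weight,
        "hematocrit": meta.hematocrit,
        "subject_id": meta.subject_id,
    }


def subject_meta_from_dict(d: dict) -> SubjectMeta:
    return SubjectMeta(
        injected_activity=d["injected_activity_MBq"],
        body_weight=d["body_weight_kg"],
        hematocrit=d.get("hematocrit"),
        subject_id=d.get("subject_id", ""),
    )


def write_pvc_calibration(path: str | Path, cal: PvcCalibration) -> None:
    path = Path(path)
    table = cal.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(table))
    else:
        path.write_text(json.dumps(table, indent=2))


def read_pvc_calibration(path: str | Path) -> PvcCalibration:
    path = Path(path)
    text = path.read_text()
    table = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return PvcCalibration.from_dict(table)


def save_dynamic_image(path: str | Path, img: DynamicImage) -> None:
    affine = np.diag(list(img.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(img.data.astype(np.float32), affine), str(path))


def load_dynamic_image(path: str | Path, schedule: FrameSchedule) -> DynamicImage:
    ni = nib.load(str(path))
    voxel_size = tuple(float(z) for z in ni.header.get_zooms()[:3])
    return DynamicImage(data=np.asarray(ni.dataobj, dtype=float),
                        voxel_size=voxel_size, schedule=schedule)


def save_mask(path: str | Path, mask: VoxelMask,
              voxel_size: tuple[float, float, float]) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def load_mask(path: str | Path, reference: DynamicImage,
              label: str = "") -> VoxelMask:
    ni = nib.load(str(path))
    affine_ref = np.diag(list(reference.voxel_size) + [1.0])
    if not np.array_equal(np.asarray(ni.affine), affine_ref):
        raise ValueError("mask affine does not match the image grid bit-exactly")
    return VoxelMask(data=np.asarray(ni.dataobj) > 0, label=label)
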